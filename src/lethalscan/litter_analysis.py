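"""Litter phenotype contrasts between carrier mating classes.

Litters are classified by parental carrier status (sire letter first:
NxN, CxN, NxC, CxC), survival rates are aggregated per class from pooled
counts, per-litter phenotypes are contrasted with Welch's t-test, and
pre-weaning mortality is tabulated by age window.  Under a fully
penetrant recessive lethal, carrier-by-carrier litters lose the quarter
of live-born piglets that are homozygous, a ~25% relative drop in
lactation survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .haplotype_scan import CarrierStatus

FATE_STILLBORN = "stillborn"
FATE_DIED = "died"
FATE_WEANED = "weaned"

MATING_CLASSES = ("NxN", "CxN", "NxC", "CxC")


@dataclass
class Piglet:
    piglet_id: str
    fate: str  # stillborn | died | weaned
    age_hours: float | None = None  # age at death, for fate == died
    genotype: int | None = None  # lethal-allele dosage when genotyped

    def __post_init__(self) -> None:
        if self.fate not in (FATE_STILLBORN, FATE_DIED, FATE_WEANED):
            raise ValueError(f"unknown fate {self.fate!r}")
        if self.fate == FATE_DIED and (self.age_hours is None or self.age_hours < 0):
            raise ValueError("death requires a non-negative age_hours")


@dataclass
class LitterRecord:
    """One farrowing with its counts and optional per-piglet fates."""

    litter_id: str
    sire: str
    dam: str
    total_born: int
    live_born: int
    stillborn: int
    mummified: int = 0
    piglets: list[Piglet] = field(default_factory=list)
    n_weaned: int | None = None  # taken from piglet fates when absent

    def __post_init__(self) -> None:
        if self.live_born + self.stillborn != self.total_born:
            raise ValueError("live_born + stillborn must equal total_born")
        if self.n_weaned is None:
            self.n_weaned = sum(1 for p in self.piglets if p.fate == FATE_WEANED)

    @property
    def farrowing_survival(self) -> float:
        return self.live_born / self.total_born if self.total_born else float("nan")

    @property
    def lactation_survival(self) -> float:
        return self.n_weaned / self.live_born if self.live_born else float("nan")


@dataclass
class MatingClassSummary:
    mating_class: str
    n_litters: int
    mean_total_born: float
    mean_live_born: float
    farrowing_survival_pct: float
    lactation_survival_pct: float | None  # None when no live-born in the class


def classify_matings(litters: Iterable[LitterRecord],
                     carriers: CarrierStatus) -> tuple[dict[str, str], list[str]]:
    """Map litter id -> mating class; sire status is the first letter.

    Litters with either parent of unknown carrier status are excluded and
    returned separately.
    """
    classes: dict[str, str] = {}
    excluded: list[str] = []
    for litter in litters:
        sire_d = carriers.dosage.get(litter.sire)
        dam_d = carriers.dosage.get(litter.dam)
        if sire_d is None or dam_d is None:
            excluded.append(litter.litter_id)
            continue
        classes[litter.litter_id] = (
            ("C" if sire_d >= 1 else "N") + "x" + ("C" if dam_d >= 1 else "N"))
    return classes, excluded


def summarize_by_class(litters: Iterable[LitterRecord],
                       classes: dict[str, str]) -> list[MatingClassSummary]:
    """Per-class litter means and pooled survival percentages.

    Survival rates pool counts across litters (ratio of sums), which is
    robust to litter-size variation; per-litter ratios are reserved for
    the Welch contrasts.
    """
    litters = list(litters)
    out = []
    for cls in MATING_CLASSES:
        members = [l for l in litters if classes.get(l.litter_id) == cls]
        if not members:
            continue
        total = sum(l.total_born for l in members)
        live = sum(l.live_born for l in members)
        weaned = sum(l.n_weaned for l in members)
        out.append(MatingClassSummary(
            mating_class=cls,
            n_litters=len(members),
            mean_total_born=total / len(members),
            mean_live_born=live / len(members),
            farrowing_survival_pct=100.0 * live / total if total else float("nan"),
            lactation_survival_pct=100.0 * weaned / live if live else None,
        ))
    return out


def summary_frame(summaries: list[MatingClassSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "status": s.mating_class,
        "n_litters": s.n_litters,
        "avg_total_born": s.mean_total_born,
        "avg_live_born": s.mean_live_born,
        "farrowing_survival_pct": s.farrowing_survival_pct,
        "lactation_survival_pct": s.lactation_survival_pct,
    } for s in summaries])


def welch_t_test(sample_a: Iterable[float], sample_b: Iterable[float]
                 ) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(df), float(p)


def contrast_classes(litters: Iterable[LitterRecord], classes: dict[str, str],
                     phenotype: str = "lactation_survival",
                     class_a: str = "CxC", class_b: str = "CxN",
                     pool_reciprocal: bool = False) -> tuple[float, float, float]:
    """Welch contrast of a per-litter phenotype between two mating classes.

    ``pool_reciprocal`` pools CxN with NxC for the reference class (the
    default contrasts the literal carrier-sire class only).
    """
    litters = list(litters)

    def values(cls: str) -> list[float]:
        accept = {cls}
        if pool_reciprocal and cls in ("CxN", "NxC"):
            accept = {"CxN", "NxC"}
        vals = [getattr(l, phenotype) for l in litters if classes.get(l.litter_id) in accept]
        return [v for v in vals if not np.isnan(v)]

    return welch_t_test(values(class_a), values(class_b))


def mortality_timing(litters: Iterable[LitterRecord],
                     genotype_labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Counts of live-born piglets by outcome window, stratified by genotype.

    Rows: died <=24h, died (24,48]h, died >48h, weaned.  Columns: one per
    genotype stratum (homozygote / carrier / wildtype / ungenotyped).
    """
    labels = genotype_labels or {2: "homozygote", 1: "carrier", 0: "wildtype"}
    strata = ["died_le24h", "died_le48h", "died_gt48h", "weaned"]
    cols: dict[str, dict[str, int]] = {}
    for litter in litters:
        for p in litter.piglets:
            if p.fate == FATE_STILLBORN:
                continue
            group = labels.get(p.genotype, "ungenotyped") if p.genotype is not None \
                else "ungenotyped"
            col = cols.setdefault(group, {s: 0 for s in strata})
            if p.fate == FATE_WEANED:
                col["weaned"] += 1
            elif p.age_hours <= 24:
                col["died_le24h"] += 1
            elif p.age_hours <= 48:
                col["died_le48h"] += 1
            else:
                col["died_gt48h"] += 1
    return pd.DataFrame(cols, dtype=int).reindex(strata).fillna(0).astype(int)


# ---------------------------------------------------------------------------
# CSV round-trip (documented headers)

LITTER_COLUMNS = ["litter_id", "sire", "dam", "total_born", "live_born",
                  "stillborn", "mummified", "n_weaned"]
PIGLET_COLUMNS = ["litter_id", "piglet_id", "fate", "age_hours", "genotype"]


def litters_to_frames(litters: Iterable[LitterRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    lit_rows, pig_rows = [], []
    for l in litters:
        lit_rows.append([l.litter_id, l.sire, l.dam, l.total_born, l.live_born,
                         l.stillborn, l.mummified, l.n_weaned])
        for p in l.piglets:
            pig_rows.append([l.litter_id, p.piglet_id, p.fate, p.age_hours, p.genotype])
    return (pd.DataFrame(lit_rows, columns=LITTER_COLUMNS),
            pd.DataFrame(pig_rows, columns=PIGLET_COLUMNS))


def litters_from_frames(litter_frame: pd.DataFrame,
                        piglet_frame: pd.DataFrame | None = None) -> list[LitterRecord]:
    piglets_by_litter: dict[str, list[Piglet]] = {}
    if piglet_frame is not None:
        for row in piglet_frame.itertuples(index=False):
            geno = None if pd.isna(row.genotype) else int(row.genotype)
            age = None if pd.isna(row.age_hours) else float(row.age_hours)
            piglets_by_litter.setdefault(str(row.litter_id), []).append(
                Piglet(str(row.piglet_id), str(row.fate), age, geno))
    out = []
    for row in litter_frame.itertuples(index=False):
        lid = str(row.litter_id)
        out.append(LitterRecord(
            litter_id=lid, sire=str(row.sire), dam=str(row.dam),
            total_born=int(row.total_born), live_born=int(row.live_born),
            stillborn=int(row.stillborn), mummified=int(row.mummified),
            piglets=piglets_by_litter.get(lid, []),
            n_weaned=int(row.n_weaned) if not pd.isna(row.n_weaned) else None))
    return out
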