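"""Mendelian segregation tests and penetrance summaries for genotyped litters.

Carrier-by-carrier matings are expected to segregate 1 wildtype : 2
carrier : 1 homozygote at birth; when homozygotes die before genotyping
age the surviving progeny segregate 1 : 2.  Goodness of fit is assessed
with a chi-squared test and, for small litter sets, an exact multinomial
test under probability-mass ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

EXPECTATIONS = {
    "birth_1_2_1": (1.0, 2.0, 1.0),
    "survivors_1_2": (1.0, 2.0),
}


@dataclass
class PigletGenotype:
    genotype: int  # 0 wildtype, 1 carrier, 2 homozygote
    fate: str  # stillborn | died | weaned
    age_hours: float | None = None


@dataclass
class LitterGenotypes:
    litter_id: str
    n_wildtype: int
    n_carrier: int
    n_homozygote: int
    piglets: list[PigletGenotype] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n_wildtype + self.n_carrier + self.n_homozygote

    def __post_init__(self) -> None:
        if min(self.n_wildtype, self.n_carrier, self.n_homozygote) < 0 or self.total < 1:
            raise ValueError("genotype counts must be non-negative with total >= 1")


@dataclass
class SegregationTestResult:
    chi_squared: float
    df: int
    p_chi_squared: float
    p_exact: float | None  # exact multinomial p, when total <= exact_max
    low_expected_warning: bool


def pool_litters(litters: Iterable[LitterGenotypes]) -> tuple[int, int, int]:
    wt = het = hom = 0
    for l in litters:
        wt += l.n_wildtype
        het += l.n_carrier
        hom += l.n_homozygote
    return wt, het, hom


def segregation_test(counts: Sequence[int], expectation: str,
                     exact_max: int = 100) -> SegregationTestResult:
    """Goodness of fit of genotype counts against a Mendelian ratio.

    ``birth_1_2_1`` expects (wildtype, carrier, homozygote) against 1:2:1;
    ``survivors_1_2`` expects (wildtype, carrier) against 1:2, the
    post-lethality expectation when homozygotes die before genotyping.
    An exact multinomial p (probability-mass ordering) is reported in
    addition whenever the total count is at most ``exact_max``.
    """
    if expectation not in EXPECTATIONS:
        raise ValueError(f"unknown expectation {expectation!r}")
    ratio = EXPECTATIONS[expectation]
    counts = tuple(int(c) for c in counts)
    if len(counts) != len(ratio):
        raise ValueError(f"{expectation} expects {len(ratio)} counts, got {len(counts)}")
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    probs = np.asarray(ratio) / sum(ratio)
    expected = total * probs
    low = bool(np.any(expected < 1))
    if low:
        warnings.warn("expected cell count below 1; prefer the exact test")
    chi2, p_chi2 = stats.chisquare(counts, f_exp=expected)
    p_exact = exact_multinomial_p(counts, probs) if total <= exact_max else None
    return SegregationTestResult(
        chi_squared=float(chi2), df=len(counts) - 1, p_chi_squared=float(p_chi2),
        p_exact=p_exact, low_expected_warning=low)


def exact_multinomial_p(counts: Sequence[int], probs: Sequence[float]) -> float:
    """Exact multinomial goodness-of-fit p with probability-mass ordering.

    Sums the probabilities of all outcome vectors whose multinomial
    probability does not exceed that of the observed vector (the same
    ordering convention as the HWE exact test).
    """
    counts = tuple(int(c) for c in counts)
    probs = np.asarray(probs, dtype=float)
    n = sum(counts)
    k = len(counts)
    logp_obs = stats.multinomial.logpmf(counts, n, probs)
    total = 0.0
    for combo in _compositions(n, k):
        lp = stats.multinomial.logpmf(combo, n, probs)
        if lp <= logp_obs + 1e-10:
            total += float(np.exp(lp))
    return min(total, 1.0)


def _compositions(n: int, k: int):
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


@dataclass
class PenetranceSummary:
    n_homozygotes: int
    n_homozygotes_dead_within_window: int
    penetrance: float | None  # None when no homozygotes observed
    n_others: int
    n_others_dead_within_window: int
    others_rate: float | None


def penetrance_summary(litters: Iterable[LitterGenotypes],
                       death_window_hours: float = 48.0) -> PenetranceSummary:
    """Fraction of homozygotes dead within the window, vs all other piglets.

    Stillborn piglets count as dead within the window (age 0); litters
    must carry per-piglet genotypes and fates.
    """
    n_hom = hom_dead = n_other = other_dead = 0
    for litter in litters:
        for p in litter.piglets:
            dead = (p.fate == "stillborn"
                    or (p.fate == "died" and p.age_hours is not None
                        and p.age_hours <= death_window_hours))
            if p.genotype == 2:
                n_hom += 1
                hom_dead += dead
            else:
                n_other += 1
                other_dead += dead
    return PenetranceSummary(
        n_homozygotes=n_hom,
        n_homozygotes_dead_within_window=hom_dead,
        penetrance=hom_dead / n_hom if n_hom else None,
        n_others=n_other,
        n_others_dead_within_window=other_dead,
        others_rate=other_dead / n_other if n_other else None)
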