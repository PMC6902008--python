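"""Gene-drop simulation of a pedigreed population carrying a recessive lethal.

The simulator emulates the statistical structure every downstream stage
assumes: a pig nucleus line of discrete generations bred by random
mating (one sire serving ~10 dams), litters of about ten piglets with
baseline farrowing/lactation survival of 91%/90%, one recessive lethal
allele at ~4.5% founder frequency riding on an identifiable ancestral
marker haplotype, homozygote death before genotyping age, a sequenced
subset with an LD neighborhood around the causal 16-bp deletion, and
DEBV-like trait records with reliabilities and weights.

Meiosis uses Haldane's no-interference model: a Poisson crossover
process along the chromosome, realized at marker resolution as
independent inter-marker recombination events with probability
``(1 - exp(-2 d)) / 2`` for map distance ``d`` Morgan.

Only piglets surviving to weaning enter the genotyped panel, so under
full penetrance no panel animal is homozygous for the lethal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotype_io import MarkerMap, PhasedPanel
from .litter_analysis import (FATE_DIED, FATE_STILLBORN, FATE_WEANED,
                              LitterRecord, Piglet)
from .segregation_validation import LitterGenotypes, PigletGenotype
from .variant_prioritization import CdsModel, VariantRecord, format_hgvs_del

HOURS_PER_DAY = 24.0
WEANING_HOURS = 21 * HOURS_PER_DAY

CAUSAL_DELETED_SEQUENCE = "GACGGTGTACGCCGGT"


@dataclass
class SimulationConfig:
    """Study conditions for the gene drop.

    Baseline litter parameters follow the reference population this
    simulator emulates: mean total born ~10, farrowing survival 91%,
    lactation survival 90%, lethal allele frequency 4.5%, and a carrier
    effect of -0.39 on the lactation-survival DEBV.  By default
    homozygotes experience the baseline stillbirth rate and every
    live-born homozygote dies within 48 h (full penetrance).
    """

    n_founders: int = 1000
    n_generations: int = 2
    litter_size_mean: float = 10.0
    markers_per_chromosome: int = 100
    n_chromosomes: int = 3
    chromosome_length_cM: float = 100.0
    lethal_allele_freq: float = 0.045
    lethal_chromosome: int = 1  # 1-based chromosome index
    lethal_position_cM: float | None = None  # default: mid-chromosome
    core_haplotype_halfwidth_cM: float = 12.5
    p_stillborn_given_homozygote: float | None = None  # default: 1 - farrowing survival
    p_death_48h_given_homozygote: float | None = None  # default: complement (full penetrance)
    baseline_farrowing_survival: float = 0.91
    baseline_lactation_survival: float = 0.90
    carrier_effect_on_trait: float = -0.39
    trait_heritability: float = 0.10
    sire_dam_ratio: float = 0.1  # sires per dam (1:10)
    litters_per_generation: int | None = None  # cap; default one litter per dam
    n_sequenced: int = 71
    n_sequenced_carriers: int = 5
    n_wgs_variants: int = 300
    n_validation_litters: int = 5
    seed: int = 1

    def resolved(self) -> "SimulationConfig":
        cfg = SimulationConfig(**asdict(self))
        if cfg.lethal_position_cM is None:
            cfg.lethal_position_cM = cfg.chromosome_length_cM / 2.0
        if cfg.p_stillborn_given_homozygote is None:
            cfg.p_stillborn_given_homozygote = 1.0 - cfg.baseline_farrowing_survival
        if cfg.p_death_48h_given_homozygote is None:
            cfg.p_death_48h_given_homozygote = 1.0 - cfg.p_stillborn_given_homozygote
        cfg.validate()
        return cfg

    def validate(self) -> None:
        fracs = {
            "lethal_allele_freq": self.lethal_allele_freq,
            "baseline_farrowing_survival": self.baseline_farrowing_survival,
            "baseline_lactation_survival": self.baseline_lactation_survival,
            "trait_heritability": self.trait_heritability,
            "p_stillborn_given_homozygote": self.p_stillborn_given_homozygote or 0.0,
            "p_death_48h_given_homozygote": self.p_death_48h_given_homozygote or 0.0,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if (self.p_stillborn_given_homozygote or 0) + (self.p_death_48h_given_homozygote or 0) > 1 + 1e-9:
            raise ValueError("homozygote fate probabilities exceed 1")
        if self.litter_size_mean <= 0:
            raise ValueError("litter_size_mean must be positive")
        if not 1 <= self.lethal_chromosome <= self.n_chromosomes:
            raise ValueError("lethal_chromosome out of range")
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need at least 2 founders and 1 generation")


@dataclass
class SyntheticDataset:
    panel: PhasedPanel
    pedigree: pd.DataFrame  # animal, sire, dam ('' unknown), generation, sex
    litters: list[LitterRecord]
    truth: pd.DataFrame  # animal, dosage, weaned
    lethal_chromosome: str
    lethal_position_bp: int
    wgs_animals: list[str]
    wgs_variants: list[VariantRecord]
    trait_records: pd.DataFrame  # animal, debv, reliability, weight
    validation_litter_ids: list[str]
    config: SimulationConfig


def expected_cxc_litter_fraction(carrier_freq: float) -> float:
    """Random-mating expectation of carrier-by-carrier litters: freq squared."""
    if not 0.0 <= carrier_freq <= 1.0:
        raise ValueError("carrier frequency must lie in [0, 1]")
    return carrier_freq * carrier_freq


def simulate_population(config: SimulationConfig) -> SyntheticDataset:
    """Run the gene drop; the seed fully determines the output."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)

    # --- genome map: evenly spaced markers plus a hidden lethal pseudo-marker
    m_per = cfg.markers_per_chromosome
    spacing = cfg.chromosome_length_cM / m_per
    chrom_labels = [str(c + 1) for c in range(cfg.n_chromosomes)]
    chroms: list[str] = []
    cm: list[float] = []
    is_panel: list[bool] = []
    for c, label in enumerate(chrom_labels):
        positions = [spacing * (j + 0.5) for j in range(m_per)]
        if label == str(cfg.lethal_chromosome):
            positions = sorted(set(positions) | {cfg.lethal_position_cM})
        for p in positions:
            chroms.append(label)
            cm.append(p)
            is_panel.append(not (label == str(cfg.lethal_chromosome)
                                 and p == cfg.lethal_position_cM))
    chrom_arr = np.array(chroms, dtype=object)
    cm_arr = np.array(cm)
    panel_mask = np.array(is_panel)
    lethal_col = int(np.flatnonzero(~panel_mask)[0])
    n_mark = len(cm_arr)
    bp_arr = np.round(cm_arr * 1e6).astype(np.int64)

    # per-interval recombination probabilities (0.5 at chromosome starts)
    recomb = np.empty(n_mark)
    recomb[0] = 0.5
    d_morgan = np.diff(cm_arr) / 100.0
    recomb[1:] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    recomb[1:][chrom_arr[1:] != chrom_arr[:-1]] = 0.5

    # --- founder haplotypes
    nf = cfg.n_founders
    marker_freq = rng.uniform(0.05, 0.95, n_mark)
    hap = (rng.random((2 * nf, n_mark)) < marker_freq).astype(np.int8)
    hap[:, lethal_col] = 0
    carrier_haps = np.flatnonzero(rng.random(2 * nf) < cfg.lethal_allele_freq)
    # founders are survivors: a homozygous-lethal founder is impossible, so
    # keep at most one carrier haplotype per founder
    seen: set[int] = set()
    kept = [h for h in carrier_haps if not (h // 2 in seen or seen.add(h // 2))]
    carrier_haps = np.array(kept, dtype=np.int64)
    if cfg.lethal_allele_freq > 0 and len(carrier_haps) == 0:
        raise ValueError(
            "no founder haplotype carries the lethal allele; increase "
            "n_founders or lethal_allele_freq")
    core_cols = np.flatnonzero(
        (chrom_arr == str(cfg.lethal_chromosome))
        & (np.abs(cm_arr - cfg.lethal_position_cM) <= cfg.core_haplotype_halfwidth_cM))
    core_pattern = rng.integers(0, 2, len(core_cols)).astype(np.int8)
    hap[np.ix_(carrier_haps, core_cols)] = core_pattern
    hap[carrier_haps, lethal_col] = 1

    sigma_a = np.sqrt(cfg.trait_heritability)
    sigma_e = np.sqrt(1.0 - cfg.trait_heritability)

    # --- per-animal bookkeeping (index 0..n-1 in birth order)
    ids: list[str] = []
    sire_of: list[int] = []
    dam_of: list[int] = []
    generation: list[int] = []
    sexes: list[int] = []
    dosages: list[int] = []
    fates: list[str] = []
    ages: list[float] = []
    polygenic: list[float] = []
    hap_row: list[int] = []  # row of first haplotype in the store, -1 if not kept
    hap_store: list[np.ndarray] = []

    def add_animal(sire: int, dam: int, gen: int, sex: int, dosage: int,
                   fate: str, age: float, a_val: float,
                   haplotypes: np.ndarray | None) -> int:
        i = len(ids)
        ids.append(f"A{i + 1}")
        sire_of.append(sire)
        dam_of.append(dam)
        generation.append(gen)
        sexes.append(sex)
        dosages.append(dosage)
        fates.append(fate)
        ages.append(age)
        polygenic.append(a_val)
        if haplotypes is not None:
            hap_row.append(2 * (len(hap_store) // 2))
            hap_store.append(haplotypes[0])
            hap_store.append(haplotypes[1])
        else:
            hap_row.append(-1)
        return i

    founder_sex = rng.integers(0, 2, nf)
    founder_a = rng.normal(0.0, sigma_a, nf)
    for i in range(nf):
        add_animal(-1, -1, 0, int(founder_sex[i]), int(hap[2 * i, lethal_col]
                                                       + hap[2 * i + 1, lethal_col]),
                   FATE_WEANED, np.nan, float(founder_a[i]),
                   (hap[2 * i], hap[2 * i + 1]))

    litters: list[LitterRecord] = []
    current_gen = list(range(nf))

    for gen in range(1, cfg.n_generations + 1):
        females = [i for i in current_gen if sexes[i] == 1]
        males = [i for i in current_gen if sexes[i] == 0]
        if not females or not males:
            raise ValueError(f"generation {gen - 1} lacks one sex; enlarge the population")
        n_litters = len(females)
        if cfg.litters_per_generation is not None:
            n_litters = min(n_litters, cfg.litters_per_generation)
        dams = rng.choice(females, size=n_litters, replace=False)
        n_sires = max(1, int(round(n_litters * cfg.sire_dam_ratio)))
        sire_pool = rng.choice(males, size=min(n_sires, len(males)), replace=False)
        sires = rng.choice(sire_pool, size=n_litters)
        sizes = np.maximum(1, rng.poisson(cfg.litter_size_mean, n_litters))
        litter_of = np.repeat(np.arange(n_litters), sizes)
        n_pig = int(sizes.sum())

        sire_rows = np.array([hap_row[s] for s in sires])[litter_of]
        dam_rows = np.array([hap_row[d] for d in dams])[litter_of]
        gam_s = _gametes(np.vstack(hap_store), sire_rows, recomb, rng)
        gam_d = _gametes(np.vstack(hap_store), dam_rows, recomb, rng)

        dosage = gam_s[:, lethal_col].astype(int) + gam_d[:, lethal_col].astype(int)
        sex = rng.integers(0, 2, n_pig)
        a_mid = 0.5 * (np.array([polygenic[s] for s in sires])[litter_of]
                       + np.array([polygenic[d] for d in dams])[litter_of])
        a_val = a_mid + rng.normal(0.0, np.sqrt(0.5) * sigma_a, n_pig)

        u = rng.random(n_pig)
        u_age = rng.random(n_pig)
        fate = np.full(n_pig, FATE_WEANED, dtype=object)
        age = np.full(n_pig, np.nan)
        hom = dosage == 2
        p_sb, p_d48 = cfg.p_stillborn_given_homozygote, cfg.p_death_48h_given_homozygote
        fate[hom & (u < p_sb)] = FATE_STILLBORN
        die48 = hom & (u >= p_sb) & (u < p_sb + p_d48)
        fate[die48] = FATE_DIED
        # truncated exponential death age (most homozygote deaths inside 24 h)
        scale = 8.0
        age[die48] = -scale * np.log1p(-u_age[die48] * (1.0 - np.exp(-48.0 / scale)))
        normal = ~hom | (hom & (u >= p_sb + p_d48))
        u2 = rng.random(n_pig)
        sb = normal & (u2 < 1.0 - cfg.baseline_farrowing_survival)
        fate[sb] = FATE_STILLBORN
        lact_death = normal & ~sb & (u2 < (1.0 - cfg.baseline_farrowing_survival)
                                     + cfg.baseline_farrowing_survival
                                     * (1.0 - cfg.baseline_lactation_survival))
        fate[lact_death] = FATE_DIED
        age[lact_death] = u_age[lact_death] * WEANING_HOURS

        next_gen: list[int] = []
        pig_idx: list[int] = []
        for k in range(n_pig):
            keep = fate[k] == FATE_WEANED
            idx = add_animal(int(sires[litter_of[k]]), int(dams[litter_of[k]]), gen,
                             int(sex[k]), int(dosage[k]), str(fate[k]),
                             float(age[k]), float(a_val[k]),
                             (gam_s[k], gam_d[k]) if keep else None)
            pig_idx.append(idx)
            if keep:
                next_gen.append(idx)

        start = 0
        for li in range(n_litters):
            members = pig_idx[start:start + sizes[li]]
            start += sizes[li]
            piglets = [Piglet(ids[i], fates[i],
                              None if np.isnan(ages[i]) else float(ages[i]), None)
                       for i in members]
            n_sb = sum(1 for i in members if fates[i] == FATE_STILLBORN)
            litters.append(LitterRecord(
                litter_id=f"L{gen}_{li + 1}",
                sire=ids[sires[li]], dam=ids[dams[li]],
                total_born=len(members), live_born=len(members) - n_sb,
                stillborn=n_sb, mummified=0, piglets=piglets))
            # remember member indices for validation genotyping
            litters[-1]._member_indices = members  # type: ignore[attr-defined]
        current_gen = next_gen

    # --- validation litters: CxC litters in the final generation, fully genotyped
    validation_ids: list[str] = []
    cxc = [l for l in litters
           if l.litter_id.startswith(f"L{cfg.n_generations}_")
           and dosages[int(l.sire[1:]) - 1] >= 1 and dosages[int(l.dam[1:]) - 1] >= 1]
    for l in cxc[:cfg.n_validation_litters]:
        validation_ids.append(l.litter_id)
        for p, i in zip(l.piglets, l._member_indices):  # type: ignore[attr-defined]
            p.genotype = dosages[i]

    # --- panel of weaned (genotyped) animals
    stored = [i for i in range(len(ids)) if hap_row[i] >= 0]
    store = np.vstack(hap_store)
    panel_cols = np.flatnonzero(panel_mask)
    marker_ids = np.array([f"M{c}_{j}" for c, j in zip(chrom_arr[panel_cols],
                                                       bp_arr[panel_cols])], dtype=object)
    markers = MarkerMap(marker_ids, chrom_arr[panel_cols], bp_arr[panel_cols])
    rows = np.concatenate([[hap_row[i], hap_row[i] + 1] for i in stored])
    panel = PhasedPanel(markers, [ids[i] for i in stored],
                        store[np.ix_(rows, panel_cols)], phased=True)

    pedigree = pd.DataFrame({
        "animal": ids,
        "sire": [ids[s] if s >= 0 else "" for s in sire_of],
        "dam": [ids[d] if d >= 0 else "" for d in dam_of],
        "generation": generation,
        "sex": ["M" if s == 0 else "F" for s in sexes],
    })
    truth = pd.DataFrame({
        "animal": ids,
        "dosage": dosages,
        "weaned": [r >= 0 for r in hap_row],
    })

    # --- trait records for panel animals
    n_panel = len(stored)
    weight = rng.uniform(0.5, 2.0, n_panel)
    reliability = rng.uniform(0.15, 0.95, n_panel)
    resid = rng.normal(0.0, 1.0, n_panel) * sigma_e / np.sqrt(weight)
    debv = (cfg.carrier_effect_on_trait * np.array([dosages[i] for i in stored])
            + np.array([polygenic[i] for i in stored]) + resid)
    trait_records = pd.DataFrame({
        "animal": [ids[i] for i in stored],
        "debv": debv,
        "reliability": reliability,
        "weight": weight,
    })

    # --- sequenced subset with an LD neighborhood around the lethal locus
    wgs_animals, wgs_variants = _build_wgs_subset(
        cfg, rng, stored, ids, store, hap_row, lethal_col,
        str(cfg.lethal_chromosome), int(np.round(cfg.lethal_position_cM * 1e6)))

    for l in litters:  # drop the private helper attribute
        if hasattr(l, "_member_indices"):
            del l._member_indices

    return SyntheticDataset(
        panel=panel, pedigree=pedigree, litters=litters, truth=truth,
        lethal_chromosome=str(cfg.lethal_chromosome),
        lethal_position_bp=int(np.round(cfg.lethal_position_cM * 1e6)),
        wgs_animals=wgs_animals, wgs_variants=wgs_variants,
        trait_records=trait_records, validation_litter_ids=validation_ids,
        config=cfg)


def _gametes(store: np.ndarray, row_starts: np.ndarray, recomb: np.ndarray,
             rng: np.random.Generator, chunk: int = 4096) -> np.ndarray:
    """One recombinant gamete per parent row pair, vectorized and chunked."""
    n, m = len(row_starts), store.shape[1]
    out = np.empty((n, m), dtype=np.int8)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        rows = row_starts[lo:hi]
        switches = rng.random((hi - lo, m)) < recomb
        source = np.bitwise_xor.accumulate(switches, axis=1)
        hap_a = store[rows]
        hap_b = store[rows + 1]
        out[lo:hi] = np.where(source, hap_b, hap_a)
    return out


def _build_wgs_subset(cfg: SimulationConfig, rng: np.random.Generator,
                      stored: list[int], ids: list[str], store: np.ndarray,
                      hap_row: list[int], lethal_col: int,
                      chrom: str, lethal_bp: int
                      ) -> tuple[list[str], list[VariantRecord]]:
    carriers = [i for i in stored if store[hap_row[i], lethal_col]
                + store[hap_row[i] + 1, lethal_col] == 1]
    carrier_set = set(carriers)
    noncarriers = [i for i in stored if i not in carrier_set]
    n_car = min(cfg.n_sequenced_carriers, len(carriers))
    if n_car < cfg.n_sequenced_carriers:
        warnings.warn(f"only {n_car} carriers available for sequencing")
    seq = list(rng.choice(carriers, n_car, replace=False)) if n_car else []
    n_rest = min(cfg.n_sequenced - n_car, len(noncarriers))
    seq += list(rng.choice(noncarriers, n_rest, replace=False))
    seq_ids = [ids[i] for i in seq]
    # lethal indicator per sequenced haplotype
    hap_lethal = np.array([[store[hap_row[i], lethal_col],
                            store[hap_row[i] + 1, lethal_col]] for i in seq], dtype=np.int8)

    nv = cfg.n_wgs_variants
    offsets = np.sort(np.concatenate([
        rng.integers(-1_500_000, 0, nv // 2),
        rng.integers(1, 1_500_000, nv - nv // 2 - 1)]))
    n_hap = hap_lethal.size

    variants: list[VariantRecord] = []
    kinds = rng.random(nv - 1)
    graded_scores = iter([0.19, 0.27, 0.45])
    special = {"splice": None, "missense": []}
    for k, off in enumerate(offsets):
        if kinds[k] < 0.40:  # perfect LD with the lethal haplotype
            alleles = hap_lethal.ravel().copy()
            conc = 1.0
        elif kinds[k] < 0.80:  # graded high LD
            conc = rng.uniform(0.90, 0.995)
            noise = rng.random(n_hap)
            alleles = np.where(noise < conc, hap_lethal.ravel(),
                               (rng.random(n_hap) < 0.05).astype(np.int8))
        else:  # background, unlinked
            alleles = (rng.random(n_hap) < rng.uniform(0.05, 0.5)).astype(np.int8)
            conc = 0.0
        dosage = alleles.reshape(-1, 2).sum(axis=1)
        v = VariantRecord(
            chromosome=chrom, position=int(lethal_bp + off),
            ref="A", alt="G",
            dosages={a: int(d) for a, d in zip(seq_ids, dosage)})
        if 0.0 < conc < 1.0:
            if special["splice"] is None:
                special["splice"] = v
            elif len(special["missense"]) < 3:
                special["missense"].append(v)
        variants.append(v)
    if special["splice"] is not None:
        special["splice"].consequence = "splice_acceptor"
    for v in special["missense"]:
        v.consequence = "missense"
        v.score = next(graded_scores)

    causal = VariantRecord(
        chromosome=chrom, position=lethal_bp,
        ref="A" + CAUSAL_DELETED_SEQUENCE, alt="A",
        dosages={ids[i]: int(store[hap_row[i], lethal_col]
                             + store[hap_row[i] + 1, lethal_col]) for i in seq},
        variant_id=format_hgvs_del(chrom, lethal_bp + 1, CAUSAL_DELETED_SEQUENCE),
        consequence="frameshift")
    variants.append(causal)
    variants.sort(key=lambda v: v.position)
    return seq_ids, variants


def validation_litter_genotypes(dataset: SyntheticDataset) -> list[LitterGenotypes]:
    """Genotyped-litter records for the flagged validation litters."""
    out = []
    for l in dataset.litters:
        if l.litter_id not in dataset.validation_litter_ids:
            continue
        piglets = [PigletGenotype(p.genotype, p.fate, p.age_hours)
                   for p in l.piglets if p.genotype is not None]
        out.append(LitterGenotypes(
            litter_id=l.litter_id,
            n_wildtype=sum(1 for p in piglets if p.genotype == 0),
            n_carrier=sum(1 for p in piglets if p.genotype == 1),
            n_homozygote=sum(1 for p in piglets if p.genotype == 2),
            piglets=piglets))
    return out


# ---------------------------------------------------------------------------
# synthetic stand-in transcript for the frameshift worked example


def synthetic_sptbn4_like_model() -> tuple[CdsModel, str]:
    """Synthetic transcript model mirroring the published SPTBN4 geometry.

    This is a constructed stand-in, not the real Ensembl transcript: a
    single-exon plus-strand CDS encoding a 2563-residue protein in which
    deleting the 16-bp run ``GACGGTGTACGCCGGT`` at genomic position
    48,801,280 shifts the frame at codon 1902, so translation of the
    mutant yields the documented geometry (shared prefix 1901, a run of
    novel residues, then a premature stop, truncating the C-terminal 662
    wild-type residues).  Deterministically generated; returns the model
    and the HGVS-style deletion identifier.
    """
    rng = np.random.default_rng(48801280)
    protein_len = 2563
    stops = {"TAA", "TAG", "TGA"}
    bases = "ACGT"
    codons = [a + b + c for a in bases for b in bases for c in bases if a + b + c not in stops]
    seq = ["ATG"] + [codons[i] for i in rng.integers(0, len(codons), protein_len - 1)]
    cds = list("".join(seq) + "TAA")

    del_start = 3 * 1901  # 0-based CDS offset of codon 1902
    cds[del_start:del_start + 16] = list(CAUSAL_DELETED_SEQUENCE)

    # resample the window downstream of the deletion until the shifted frame
    # reads exactly 30 novel codons then a stop, while the wild-type frame
    # stays stop-free
    win_lo, win_hi = del_start + 16, del_start + 16 + 95  # 5719 .. 5814
    for _ in range(200_000):
        window = [bases[i] for i in rng.integers(0, 4, win_hi - win_lo)]
        trial = cds[:win_lo] + window + cds[win_hi:]
        text = "".join(trial)
        ok = True
        for s in range(del_start + 15, win_hi, 3):  # wild-type frame codons
            if text[s:s + 3] in stops:
                ok = False
                break
        if ok:
            shifted = [text[win_lo + 3 * k: win_lo + 3 * k + 3] for k in range(31)]
            ok = (all(c not in stops for c in shifted[:30])
                  and shifted[30] in stops
                  and _aa(text[win_lo:win_lo + 3]) != _aa(text[del_start:del_start + 3]))
        if ok:
            cds = trial
            break
    else:  # pragma: no cover - the search space makes failure implausible
        raise RuntimeError("could not construct the synthetic transcript")

    text = "".join(cds)
    genomic_pos = 48_801_280
    exon_start = genomic_pos - del_start
    model = CdsModel(
        transcript_id="SYNTHETIC-SPTBN4-LIKE",
        cds=text,
        exons=[(exon_start, exon_start + len(text) - 1)],
        strand="+",
        trailing="".join(bases[i] for i in rng.integers(0, 4, 60)))
    return model, format_hgvs_del("6", genomic_pos, CAUSAL_DELETED_SEQUENCE)


def _aa(codon: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(codon).translate())
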