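"""Phased SNP-panel input/output and genotype quality control.

The central container is :class:`PhasedPanel`: a marker map plus a
``(2 * n_animals, n_markers)`` matrix of haplotype alleles coded 0/1
(``-1`` = missing, allowed only on unphased panels).  Panels are read from
PLINK text ``.ped``/``.map`` pairs or from VCF (``|``-separated genotypes
are treated as phased), and quality control applies the standard
array-genotype filters: per-sample missingness, marker call rate, minor
allele frequency, a Hardy-Weinberg exact test, and removal of markers with
unknown map position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

MISSING = -1


class PanelFormatError(ValueError):
    """Raised when an input file does not parse under the named format."""


@dataclass
class MarkerMap:
    """Marker identifiers and 1-based genomic coordinates.

    ``position <= 0`` encodes an unknown map location (such markers are
    representable so that QC can count and remove them).
    """

    ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not (len(self.ids) == len(self.chromosomes) == len(self.positions)):
            raise ValueError("marker map columns have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate marker ids in map")
        # known positions must be strictly increasing within a chromosome
        for chrom in dict.fromkeys(self.chromosomes):
            pos = self.positions[(self.chromosomes == chrom) & (self.positions > 0)]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.ids[idx], self.chromosomes[idx], self.positions[idx])


@dataclass
class PhasedPanel:
    """Marker map plus per-animal haplotype allele matrix.

    Row ``2*i`` and ``2*i + 1`` of ``alleles`` are the two haplotypes of
    ``animals[i]``.  ``phased`` is True only when every genotype in the
    source was phased and no allele is missing.
    """

    markers: MarkerMap
    animals: list[str]
    alleles: np.ndarray
    phased: bool
    skipped_records: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.animals), len(self.markers)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.animals)} animals x {len(self.markers)} markers"
            )
        if self.phased and np.any(self.alleles == MISSING):
            raise ValueError("phased panel may not contain missing alleles")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_missing_fraction(self) -> np.ndarray:
        """Fraction of missing alleles per animal (over both haplotypes)."""
        miss = (self.alleles == MISSING).reshape(self.n_animals, 2, self.n_markers)
        return miss.mean(axis=(1, 2))

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-marker (hom-ref, het, hom-alt) counts over fully called animals."""
        a = self.alleles.reshape(self.n_animals, 2, self.n_markers)
        called = np.all(a != MISSING, axis=1)
        dose = np.where(called, a.sum(axis=1), 0)
        n_hom_ref = ((dose == 0) & called).sum(axis=0)
        n_het = ((dose == 1) & called).sum(axis=0)
        n_hom_alt = ((dose == 2) & called).sum(axis=0)
        return n_hom_ref, n_het, n_hom_alt

    def subset(self, animal_idx: np.ndarray | None = None,
               marker_idx: np.ndarray | None = None) -> "PhasedPanel":
        animal_idx = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        marker_idx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        rows = np.repeat(animal_idx * 2, 2) + np.tile([0, 1], len(animal_idx))
        return PhasedPanel(
            markers=self.markers.subset(marker_idx),
            animals=[self.animals[i] for i in animal_idx],
            alleles=self.alleles[np.ix_(rows, marker_idx)],
            phased=self.phased,
        )


@dataclass
class QcReport:
    """Tally of animals/markers removed by each filter, in filter order.

    A marker is counted once, in the first filter that removes it
    (position -> call rate -> MAF -> HWE).
    """

    n_animals_removed: int
    n_markers_removed_position: int
    n_markers_removed_callrate: int
    n_markers_removed_maf: int
    n_markers_removed_hwe: int
    n_markers_kept: int

    @property
    def n_markers_input(self) -> int:
        return (self.n_markers_kept + self.n_markers_removed_position
                + self.n_markers_removed_callrate + self.n_markers_removed_maf
                + self.n_markers_removed_hwe)


# ---------------------------------------------------------------------------
# readers / writers


def read_panel(path: str, format: str) -> PhasedPanel:
    """Read a panel from ``ped_map`` (PLINK text) or ``vcf``.

    For ``ped_map``, ``path`` may be the ``.ped`` file or the common prefix.
    Multi-allelic VCF records are skipped and tallied in
    ``panel.skipped_records``.
    """
    if format == "ped_map":
        return _read_ped_map(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown panel format: {format!r}")


def _read_ped_map(path: str) -> PhasedPanel:
    prefix = path[:-4] if path.endswith((".ped", ".map")) else path
    ped_path, map_path = prefix + ".ped", prefix + ".map"
    ids, chroms, poss = [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise PanelFormatError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chroms.append(parts[0])
            ids.append(parts[1])
            try:
                poss.append(int(parts[3]))
            except ValueError as exc:
                raise PanelFormatError(f"{map_path}:{ln}: bad position {parts[3]!r}") from exc
    markers = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                        np.array(poss, dtype=np.int64))
    m = len(markers)

    animals: list[str] = []
    rows: list[np.ndarray] = []
    # first-seen allele letter per marker maps to 0, second-seen to 1
    allele_key: list[dict[str, int]] = [dict() for _ in range(m)]
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise PanelFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} columns, got {len(parts)}")
            animals.append(parts[1])
            h1 = np.full(m, MISSING, dtype=np.int8)
            h2 = np.full(m, MISSING, dtype=np.int8)
            for j in range(m):
                for hap, tok in ((h1, parts[6 + 2 * j]), (h2, parts[7 + 2 * j])):
                    if tok == "0":
                        continue
                    key = allele_key[j]
                    if tok not in key:
                        if len(key) >= 2:
                            raise PanelFormatError(
                                f"{ped_path}:{ln}: marker {markers.ids[j]} has >2 alleles")
                        key[tok] = len(key)
                    hap[j] = key[tok]
            rows.extend((h1, h2))
    alleles = np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    return PhasedPanel(markers, animals, alleles, phased=False)


def _read_vcf(path: str) -> PhasedPanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    animals = list(vcf.samples)
    ids, chroms, poss = [], [], []
    cols: list[np.ndarray] = []
    skipped: list[tuple[int, str]] = []
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped.append((rec.POS, f"multi-allelic ({rec.REF}->{','.join(rec.ALT)})"))
            continue
        gts = rec.genotypes  # [a0, a1, phased] per sample
        col = np.full(2 * len(animals), MISSING, dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) != 3:
                raise PanelFormatError(
                    f"{path}: mixed ploidy at {rec.CHROM}:{rec.POS} sample {animals[i]}")
            a0, a1, phased = gt
            if a0 >= 0:
                col[2 * i] = a0
            if a1 >= 0:
                col[2 * i + 1] = a1
            if not phased:
                all_phased = False
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        cols.append(col)
    markers = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                        np.array(poss, dtype=np.int64))
    alleles = (np.column_stack(cols) if cols
               else np.empty((2 * len(animals), 0), dtype=np.int8))
    phased = all_phased and not np.any(alleles == MISSING)
    panel = PhasedPanel(markers, animals, alleles, phased=phased)
    panel.skipped_records = skipped
    return panel


def write_panel(panel: PhasedPanel, path: str, format: str) -> None:
    """Write a panel as PLINK text (``ped_map``) or VCF."""
    if format == "ped_map":
        _write_ped_map(panel, path)
    elif format == "vcf":
        _write_vcf(panel, path)
    else:
        raise ValueError(f"unknown panel format: {format!r}")


def _write_ped_map(panel: PhasedPanel, path: str) -> None:
    prefix = path[:-4] if path.endswith((".ped", ".map")) else path
    with open(prefix + ".map", "w") as fh:
        for i in range(panel.n_markers):
            fh.write(f"{panel.markers.chromosomes[i]}\t{panel.markers.ids[i]}\t0\t"
                     f"{panel.markers.positions[i]}\n")
    code = {0: "A", 1: "B", MISSING: "0"}
    with open(prefix + ".ped", "w") as fh:
        for i, animal in enumerate(panel.animals):
            toks = ["FAM", animal, "0", "0", "0", "-9"]
            h1, h2 = panel.alleles[2 * i], panel.alleles[2 * i + 1]
            for j in range(panel.n_markers):
                toks.append(code[int(h1[j])])
                toks.append(code[int(h2[j])])
            fh.write(" ".join(toks) + "\n")


def _write_vcf(panel: PhasedPanel, path: str) -> None:
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.markers.chromosomes):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.animals) + "\n")
        for j in range(panel.n_markers):
            gts = []
            for i in range(panel.n_animals):
                a0, a1 = panel.alleles[2 * i, j], panel.alleles[2 * i + 1, j]
                gts.append(f"{'.' if a0 == MISSING else a0}{sep}{'.' if a1 == MISSING else a1}")
            fh.write(f"{panel.markers.chromosomes[j]}\t{panel.markers.positions[j]}\t"
                     f"{panel.markers.ids[j]}\tA\tB\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums, over every
    heterozygote count of matching parity, the probabilities of all
    configurations whose conditional probability does not exceed that of
    the observed configuration (probability-mass ordering; no mid-p).
    Computed with log-gamma weights so it is stable for large samples.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # heterozygote counts with the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_hom_rare = (n_rare - hets) // 2
    n_hom_common = n - hets - n_hom_rare
    logw = (gammaln(n + 1) - gammaln(hets + 1) - gammaln(n_hom_rare + 1)
            - gammaln(n_hom_common + 1) + hets * np.log(2.0))
    logw -= logsumexp(logw)
    obs = logw[hets == n_het][0]
    p = float(np.exp(logw[logw <= obs + 1e-10]).sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# quality control


def apply_qc(panel: PhasedPanel,
             max_sample_missing: float = 0.15,
             min_call_rate: float = 0.85,
             min_maf: float = 0.01,
             hwe_min_p: float = 1e-12) -> tuple[PhasedPanel, QcReport]:
    """Apply sample and marker filters, in a fixed deterministic order.

    Animals whose missing-genotype fraction exceeds ``max_sample_missing``
    are removed first.  Markers are then removed, each counted in the first
    failing filter: unknown map position, call rate below ``min_call_rate``,
    minor allele frequency at or below ``min_maf`` (the MAF criterion is
    strictly greater-than), and HWE exact-test P below ``hwe_min_p``.
    """
    if panel.n_animals == 0 or panel.n_markers == 0:
        raise ValueError("empty panel")

    keep_animals = np.flatnonzero(panel.sample_missing_fraction() <= max_sample_missing)
    n_animals_removed = panel.n_animals - len(keep_animals)
    if len(keep_animals) == 0:
        raise ValueError("all animals removed by missingness filter; panel unusable")
    panel = panel.subset(animal_idx=keep_animals)

    m = panel.n_markers
    removed = np.zeros(m, dtype=np.int8)  # 0 kept, 1 pos, 2 callrate, 3 maf, 4 hwe

    removed[panel.markers.positions <= 0] = 1

    a = panel.alleles.reshape(panel.n_animals, 2, m)
    called = np.all(a != MISSING, axis=1)
    call_rate = called.mean(axis=0)
    removed[(removed == 0) & (call_rate < min_call_rate)] = 2

    alt = np.where(a == MISSING, 0, a).sum(axis=(0, 1))
    n_alleles_obs = (a != MISSING).sum(axis=(0, 1))
    alt_freq = np.divide(alt, n_alleles_obs, out=np.zeros(m), where=n_alleles_obs > 0)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    removed[(removed == 0) & (maf <= min_maf)] = 3

    n_hom_ref, n_het, n_hom_alt = panel.genotype_counts()
    for j in np.flatnonzero(removed == 0):
        total = n_hom_ref[j] + n_het[j] + n_hom_alt[j]
        if total >= 1 and hwe_exact_test(n_hom_ref[j], n_het[j], n_hom_alt[j]) < hwe_min_p:
            removed[j] = 4

    keep = np.flatnonzero(removed == 0)
    if len(keep) == 0:
        raise ValueError("all markers removed by QC; panel unusable")
    report = QcReport(
        n_animals_removed=n_animals_removed,
        n_markers_removed_position=int((removed == 1).sum()),
        n_markers_removed_callrate=int((removed == 2).sum()),
        n_markers_removed_maf=int((removed == 3).sum()),
        n_markers_removed_hwe=int((removed == 4).sum()),
        n_markers_kept=len(keep),
    )
    return panel.subset(marker_idx=keep), report
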