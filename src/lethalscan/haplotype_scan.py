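"""Sliding-window haplotype scan for a deficit of homozygotes.

A recessive lethal haplotype reveals itself on phased array data as a
haplotype whose homozygote count falls far below the Hardy-Weinberg
expectation ``N * f**2``.  The scan slides fixed-size marker windows along
each chromosome, estimates haplotype frequencies from the ``2N`` phased
haplotypes, and applies a lower-tail exact binomial test to every
haplotype common enough to have power (``expected_hom >= min_expected_hom``).
Overlapping significant windows carrying the same haplotype lineage are
merged into regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .genotype_io import MISSING, PhasedPanel


@dataclass
class HaplotypeWindow:
    chromosome: str
    first_index: int
    last_index: int
    first_pos: int
    last_pos: int
    alleles: str  # over {0,1}, one character per window marker

    @property
    def n_markers(self) -> int:
        return self.last_index - self.first_index + 1

    def __post_init__(self) -> None:
        if len(self.alleles) != self.n_markers:
            raise ValueError("haplotype allele string does not span the window")
        if set(self.alleles) - {"0", "1"}:
            raise ValueError("haplotype alleles must be 0/1")


@dataclass
class DepletionResult:
    window: HaplotypeWindow
    n_diplotypes: int
    hap_freq: float
    expected_hom: float
    observed_hom: int
    p_value: float
    significant: bool
    p_bonferroni: float = 1.0


@dataclass
class CarrierStatus:
    """Dosage in {0,1,2} of a focal window haplotype, per animal."""

    dosage: dict[str, int]

    @property
    def carrier_fraction(self) -> float:
        if not self.dosage:
            return 0.0
        return sum(1 for d in self.dosage.values() if d >= 1) / len(self.dosage)


@dataclass
class Region:
    """Run of merged significant windows sharing one haplotype lineage."""

    chromosome: str
    first_index: int
    last_index: int
    first_pos: int
    last_pos: int
    n_windows: int
    min_p: float
    best: DepletionResult


def depletion_test(n_diplotypes: int, hap_freq: float, observed_hom: int) -> float:
    """Lower-tail exact binomial P(X <= observed) with X ~ Bin(N, f^2).

    Summed in log space so that depletion probabilities of order 1e-30
    retain full relative accuracy.
    """
    if not 0.0 <= hap_freq <= 1.0:
        raise ValueError("haplotype frequency must lie in [0, 1]")
    if not 0 <= observed_hom <= n_diplotypes:
        raise ValueError("observed homozygotes must lie in [0, n_diplotypes]")
    if observed_hom == n_diplotypes:
        return 1.0
    q = hap_freq * hap_freq
    k = np.arange(observed_hom + 1)
    return float(np.exp(logsumexp(binom.logpmf(k, n_diplotypes, q))))


def window_haplotype_frequencies(
        panel: PhasedPanel, first_index: int, last_index: int) -> dict[str, tuple[int, float]]:
    """Count and frequency of every haplotype over an inclusive marker range."""
    _check_window(panel, first_index, last_index)
    codes, _ = _window_codes(panel, first_index, last_index)
    codes = codes[codes >= 0]
    uniq, counts = np.unique(codes, return_counts=True)
    total = counts.sum()
    w = last_index - first_index + 1
    return {_decode(c, w): (int(n), n / total) for c, n in zip(uniq, counts)}


def scan_genome(panel: PhasedPanel,
                window_markers: int = 20,
                step: int = 1,
                min_expected_hom: float = 10.0,
                p_threshold: float = 5e-3) -> list[DepletionResult]:
    """Test every sufficiently common haplotype in every sliding window.

    Returns results sorted by p-value.  ``p_bonferroni`` multiplies each
    p-value by the number of tests performed (capped at 1) for
    transparency; significance itself uses the unadjusted threshold.
    """
    if not panel.phased:
        raise ValueError("scan requires a phased panel")
    results: list[DepletionResult] = []
    chroms = list(dict.fromkeys(panel.markers.chromosomes))
    for chrom in chroms:
        idx = np.flatnonzero(panel.markers.chromosomes == chrom)
        if window_markers > len(idx):
            warnings.warn(f"chromosome {chrom}: fewer than {window_markers} markers, skipped")
            continue
        sub = panel.alleles[:, idx].astype(np.float64)
        pos = panel.markers.positions[idx]
        pow2 = 2.0 ** np.arange(window_markers)
        for s in range(0, len(idx) - window_markers + 1, step):
            win = sub[:, s:s + window_markers]
            codes = win @ pow2
            codes = codes.astype(np.int64)
            hap1, hap2 = codes[0::2], codes[1::2]
            n = len(hap1)
            uniq, counts = np.unique(codes, return_counts=True)
            freqs = counts / (2 * n)
            exp_hom = n * freqs ** 2
            for c, cnt, f, e in zip(uniq, counts, freqs, exp_hom):
                if e < min_expected_hom:
                    continue
                obs = int(np.count_nonzero((hap1 == c) & (hap2 == c)))
                p = depletion_test(n, f, obs)
                window = HaplotypeWindow(
                    chromosome=str(chrom),
                    first_index=int(idx[s]),
                    last_index=int(idx[s + window_markers - 1]),
                    first_pos=int(pos[s]),
                    last_pos=int(pos[s + window_markers - 1]),
                    alleles=_decode(int(c), window_markers),
                )
                results.append(DepletionResult(
                    window=window, n_diplotypes=n, hap_freq=float(f),
                    expected_hom=float(e), observed_hom=obs, p_value=p,
                    significant=p < p_threshold))
    if not results:
        warnings.warn("no haplotype reached the minimum expected-homozygote count")
    n_tests = max(len(results), 1)
    for r in results:
        r.p_bonferroni = min(1.0, r.p_value * n_tests)
    results.sort(key=lambda r: (r.p_value, r.window.chromosome, r.window.first_pos))
    return results


def merge_significant_regions(results: list[DepletionResult]) -> list[Region]:
    """Merge overlapping significant windows whose haplotypes agree on shared markers."""
    sig = [r for r in results if r.significant]
    regions: list[Region] = []
    by_chrom: dict[str, list[DepletionResult]] = {}
    for r in sig:
        by_chrom.setdefault(r.window.chromosome, []).append(r)
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.window.first_index)
        open_regions: list[tuple[dict[int, str], list[DepletionResult]]] = []
        for r in rs:
            alleles = {r.window.first_index + k: a for k, a in enumerate(r.window.alleles)}
            placed = False
            for lineage, members in open_regions:
                last = max(m.window.last_index for m in members)
                overlap = r.window.first_index <= last
                compatible = all(lineage.get(i, a) == a for i, a in alleles.items())
                if overlap and compatible:
                    lineage.update(alleles)
                    members.append(r)
                    placed = True
                    break
            if not placed:
                open_regions.append((dict(alleles), [r]))
        for _, members in open_regions:
            best = min(members, key=lambda m: m.p_value)
            regions.append(Region(
                chromosome=chrom,
                first_index=min(m.window.first_index for m in members),
                last_index=max(m.window.last_index for m in members),
                first_pos=min(m.window.first_pos for m in members),
                last_pos=max(m.window.last_pos for m in members),
                n_windows=len(members),
                min_p=best.p_value,
                best=best,
            ))
    regions.sort(key=lambda g: g.min_p)
    return regions


def assign_carrier_status(panel: PhasedPanel, window: HaplotypeWindow) -> CarrierStatus:
    """Dosage of the focal window haplotype for every animal.

    A haplotype with any missing allele inside the window never matches
    the focal haplotype.
    """
    codes, valid = _window_codes(panel, window.first_index, window.last_index)
    focal = sum(int(a) << k for k, a in enumerate(window.alleles))
    match = (codes == focal) & valid
    dosage = match[0::2].astype(int) + match[1::2].astype(int)
    return CarrierStatus(dosage={a: int(d) for a, d in zip(panel.animals, dosage)})


# ---------------------------------------------------------------------------


def _check_window(panel: PhasedPanel, first: int, last: int) -> None:
    if not (0 <= first <= last < panel.n_markers):
        raise ValueError("window outside marker bounds")
    chroms = panel.markers.chromosomes[first:last + 1]
    if len(set(chroms)) > 1:
        raise ValueError("window overlaps a chromosome boundary")


def _window_codes(panel: PhasedPanel, first: int, last: int) -> tuple[np.ndarray, np.ndarray]:
    win = panel.alleles[:, first:last + 1]
    valid = np.all(win != MISSING, axis=1)
    pow2 = 2 ** np.arange(last - first + 1, dtype=np.int64)
    codes = np.where(win == MISSING, 0, win).astype(np.int64) @ pow2
    codes = np.where(valid, codes, -1)
    return codes, valid


def _decode(code: int, width: int) -> str:
    return "".join(str((code >> k) & 1) for k in range(width))


def results_to_rows(results: list[DepletionResult]) -> list[dict]:
    """Flat dict rows for TSV output."""
    return [{
        "chromosome": r.window.chromosome,
        "first_pos": r.window.first_pos,
        "last_pos": r.window.last_pos,
        "n_markers": r.window.n_markers,
        "haplotype": r.window.alleles,
        "n_diplotypes": r.n_diplotypes,
        "hap_freq": r.hap_freq,
        "expected_hom": r.expected_hom,
        "observed_hom": r.observed_hom,
        "p_value": r.p_value,
        "p_bonferroni": r.p_bonferroni,
        "significant": r.significant,
    } for r in results]
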