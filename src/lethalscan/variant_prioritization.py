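"""Causal-variant prioritization from sequenced carriers.

Given a sequenced subset of animals with known haplotype dosage, each
candidate variant is scored by linkage disequilibrium (r^2 between
genotype dosages) with the lethal haplotype, filtered at a threshold,
and ranked by predicted consequence class: high-impact (frameshift,
stop-gained, splice site) first, then non-tolerated missense, tolerated
missense, and everything else.  A frameshift deletion can additionally
be pushed through a coding model to predict the mutant protein: shared
prefix, novel residues, premature stop, and lost wild-type residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .haplotype_scan import CarrierStatus

HIGH_IMPACT = {"frameshift", "stop_gained", "splice_acceptor", "splice_donor"}
CONSEQUENCE_CLASSES = HIGH_IMPACT | {"missense", "synonymous", "other"}


@dataclass
class VariantRecord:
    """One biallelic variant with per-animal genotype dosages.

    Indels carry explicit ref/alt strings so that deletion identifiers
    like ``6:g.48801280delGACGGTGTACGCCGGT`` round-trip.
    """

    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    dosages: dict[str, int]  # animal -> 0/1/2; missing animals omitted
    variant_id: str | None = None
    consequence: str | None = None
    score: float | None = None  # deleteriousness score in [0,1]; higher = tolerated

    def __post_init__(self) -> None:
        if self.consequence is not None and self.consequence not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.consequence!r}")

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref}>{self.alt}"


@dataclass
class LdResult:
    variant: VariantRecord
    r_squared: float | None  # None when either dosage vector has zero variance
    n_animals: int
    zero_variance: bool = False


@dataclass
class Candidate:
    variant: VariantRecord
    ld: LdResult
    tier: int  # 0 high-impact, 1 missense, 2 tolerated missense, 3 other
    tolerated: bool
    perfect_ld: bool


def haplotype_ld(variant: VariantRecord, carriers: CarrierStatus) -> LdResult:
    """r^2 between variant genotype dosage and haplotype dosage.

    Computed as the squared Pearson correlation over animals present in
    both inputs; undefined (None) when either vector is constant.
    """
    animals = [a for a in variant.dosages if a in carriers.dosage]
    if len(animals) < 3:
        raise ValueError("need at least 3 animals with both dosages")
    x = np.array([variant.dosages[a] for a in animals], dtype=float)
    y = np.array([carriers.dosage[a] for a in animals], dtype=float)
    if x.var() == 0 or y.var() == 0:
        return LdResult(variant, None, len(animals), zero_variance=True)
    r = np.corrcoef(x, y)[0, 1]
    return LdResult(variant, float(r * r), len(animals))


def prioritize(variants: list[VariantRecord], carriers: CarrierStatus,
               r2_threshold: float = 0.8,
               tolerated_score_above: float = 0.05) -> list[Candidate]:
    """Rank variants in high LD with the lethal haplotype.

    Variants with r^2 > ``r2_threshold`` are kept and ordered: high-impact
    consequences first, then missense not predicted tolerated
    (score <= ``tolerated_score_above``), tolerated missense, then the
    rest; ties broken by descending r^2 then position.  Variants at r^2 = 1
    (within 1e-9) are flagged as perfect LD.
    """
    candidates: list[Candidate] = []
    for v in variants:
        ld = haplotype_ld(v, carriers)
        if ld.r_squared is None or ld.r_squared <= r2_threshold:
            continue
        tolerated = (v.consequence == "missense" and v.score is not None
                     and v.score > tolerated_score_above)
        if v.consequence in HIGH_IMPACT:
            tier = 0
        elif v.consequence == "missense":
            tier = 2 if tolerated else 1
        else:
            tier = 3
        candidates.append(Candidate(
            variant=v, ld=ld, tier=tier, tolerated=tolerated,
            perfect_ld=ld.r_squared >= 1.0 - 1e-9))
    if not candidates:
        return []
    # within the high-impact tier, direct protein-truncating consequences
    # (frameshift, stop-gained) order before splice-site predictions, which
    # are the less certain annotation
    severity = {"frameshift": 0, "stop_gained": 0}
    candidates.sort(key=lambda c: (c.tier, severity.get(c.variant.consequence, 1),
                                   -c.ld.r_squared, c.variant.chromosome,
                                   c.variant.position))
    return candidates


def candidates_frame(candidates: list[Candidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "rank": i + 1,
        "variant": c.variant.variant_id or c.variant.key,
        "chromosome": c.variant.chromosome,
        "position": c.variant.position,
        "consequence": c.variant.consequence,
        "score": c.variant.score,
        "r_squared": c.ld.r_squared,
        "n_animals": c.ld.n_animals,
        "perfect_ld": c.perfect_ld,
        "tolerated": c.tolerated,
    } for i, c in enumerate(candidates)])


# ---------------------------------------------------------------------------
# HGVS-style deletion identifiers

_HGVS_DEL = re.compile(r"^(?P<chrom>[^:]+):g\.(?P<pos>\d+)(?:_(?P<end>\d+))?del(?P<seq>[ACGT]*)$")


def parse_hgvs_del(identifier: str) -> tuple[str, int, str]:
    """Parse ``chrom:g.<pos>del<SEQ>`` into (chromosome, 1-based start, deleted sequence)."""
    m = _HGVS_DEL.match(identifier.strip())
    if not m or not m.group("seq"):
        raise ValueError(f"not a genomic deletion identifier: {identifier!r}")
    return m.group("chrom"), int(m.group("pos")), m.group("seq")


def format_hgvs_del(chromosome: str, position: int, deleted: str) -> str:
    return f"{chromosome}:g.{position}del{deleted}"


# ---------------------------------------------------------------------------
# frameshift consequence prediction


@dataclass
class CdsModel:
    """Spliced coding sequence with its genomic exon intervals.

    ``exons`` are 1-based inclusive genomic (start, end) pairs in
    transcription order; for minus-strand transcripts each exon's sequence
    contributes reverse-complemented.  ``cds`` includes the stop codon;
    ``trailing`` is transcript sequence 3' of the stop, used for
    read-through when a frameshift abolishes the stop.
    """

    transcript_id: str
    cds: str
    exons: list[tuple[int, int]]
    strand: str = "+"
    trailing: str = ""

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        self.trailing = self.trailing.upper()
        if len(self.cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if not self.cds.startswith("ATG"):
            raise ValueError("CDS must start with a start codon")
        if self.cds[-3:] not in ("TAA", "TAG", "TGA"):
            raise ValueError("CDS must end with a stop codon")
        if sum(e - s + 1 for s, e in self.exons) != len(self.cds):
            raise ValueError("exon intervals do not sum to the CDS length")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())[:-1]  # strip the stop

    def genomic_to_cds(self, start: int, end: int) -> tuple[int, int]:
        """Map a genomic interval (1-based inclusive) to 0-based CDS offsets.

        The interval must fall entirely inside a single exon.
        """
        offset = 0
        for ex_start, ex_end in self.exons:
            if ex_start <= start and end <= ex_end:
                if self.strand == "+":
                    lo = offset + (start - ex_start)
                else:
                    lo = offset + (ex_end - end)
                return lo, lo + (end - start)
            offset += ex_end - ex_start + 1
        for ex_start, ex_end in self.exons:
            if start <= ex_end and end >= ex_start:
                raise ValueError("deletion spans an exon boundary: unsupported")
        raise ValueError("deletion outside the coding sequence: non-coding")


@dataclass
class FrameshiftConsequence:
    kind: str  # frameshift | inframe_deletion | no_stop_found
    shared_prefix_aa: int
    novel_aa: int
    mutant_length_aa: int
    lost_wt_aa: int
    mutant_protein: str = ""


def apply_deletion_and_translate(cds: CdsModel, deletion_start: int,
                                 deletion_end: int,
                                 deleted_sequence: str | None = None
                                 ) -> FrameshiftConsequence:
    """Predict the protein consequence of a genomic deletion inside the CDS.

    The deletion (1-based inclusive genomic interval) is mapped to CDS
    coordinates strand-aware.  In-frame deletions report ``novel_aa = 0``;
    frameshifts translate the shifted sequence (extended by the trailing
    transcript sequence) to the first stop and report the shared prefix
    with the wild type, the novel residue count, and the lost wild-type
    residues.  ``deleted_sequence``, when given (e.g. from an HGVS ``del``
    identifier), is validated against the reference CDS.
    """
    lo, hi = cds.genomic_to_cds(deletion_start, deletion_end)
    removed = cds.cds[lo:hi + 1]
    if deleted_sequence is not None:
        expected = deleted_sequence.upper()
        if cds.strand == "-":
            expected = str(Seq(expected).reverse_complement())
        if removed != expected:
            raise ValueError(
                f"deleted sequence mismatch: reference has {removed!r}, "
                f"identifier claims {expected!r}")
    wt_protein = cds.protein
    del_len = hi - lo + 1

    if del_len % 3 == 0:
        mutant = _translate_to_stop(cds.cds[:lo] + cds.cds[hi + 1:] + cds.trailing) or ""
        return FrameshiftConsequence(
            kind="inframe_deletion",
            shared_prefix_aa=_shared_prefix(wt_protein, mutant),
            novel_aa=0,
            mutant_length_aa=len(mutant),
            lost_wt_aa=del_len // 3,
            mutant_protein=mutant)

    mutant_nt = cds.cds[:lo] + cds.cds[hi + 1:] + cds.trailing
    mutant = _translate_to_stop(mutant_nt)
    if mutant is None:
        n_aa = len(mutant_nt) // 3
        prot = str(Seq(mutant_nt[:3 * n_aa]).translate())
        shared = _shared_prefix(wt_protein, prot)
        return FrameshiftConsequence(
            kind="no_stop_found", shared_prefix_aa=shared,
            novel_aa=len(prot) - shared, mutant_length_aa=len(prot),
            lost_wt_aa=len(wt_protein) - shared, mutant_protein=prot)
    shared = _shared_prefix(wt_protein, mutant)
    return FrameshiftConsequence(
        kind="frameshift",
        shared_prefix_aa=shared,
        novel_aa=len(mutant) - shared,
        mutant_length_aa=len(mutant),
        lost_wt_aa=len(wt_protein) - shared,
        mutant_protein=mutant)


def _translate_to_stop(nt: str) -> str | None:
    """Translate codon-wise until the first stop; None if no stop is reached."""
    aas = []
    for i in range(0, len(nt) - 2, 3):
        aa = str(Seq(nt[i:i + 3]).translate())
        if aa == "*":
            return "".join(aas)
        aas.append(aa)
    return None


def _shared_prefix(a: str | None, b: str | None) -> int:
    if a is None or b is None:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


# ---------------------------------------------------------------------------
# file interfaces


def read_variants_vcf(path: str) -> tuple[list[VariantRecord], list[str]]:
    """Read biallelic variants with genotype dosages from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    animals = list(vcf.samples)
    out: list[VariantRecord] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        dosages = {}
        for i, gt in enumerate(rec.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                continue
            dosages[animals[i]] = int(a0 > 0) + int(a1 > 0)
        out.append(VariantRecord(
            chromosome=rec.CHROM, position=rec.POS, ref=rec.REF, alt=rec.ALT[0],
            dosages=dosages,
            variant_id=rec.ID if rec.ID not in (None, ".") else None))
    return out, animals


ANNOTATION_COLUMNS = ["variant", "consequence", "score"]


def attach_annotations(variants: list[VariantRecord], table: pd.DataFrame) -> None:
    """Attach consequence classes/scores from a sidecar table (in place).

    The ``variant`` column may hold either the record key
    ``chrom:pos:ref>alt`` or the variant id.
    """
    by_key = {v.key: v for v in variants}
    by_id = {v.variant_id: v for v in variants if v.variant_id}
    for row in table.itertuples(index=False):
        v = by_key.get(str(row.variant)) or by_id.get(str(row.variant))
        if v is None:
            continue
        if isinstance(row.consequence, str) and row.consequence:
            v.consequence = row.consequence
        if not pd.isna(row.score):
            v.score = float(row.score)
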