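"""End-to-end orchestration: QC, scan, carriers, litters, prioritization,
segregation and association from one config, with a reproducible manifest.

Stage order mirrors the discovery workflow: genotype QC, the
deficit-of-homozygotes scan, carrier assignment from the top region,
litter contrasts, then (when their inputs are present) causal-variant
prioritization, Mendelian validation of genotyped litters, and the
carrier association on breeding values.  Missing optional inputs skip
their stages with a logged notice; outputs are deterministically sorted
and re-running the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import pandas as pd
import yaml

from . import __version__, dataset_io, genotype_io
from . import haplotype_scan as hs
from . import litter_analysis as la
from . import segregation_validation as sv
from . import variant_prioritization as vp
from . import carrier_association as ca

log = logging.getLogger("lethalscan.pipeline")


@dataclasses.dataclass
class PipelineConfig:
    panel: str
    panel_format: str = "vcf"
    pedigree: str | None = None
    litters: str | None = None
    piglets: str | None = None
    variants: str | None = None
    annotations: str | None = None
    traits: str | None = None  # csv with columns animal, debv, reliability, weight
    out_dir: str = "lethalscan_out"
    seed: int = 1
    # QC
    max_sample_missing: float = 0.15
    min_call_rate: float = 0.85
    min_maf: float = 0.01
    hwe_min_p: float = 1e-12
    # scan
    window_markers: int = 20
    step: int = 1
    min_expected_hom: float = 10.0
    p_threshold: float = 5e-3
    # prioritization
    r2_threshold: float = 0.8
    tolerated_score_above: float = 0.05
    # association
    heritability: float = 0.10

    def validate(self) -> None:
        if not os.path.exists(self.panel_path()):
            raise FileNotFoundError(f"panel not found: {self.panel}")
        for name in ("pedigree", "litters", "piglets", "variants", "annotations", "traits"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{name} file not found: {p}")

    def panel_path(self) -> str:
        if self.panel_format == "ped_map" and not self.panel.endswith(".ped"):
            return self.panel + ".ped"
        return self.panel

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns a summary dict (also written as JSON)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {}

    def out(name: str) -> str:
        return os.path.join(config.out_dir, name)

    # --- qc
    try:
        log.info("[qc] reading panel %s", config.panel)
        panel = genotype_io.read_panel(config.panel, config.panel_format)
        panel, qc = genotype_io.apply_qc(
            panel, config.max_sample_missing, config.min_call_rate,
            config.min_maf, config.hwe_min_p)
        summary["qc"] = dataclasses.asdict(qc)
    except Exception as exc:
        raise StageError("qc", exc) from exc

    # --- scan
    try:
        log.info("[scan] %d animals x %d markers", panel.n_animals, panel.n_markers)
        results = hs.scan_genome(panel, config.window_markers, config.step,
                                 config.min_expected_hom, config.p_threshold)
        _write_tsv(pd.DataFrame(hs.results_to_rows(results)), out("scan.tsv"), config)
        regions = hs.merge_significant_regions(results)
        _write_bed(regions, out("regions.bed"))
        summary["scan"] = {"n_tests": len(results),
                           "n_significant": sum(r.significant for r in results),
                           "n_regions": len(regions)}
    except Exception as exc:
        raise StageError("scan", exc) from exc

    # --- carriers from the top region's best window
    carriers = None
    if regions:
        try:
            best = regions[0].best
            carriers = hs.assign_carrier_status(panel, best.window)
            frame = pd.DataFrame(sorted(carriers.dosage.items()),
                                 columns=["animal", "dosage"])
            _write_tsv(frame, out("carriers.tsv"), config)
            summary["carriers"] = {
                "carrier_fraction": carriers.carrier_fraction,
                "region": f"{regions[0].chromosome}:{regions[0].first_pos}-{regions[0].last_pos}",
                "p_value": best.p_value,
            }
        except Exception as exc:
            raise StageError("carriers", exc) from exc
    else:
        log.info("[carriers] no significant region; downstream stages limited")

    # --- litters
    litters = None
    if config.litters and carriers is not None:
        try:
            litters = dataset_io.read_litters(config.litters, config.piglets)
            classes, excluded = la.classify_matings(litters, carriers)
            summaries = la.summarize_by_class(litters, classes)
            _write_tsv(la.summary_frame(summaries), out("litter_summary.tsv"), config)
            t, df, p = la.contrast_classes(litters, classes)
            summary["litters"] = {
                "n_classified": len(classes), "n_excluded": len(excluded),
                "welch_t": t, "welch_df": df, "welch_p": p,
                "classes": {s.mating_class: s.n_litters for s in summaries},
            }
        except Exception as exc:
            raise StageError("litters", exc) from exc
    elif config.litters is None:
        log.info("[litters] no litter file; stage skipped")

    # --- prioritize
    if config.variants and carriers is not None:
        try:
            variants, _ = vp.read_variants_vcf(config.variants)
            if config.annotations:
                vp.attach_annotations(variants, pd.read_csv(config.annotations, sep="\t"))
            candidates = vp.prioritize(variants, carriers, config.r2_threshold,
                                       config.tolerated_score_above)
            _write_tsv(vp.candidates_frame(candidates), out("candidates.tsv"), config)
            summary["prioritize"] = {
                "n_pass": len(candidates),
                "n_perfect_ld": sum(c.perfect_ld for c in candidates),
                "top": candidates[0].variant.variant_id or candidates[0].variant.key
                if candidates else None,
            }
        except Exception as exc:
            raise StageError("prioritize", exc) from exc
    elif config.variants is None:
        log.info("[prioritize] no variant file; stage skipped")

    # --- segregation of genotyped litters
    if litters is not None:
        try:
            geno = [l for l in litters if any(p.genotype is not None for p in l.piglets)]
            if geno:
                lgs = [sv.LitterGenotypes(
                    litter_id=l.litter_id,
                    n_wildtype=sum(1 for p in l.piglets if p.genotype == 0),
                    n_carrier=sum(1 for p in l.piglets if p.genotype == 1),
                    n_homozygote=sum(1 for p in l.piglets if p.genotype == 2),
                    piglets=[sv.PigletGenotype(p.genotype, p.fate, p.age_hours)
                             for p in l.piglets if p.genotype is not None])
                    for l in geno]
                wt, het, hom = sv.pool_litters(lgs)
                res = sv.segregation_test((wt, het, hom), "birth_1_2_1")
                pen = sv.penetrance_summary(lgs)
                summary["segregation"] = {
                    "counts": [wt, het, hom],
                    "chi_squared": res.chi_squared, "df": res.df,
                    "p_chi_squared": res.p_chi_squared, "p_exact": res.p_exact,
                    "penetrance": pen.penetrance,
                }
        except Exception as exc:
            raise StageError("segregation", exc) from exc

    # --- association
    if config.traits and config.pedigree and carriers is not None:
        try:
            traits = pd.read_csv(config.traits)
            ped_frame = pd.read_csv(config.pedigree)
            ped = ca.Pedigree.from_triples(
                ped_frame[["animal", "sire", "dam"]].itertuples(index=False))
            table = ca.run_association({"trait": traits}, carriers, ped,
                                       config.heritability)
            _write_tsv(table, out("association.tsv"), config)
            if len(table):
                summary["association"] = table.iloc[0].to_dict()
        except Exception as exc:
            raise StageError("association", exc) from exc
    elif config.traits is None:
        log.info("[association] no trait file; stage skipped")

    manifest = {
        "lethalscan_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "input_checksums": _checksums(config),
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(x):
    try:
        return x.item()
    except AttributeError:
        return str(x)


def _checksums(config: PipelineConfig) -> dict[str, str]:
    sums = {}
    for name in ("panel", "pedigree", "litters", "piglets", "variants",
                 "annotations", "traits"):
        path = getattr(config, name)
        if name == "panel":
            path = config.panel_path()
        if path and os.path.exists(path):
            with open(path, "rb") as fh:
                sums[name] = hashlib.sha256(fh.read()).hexdigest()
    return sums


def _write_tsv(frame: pd.DataFrame, path: str, config: PipelineConfig) -> None:
    params = dataclasses.asdict(config)
    with open(path, "w") as fh:
        fh.write("# lethalscan " + " ".join(f"{k}={v}" for k, v in sorted(params.items())
                                            if isinstance(v, (int, float))) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def _write_bed(regions, path: str) -> None:
    # BED is 0-based half-open; marker positions are 1-based
    with open(path, "w") as fh:
        for g in regions:
            fh.write(f"{g.chromosome}\t{g.first_pos - 1}\t{g.last_pos}\t"
                     f"depleted_region\t0\t.\n")
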