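"""On-disk layout for simulated datasets and pipeline inputs.

Everything is plain text: the panel as VCF or PLINK .ped/.map, tables as
CSV/TSV, the sequenced subset as a small VCF plus a consequence-annotation
sidecar TSV, and the simulation config as YAML.
"""

from __future__ import annotations

import dataclasses
import os

import pandas as pd
import yaml

from . import genotype_io, litter_analysis
from .synthetic_population import SimulationConfig, SyntheticDataset
from .variant_prioritization import ANNOTATION_COLUMNS, VariantRecord

PANEL_VCF = "panel.vcf"
PANEL_PREFIX = "panel"
PEDIGREE_CSV = "pedigree.csv"
LITTERS_CSV = "litters.csv"
PIGLETS_CSV = "piglets.csv"
TRUTH_CSV = "truth.csv"
TRAITS_CSV = "traits.csv"
WGS_VCF = "wgs.vcf"
ANNOTATIONS_TSV = "annotations.tsv"
CONFIG_YAML = "config.yaml"


def write_dataset(dataset: SyntheticDataset, outdir: str,
                  panel_format: str = "vcf") -> None:
    os.makedirs(outdir, exist_ok=True)
    if panel_format == "vcf":
        genotype_io.write_panel(dataset.panel, os.path.join(outdir, PANEL_VCF), "vcf")
    else:
        genotype_io.write_panel(dataset.panel, os.path.join(outdir, PANEL_PREFIX), "ped_map")
    dataset.pedigree.to_csv(os.path.join(outdir, PEDIGREE_CSV), index=False)
    lit, pig = litter_analysis.litters_to_frames(dataset.litters)
    lit.to_csv(os.path.join(outdir, LITTERS_CSV), index=False)
    pig.to_csv(os.path.join(outdir, PIGLETS_CSV), index=False)
    truth = dataset.truth.copy()
    truth.attrs = {}
    truth.to_csv(os.path.join(outdir, TRUTH_CSV), index=False)
    dataset.trait_records.to_csv(os.path.join(outdir, TRAITS_CSV), index=False)
    write_variants_vcf(dataset.wgs_variants, dataset.wgs_animals,
                       os.path.join(outdir, WGS_VCF))
    annotations_frame(dataset.wgs_variants).to_csv(
        os.path.join(outdir, ANNOTATIONS_TSV), sep="\t", index=False)
    cfg = dataclasses.asdict(dataset.config)
    cfg["lethal_position_bp"] = dataset.lethal_position_bp
    with open(os.path.join(outdir, CONFIG_YAML), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_variants_vcf(variants: list[VariantRecord], animals: list[str],
                       path: str) -> None:
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chromosome for v in variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(animals) + "\n")
        for v in variants:
            gts = [gt.get(v.dosages.get(a), "./.") for a in animals]
            fh.write(f"{v.chromosome}\t{v.position}\t{v.variant_id or '.'}\t"
                     f"{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def annotations_frame(variants: list[VariantRecord]) -> pd.DataFrame:
    rows = [{"variant": v.key, "consequence": v.consequence or "", "score": v.score}
            for v in variants if v.consequence is not None]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_litters(litters_csv: str, piglets_csv: str | None = None):
    lit = pd.read_csv(litters_csv)
    pig = pd.read_csv(piglets_csv) if piglets_csv and os.path.exists(piglets_csv) else None
    return litter_analysis.litters_from_frames(lit, pig)


def read_config(path: str) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    return SimulationConfig(**{k: v for k, v in data.items() if k in fields})
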