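"""On-disk dataset layout: counts TSV, metadata TSV, VCF v4.2, BED gene
map, and truth JSON, with an exact round trip.

The VCF carries one record per SNP with INFO tags GENE, FCLASS and SET
and a single GT FORMAT field; genotype dosages 0/1/2 map to 0/0, 0/1 and
1/1, missing to ./. (reading uses cyvcf2). BED spans are 0-based
half-open; VCF positions 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .popgen import MISSING, VariantTable
from .simulate import GeneratorConfig, SyntheticTruth, gene_coordinates

__all__ = ["write_dataset", "read_dataset", "write_vcf", "read_vcf"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(variants: VariantTable, path) -> None:
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={s}>" for s in
              dict.fromkeys(variants.snps["scaffold"])]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">',
        '##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">',
        '##INFO=<ID=SET,Number=1,Type=String,Description="Plasticity SNP set">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(variants.sample_ids),
    ]
    snps = variants.snps
    for i, (snp_id, row) in enumerate(snps.iterrows()):
        info = f"GENE={row['gene_id']};FCLASS={row['functional_class']};SET={row['set_label']}"
        gts = "\t".join(_GT[int(g)] for g in variants.genotypes[i])
        lines.append(
            f"{row['scaffold']}\t{int(row['pos'])}\t{snp_id}\tA\tG\t"
            f"{row['qual']:.2f}\tPASS\t{info}\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, genos = [], []
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1:
            raise ValidationError(f"non-biallelic record at {v.CHROM}:{v.POS}")
        dosage = np.empty(len(sample_ids), dtype=np.int8)
        for k, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            dosage[k] = MISSING if (a < 0 or b < 0) else a + b
        rows.append({
            "snp_id": v.ID,
            "scaffold": v.CHROM,
            "pos": int(v.POS),
            "qual": round(float(v.QUAL), 2) if v.QUAL is not None else np.nan,
            "gene_id": v.INFO.get("GENE"),
            "functional_class": v.INFO.get("FCLASS"),
            "set_label": v.INFO.get("SET"),
        })
        genos.append(dosage)
    snps = pd.DataFrame(rows).set_index("snp_id")
    return VariantTable(snps=snps, genotypes=np.vstack(genos),
                        sample_ids=sample_ids)


def write_dataset(samples: pd.DataFrame, counts: pd.DataFrame,
                  variants: VariantTable | None, truth: SyntheticTruth | None,
                  out_dir, config: GeneratorConfig | None = None) -> dict:
    """Write the full dataset; returns the mapping of table -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not counts.columns.equals(samples.index):
        raise ValidationError("counts columns must match metadata sample ids")
    paths = {}
    paths["counts"] = out / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    paths["metadata"] = out / "metadata.tsv"
    samples.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    if variants is not None:
        paths["vcf"] = out / "variants.vcf"
        write_vcf(variants, paths["vcf"])
    if truth is not None:
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    if config is not None:
        coords = gene_coordinates(config, list(counts.index))
        paths["bed"] = out / "genes.bed"
        with open(paths["bed"], "w") as fh:
            for gid, row in coords.iterrows():
                # BED is 0-based half-open
                fh.write(f"{row['scaffold']}\t{row['start'] - 1}\t{row['end']}\t{gid}\n")
    return {k: str(v) for k, v in paths.items()}


def read_dataset(out_dir) -> dict:
    """Read back everything :func:`write_dataset` wrote."""
    out = Path(out_dir)
    result: dict = {}
    result["counts"] = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
    result["samples"] = pd.read_csv(out / "metadata.tsv", sep="\t", index_col=0)
    if (out / "variants.vcf").exists():
        result["variants"] = read_vcf(out / "variants.vcf")
    if (out / "truth.json").exists():
        raw = json.loads((out / "truth.json").read_text())
        raw["class_proportions"] = {k: tuple(v)
                                    for k, v in raw["class_proportions"].items()}
        result["truth"] = SyntheticTruth(**raw)
    return result
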