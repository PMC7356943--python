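"""Readers and writers for the pipeline's tabular formats.

All tables are UTF-8 TSV with a header row; "." marks missing values.
Genotypes can also come from a VCF (biallelic sites; genotype categories
are formed from the GT field, coordinates are ignored).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .simulate import SNPSpec

__all__ = [
    "read_genotypes_tsv",
    "read_genotypes_vcf",
    "read_abundance_tsv",
    "read_cohort_tsv",
    "write_table",
    "read_snp_specs",
    "write_snp_specs",
    "write_manifest",
    "read_manifest",
]

MISSING = "."


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Subjects x SNPs genotype-string table (first column = subject id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[MISSING])
    return df


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Genotype categories from a VCF; biallelic records only.

    SNP ids come from the ID column (falling back to CHROM:POS); genotype
    strings concatenate the called alleles, e.g. REF=A, ALT=G, GT=0/1
    yields "AG".
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    data: dict[str, list] = {}
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
        alleles = (rec.ref, rec.alts[0])
        col = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt) or len(gt) != 2:
                col.append(None)
            else:
                col.append("".join(alleles[a] for a in sorted(gt)))
        data[snp_id] = col
    vcf.close()
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))


def read_abundance_tsv(path) -> pd.DataFrame:
    """Families x samples integer count matrix (header row of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype("int64", errors="ignore")


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    return df


def write_snp_specs(specs: list[SNPSpec], path) -> None:
    rows = []
    for s in specs:
        d = asdict(s)
        d["alleles"] = "/".join(s.alleles)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_snp_specs(path) -> list[SNPSpec]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "alleles": str})
    return [
        SNPSpec(
            snp_id=row.snp_id,
            alleles=tuple(row.alleles.split("/")),
            maf=float(row.maf),
            effect_model=row.effect_model,
            effect_size=float(row.effect_size),
        )
        for row in df.itertuples()
    ]


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8")


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text(encoding="utf-8"))
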