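"""Readers and writers for the pipeline's interchange formats.

Cohorts travel as long-format TSV; genotypes as uncompressed VCF with a DS
(dosage) FORMAT field and AF / IMPINFO INFO fields, or as a plain matrix
table (variants as rows, metadata columns then one column per sample).
Both genotype representations round-trip through :class:`GenotypeData`
(VCF text fields carry ~6 significant digits, so round-trips are exact to
~1e-5 relative; cohort tables round-trip bit-exactly).  Summary statistics
are written one delimited file per age with a fixed column set.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .ages import AGE_LABELS
from .assoc import AssocResult
from .cohort import Cohort
from .genotypes import GenotypeData, VARIANT_COLUMNS


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path: str, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is None:
            seed = cohort.meta.get("seed")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        cohort.to_table().to_csv(fh, sep="\t", index=False)


def read_cohort(path: str) -> Cohort:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return Cohort.from_table(df)


# ---------------------------------------------------------------------------
# Genotypes: VCF with dosages
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeData, path: str, seed: int | None = None) -> None:
    """Write dosage genotypes as an uncompressed VCF (FORMAT DS)."""
    header = pysam.VariantHeader()
    for contig in pd.unique(genotypes.variants["chrom"].astype(str)):
        header.add_line(f"##contig=<ID={contig}>")
    header.add_line(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Effect allele frequency">'
    )
    header.add_line(
        '##INFO=<ID=IMPINFO,Number=1,Type=Float,Description="Imputation info score">'
    )
    header.add_line(
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the effect allele">'
    )
    if seed is not None:
        header.add_line(f"##simulation_seed={seed}")
    for s in genotypes.sample_ids:
        header.add_sample(str(s))
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for k, rec in genotypes.variants.iterrows():
            row = vcf.new_record(
                contig=str(rec["chrom"]),
                start=int(rec["pos"]) - 1,
                alleles=(str(rec["oa"]), str(rec["ea"])),  # ALT = effect allele
                id=str(rec["id"]),
            )
            row.info["AF"] = (float(rec["eaf"]),)
            row.info["IMPINFO"] = float(rec["info"])
            ds = genotypes.dosages[:, k]
            for s, d in zip(genotypes.sample_ids, ds):
                row.samples[str(s)]["DS"] = None if np.isnan(d) else float(d)
            vcf.write(row)


def read_vcf(path: str) -> GenotypeData:
    """Read a dosage VCF (FORMAT DS) into a GenotypeData."""
    with pysam.VariantFile(path) as vcf:
        samples = np.array(list(vcf.header.samples), dtype=object)
        rows, dosages = [], []
        for rec in vcf:
            rows.append(
                {
                    "id": rec.id,
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ea": rec.alts[0],
                    "oa": rec.ref,
                    "eaf": float(rec.info["AF"][0]) if "AF" in rec.info else np.nan,
                    "info": float(rec.info["IMPINFO"])
                    if "IMPINFO" in rec.info else np.nan,
                }
            )
            ds = [rec.samples[s].get("DS") for s in samples]
            dosages.append([np.nan if d is None else float(d) for d in ds])
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeData(samples, variants, np.array(dosages, dtype=float).T)


# ---------------------------------------------------------------------------
# Genotypes: plain matrix table
# ---------------------------------------------------------------------------

def write_genotype_matrix(genotypes: GenotypeData, path: str) -> None:
    """Matrix table: variant metadata columns then one dosage column per sample."""
    df = genotypes.variants.copy()
    ds = pd.DataFrame(
        genotypes.dosages.T, columns=[str(s) for s in genotypes.sample_ids]
    )
    pd.concat([df.reset_index(drop=True), ds], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_genotype_matrix(path: str) -> GenotypeData:
    df = pd.read_csv(path, sep="\t")
    meta = df[VARIANT_COLUMNS]
    sample_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeData(np.array(sample_cols, dtype=object), meta.copy(), dosages)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def write_summary_stats(result: AssocResult, out_dir: str, prefix: str = "assoc") -> list[str]:
    """One delimited summary-statistics file per age.

    Columns (bit-stable for downstream tools):
    id, chr, pos, EA, nonEA, EAF, info, n, beta, se, p.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for a, label in enumerate(AGE_LABELS):
        sub = result.for_age(a)
        path = os.path.join(out_dir, f"{prefix}_{label}.tsv")
        sub.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_summary_stats(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
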