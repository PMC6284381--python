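"""Readers and writers for the pipeline's on-disk formats.

Variant tables travel as TSV (or minimal VCF 4.2 with AF/DP/AD in INFO),
beta matrices as CSV, peaks as 6-column BED, coverage as TSV and truth /
classification results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_variants_tsv",
    "read_variants_tsv",
    "write_variants_vcf",
    "read_variants_vcf",
    "write_beta_csv",
    "read_beta_csv",
    "write_peaks_bed",
    "read_peaks_bed",
    "write_coverage_tsv",
    "read_coverage_tsv",
    "write_json",
    "read_json",
]


def write_variants_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt-supporting reads">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(df: pd.DataFrame, path) -> None:
    """Write one sample's variants as minimal VCF 4.2 (AF/DP/AD in INFO)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for row in df.sort_values(["chrom", "pos"]).itertuples():
            info = (
                f"AF={row.AF:.6g};DP={int(row.total_reads)};"
                f"AD={int(row.alt_reads)};GENE={row.gene}"
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n"
            )


def read_variants_vcf(path, patient: str, sample_id: str,
                      timepoint: str = "INI", origin: str = "PRI") -> pd.DataFrame:
    """Read a minimal VCF into the variant-table dialect via cyvcf2."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        dp = int(v.INFO.get("DP", 0))
        ad = int(v.INFO.get("AD", 0))
        af = float(v.INFO.get("AF", ad / dp if dp else 0.0))
        rows.append(
            {
                "patient": patient,
                "sample_id": sample_id,
                "timepoint": timepoint,
                "origin": origin,
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else ".",
                "gene": v.INFO.get("GENE", ""),
                "functional_class": "nonsynonymous",
                "population_frequency": 0.0,
                "alt_reads": ad,
                "total_reads": dp,
                "AF": af,
                "detected": ad >= 5,
            }
        )
    return pd.DataFrame(rows)


def write_beta_csv(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path)


def read_beta_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """6-column BED: chrom, start, end, name, score(height), strand."""
    out = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"].astype(int),
            "end": peaks["end"].astype(int),
            "name": peaks.get("peak_id", [f"peak{i}" for i in range(len(peaks))]),
            "score": peaks.get("height", 0.0),
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "peak_id", "height", "strand"],
    )
    return df.drop(columns="strand")


def write_coverage_tsv(bins: pd.DataFrame, path) -> None:
    bins[["chrom", "start", "gc_fraction", "read_count"]].to_csv(
        path, sep="\t", index=False
    )


def read_coverage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
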