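"""Tab-delimited file interfaces.

Layouts: cohort TSV (one row per sample), methylation TSV (CpG rows,
sample columns), annotation as BED-like TSV (0-based half-open on disk,
converted to 1-based inclusive in memory), truth TSV, and result tables
with a parameter header comment block. Coordinate conversion is
centralized here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MethylationMatrix

HEADER_PREFIX = "# "


def write_table(df: pd.DataFrame, path: str, params: dict | None = None, index: bool = True) -> None:
    """Write a TSV with an optional ``# key=value`` parameter header block."""
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"{HEADER_PREFIX}{k}={v}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_cohort(cohort: pd.DataFrame, path: str, params: dict | None = None) -> None:
    write_table(cohort, path, params=params)


def read_cohort(path: str) -> pd.DataFrame:
    df = read_table(path, index_col=0)
    for col in ("sex", "education", "smoking", "marital_status", "ace_cat"):
        if col in df.columns:
            df[col] = df[col].astype("category")
    return df


def write_matrix(matrix: MethylationMatrix, matrix_path: str, annotation_path: str,
                 params: dict | None = None) -> None:
    values = pd.DataFrame(matrix.values, index=matrix.cpg_ids, columns=matrix.sample_ids)
    values.index.name = "cpg_id"
    write_table(values, matrix_path, params=dict(scale=matrix.scale, **(params or {})))
    write_annotation_bed(matrix.cpg_annotation, annotation_path)


def read_matrix(matrix_path: str, annotation_path: str, scale: str = "beta") -> MethylationMatrix:
    values = read_table(matrix_path, index_col=0)
    ann = read_annotation_bed(annotation_path)
    ann = ann.loc[values.index]
    return MethylationMatrix(
        values=values.to_numpy(), scale=scale, cpg_annotation=ann,
        sample_ids=list(values.columns),
    )


def write_annotation_bed(annotation: pd.DataFrame, path: str) -> None:
    """Annotation to BED-like TSV: chrom, start (0-based), end (half-open),
    cpg_id, gene, feature."""
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"].to_numpy(),
            "start": annotation["pos"].to_numpy() - 1,
            "end": annotation["pos"].to_numpy(),
            "cpg_id": annotation.index.to_numpy(),
            "gene": annotation["gene"].to_numpy(),
            "feature": annotation["feature"].to_numpy(),
        }
    )
    bed.to_csv(path, sep="\t", index=False)


def read_annotation_bed(path: str) -> pd.DataFrame:
    bed = read_table(path, keep_default_na=False)
    ann = pd.DataFrame(
        {
            "chrom": bed["chrom"].to_numpy(),
            "pos": bed["start"].to_numpy() + 1,  # back to 1-based inclusive
            "gene": bed["gene"].to_numpy(),
            "feature": bed["feature"].to_numpy(),
        },
        index=pd.Index(bed["cpg_id"], name="cpg_id"),
    )
    return ann


def dmr_calls_to_bed(calls: pd.DataFrame) -> pd.DataFrame:
    """Report-table (1-based inclusive) to BED frame (0-based half-open)."""
    out = calls.copy()
    out["start"] = out["start"] - 1
    return out


def write_gene_sets(sets: dict[str, tuple[str, list[str]]], path: str) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")
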