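"""Exclusively Expressed Transcript (EET) detection and tiering.

An EET is a transcript variant with zero pooled expression in the
non-fiber background (LRS) and expression in the fiber-relevant pool (OF).
EETs are tiered by OF log2(FPKM+1): high (> 1), low (< 0.1), mid in
between, unknown when the OF value is missing. A row whose OF value is
missing but whose LRS value is exactly zero still qualifies (missing is
"not quantified", not "not expressed") and lands in the unknown tier.

The bundled fixture carries the 62 transcript rows of the published EET
table (19 genes, OF/LRS pooled log2(FPKM+1)), on which the filter
recovers 20 EETs, 5 of them high tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from fiberatlas.data_io import (
    ExpressionMatrix,
    SampleSheet,
    ValidationError,
    transcript_gene_id,
    transcript_suffix,
)

HIGH_TIER_THRESHOLD = 1.0
LOW_TIER_THRESHOLD = 0.1


@dataclass
class EETRecord:
    transcript_id: str
    gene_id: str
    of_expr: float  # log2(FPKM+1); NaN if missing
    lrs_expr: float
    is_eet: bool
    tier: str = ""
    gene_has_other_expressed_variant: bool = False


def load_table1_fixture() -> ExpressionMatrix:
    """The packaged published EET table as a transcript ExpressionMatrix.

    Columns OF and LRS in log2(FPKM+1); the one blank OF cell is missing,
    not zero.
    """
    path = resources.files("fiberatlas") / "data" / "table1_eet.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    values = pd.DataFrame(
        {
            "OF": pd.to_numeric(df["OF"].mask(df["OF"] == "")),
            "LRS": pd.to_numeric(df["LRS"].mask(df["LRS"] == "")),
        },
    )
    values.index = pd.Index(df["transcript_id"], name="feature_id")
    return ExpressionMatrix(values, level="transcript", unit="log2fpkm1")


def load_table1_annotations() -> pd.DataFrame:
    """Gene annotations and duplicate-sequence flags for the fixture."""
    path = resources.files("fiberatlas") / "data" / "table1_eet.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    df["duplicate_seq"] = df["duplicate_seq"].astype(int).astype(bool)
    return df[["transcript_id", "gene_id", "annotation", "duplicate_seq"]]


def detect_eets(expr: ExpressionMatrix, zero_tol: float = 0.0) -> list[EETRecord]:
    """Flag transcripts expressed in OF with null LRS expression.

    ``expr`` must be transcript-level log2(FPKM+1) with pooled columns OF
    and LRS. A transcript is an EET iff lrs_expr <= zero_tol and its OF
    value is either missing or > zero_tol. Records come back sorted by
    gene id then transcript suffix.
    """
    if expr.unit != "log2fpkm1":
        raise ValidationError("detect_eets expects log2(FPKM+1) values")
    for col in ("OF", "LRS"):
        if col not in expr.sample_ids:
            raise ValidationError(f"pooled column {col!r} missing")
    records = []
    lrs_expressed_genes: set[str] = set()
    parsed = []
    for tx in expr.feature_ids:
        gene = transcript_gene_id(tx)
        if gene == tx and "." not in tx:
            warnings.warn(
                f"transcript id {tx!r} has no .n suffix; using it as gene id",
                stacklevel=2,
            )
        parsed.append((tx, gene))
        lrs = expr.values.at[tx, "LRS"]
        if not np.isnan(lrs) and lrs > zero_tol:
            lrs_expressed_genes.add(gene)
    for tx, gene in parsed:
        of = float(expr.values.at[tx, "OF"])
        lrs = float(expr.values.at[tx, "LRS"])
        is_eet = (not np.isnan(lrs) and lrs <= zero_tol) and (
            np.isnan(of) or of > zero_tol
        )
        records.append(
            EETRecord(
                transcript_id=tx,
                gene_id=gene,
                of_expr=of,
                lrs_expr=lrs,
                is_eet=bool(is_eet),
                gene_has_other_expressed_variant=gene in lrs_expressed_genes,
            )
        )
    records.sort(key=lambda r: (r.gene_id, transcript_suffix(r.transcript_id)))
    return tier_eets(records)


def tier_eets(records: Iterable[EETRecord]) -> list[EETRecord]:
    """Assign expression tiers: high (OF > 1), low (OF < 0.1), mid, unknown."""
    out = []
    for rec in records:
        if not rec.is_eet:
            rec.tier = ""
        elif np.isnan(rec.of_expr):
            rec.tier = "unknown"
        elif rec.of_expr > HIGH_TIER_THRESHOLD:
            rec.tier = "high"
        elif rec.of_expr < LOW_TIER_THRESHOLD:
            rec.tier = "low"
        else:
            rec.tier = "mid"
        out.append(rec)
    return out


def eet_records_frame(records: Sequence[EETRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "of_expr": [r.of_expr for r in records],
            "lrs_expr": [r.lrs_expr for r in records],
            "is_eet": [r.is_eet for r in records],
            "tier": [r.tier for r in records],
            "gene_has_other_expressed_variant": [
                r.gene_has_other_expressed_variant for r in records
            ],
        }
    )


def cumulative_group_expression(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    eet_ids: Sequence[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> dict:
    """Compare per-sample summed EET expression between two sample sets.

    Returns per-sample sums, group means, and a two-sided Wilcoxon
    rank-sum p-value (NaN unless both groups have >= 3 samples). Used to
    contrast, e.g., domesticated vs wild cultivars or wild type vs a
    fiberless mutant.
    """
    if not len(eet_ids):
        raise ValidationError("empty EET set")
    if not len(group_a) or not len(group_b):
        raise ValidationError("both groups must be nonempty")
    sub = expr.subset(features=list(eet_ids))
    sums = sub.values.sum(axis=0, min_count=1)
    a = sums[list(group_a)].to_numpy(dtype=float)
    b = sums[list(group_b)].to_numpy(dtype=float)
    if len(a) >= 3 and len(b) >= 3:
        p = float(stats.ranksums(a, b).pvalue)
    else:
        p = float("nan")
    return {
        "per_sample_sum": sums,
        "mean_a": float(np.nanmean(a)),
        "mean_b": float(np.nanmean(b)),
        "pvalue": p,
    }
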