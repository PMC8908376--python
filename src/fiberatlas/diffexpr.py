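"""OF-vs-LRS differential expression.

Fiber-relevant (ovule + fiber, "OF") samples are contrasted against the
non-fiber background (leaf + root + seed, "LRS"). A gene is called
upregulated when FDR < alpha (default 0.005) and log2 fold change > tau
(default 2); downregulated symmetrically. The per-gene test is Welch's t on
log2(FPKM+1) values with Benjamini--Hochberg adjustment (``de.test =
welch``): a two-sample location test on the stabilized scale, standing in
for a full per-sample linear model, which needs no fitted covariance
structure and behaves well at small group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fiberatlas.data_io import (
    ExpressionMatrix,
    SampleSheet,
    ValidationError,
    parse_subgenome,
)

ALPHA_DEFAULT = 0.005
LFC_DEFAULT = 2.0
VARIANCE_FLOOR = 1e-8


@dataclass
class DEGCounts:
    """Direction totals and their At/Dt subgenome split."""

    up: int
    down: int
    ns: int
    by_subgenome: pd.DataFrame  # index {At, Dt, unknown} x columns {up, down, ns}

    @property
    def total(self) -> int:
        return self.up + self.down + self.ns


def pool_groups(
    expr: ExpressionMatrix, sheet: SampleSheet, method: str = "mean"
) -> ExpressionMatrix:
    """Pool samples into two columns, OF and LRS.

    Missing values are excluded from the summary; a feature whose group
    values are all missing stays missing in the pooled column.
    """
    if method not in ("mean", "sum"):
        raise ValidationError(f"unknown pooling method {method!r}")
    sheet.validate_against(expr)
    cols = {}
    for group in ("OF", "LRS"):
        members = [s for s in sheet.samples_in_group(group) if s in expr.sample_ids]
        if not members:
            raise ValidationError(f"no samples in group {group}")
        sub = expr.values[members]
        # min_count=1 keeps all-missing rows missing rather than 0
        cols[group] = sub.mean(axis=1) if method == "mean" else sub.sum(
            axis=1, min_count=1
        )
    return ExpressionMatrix(pd.DataFrame(cols), expr.level, expr.unit)


def log2_fold_change(
    mean_of: float, mean_lrs: float, pseudocount: float = 1.0
) -> float:
    """log2((mean_of + c) / (mean_lrs + c)) with pseudocount c (default 1)."""
    if mean_of < 0 or mean_lrs < 0:
        raise ValidationError("group means must be non-negative")
    return float(np.log2((mean_of + pseudocount) / (mean_lrs + pseudocount)))


def two_group_test(
    values_of: np.ndarray,
    values_lrs: np.ndarray,
    variance_floor: float = VARIANCE_FLOOR,
) -> float:
    """Two-sided Welch t-test p-value on log2(FPKM+1) values.

    Sample variances are floored at ``variance_floor`` so that groups with
    zero spread but different means still yield a finite, extreme p-value.
    Returns NaN when either group has fewer than two present values.
    """
    a = np.asarray(values_of, dtype=float)
    b = np.asarray(values_lrs, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    va = max(a.var(ddof=1), variance_floor)
    vb = max(b.var(ddof=1), variance_floor)
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return float(2.0 * stats.t.sf(abs(t), df))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, returned in input order.

    Missing p-values propagate as missing and do not count toward the
    number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    present = ~np.isnan(p)
    if present.any():
        pp = p[present]
        if (pp < 0).any() or (pp > 1).any():
            raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if present.any():
        out[present] = multipletests(p[present], method="fdr_bh")[1]
    return out


def call_direction(fdr: float, log2fc: float, alpha: float, tau: float) -> str:
    if not np.isnan(fdr) and fdr < alpha:
        if log2fc > tau:
            return "up"
        if log2fc < -tau:
            return "down"
    return "ns"


def differential_expression(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    alpha: float = ALPHA_DEFAULT,
    tau: float = LFC_DEFAULT,
    pseudocount: float = 1.0,
    pool_method: str = "mean",
) -> pd.DataFrame:
    """Full OF-vs-LRS DE table.

    Expression is log2(FPKM+1)-transformed for testing; fold change uses
    the pooled linear-scale means with the pseudocount. Columns:
    feature_id, mean_of, mean_lrs, log2fc, pvalue, fdr, direction,
    subgenome.
    """
    sheet.validate_against(expr)
    of_samples = [s for s in sheet.samples_in_group("OF") if s in expr.sample_ids]
    lrs_samples = [s for s in sheet.samples_in_group("LRS") if s in expr.sample_ids]
    if not of_samples or not lrs_samples:
        raise ValidationError("both OF and LRS groups need at least one sample")

    pooled = pool_groups(expr, sheet, method=pool_method)
    log_expr = expr.to_log2()

    of_mat = log_expr.values[of_samples].to_numpy(dtype=float)
    lrs_mat = log_expr.values[lrs_samples].to_numpy(dtype=float)
    pvals = np.array(
        [two_group_test(of_mat[i], lrs_mat[i]) for i in range(of_mat.shape[0])]
    )
    fdr = bh_adjust(pvals)

    mean_of = pooled.values["OF"].to_numpy(dtype=float)
    mean_lrs = pooled.values["LRS"].to_numpy(dtype=float)
    lfc = np.array(
        [
            log2_fold_change(a, b, pseudocount)
            if not (np.isnan(a) or np.isnan(b))
            else np.nan
            for a, b in zip(mean_of, mean_lrs)
        ]
    )
    direction = [
        call_direction(q, f, alpha, tau) if not np.isnan(f) else "ns"
        for q, f in zip(fdr, lfc)
    ]
    return pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "mean_of": mean_of,
            "mean_lrs": mean_lrs,
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": fdr,
            "direction": direction,
            "subgenome": [parse_subgenome(f) for f in expr.feature_ids],
        }
    )


def call_degs(
    results: pd.DataFrame, alpha: float = ALPHA_DEFAULT, tau: float = LFC_DEFAULT
) -> DEGCounts:
    """(Re)label directions at the given thresholds and tally the partition."""
    direction = [
        call_direction(q, f, alpha, tau)
        for q, f in zip(results["fdr"], results["log2fc"])
    ]
    results = results.assign(direction=direction)
    tab = (
        results.groupby(["subgenome", "direction"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=["At", "Dt", "unknown"], columns=["up", "down", "ns"])
        .fillna(0)
        .astype(int)
    )
    counts = results["direction"].value_counts()
    return DEGCounts(
        up=int(counts.get("up", 0)),
        down=int(counts.get("down", 0)),
        ns=int(counts.get("ns", 0)),
        by_subgenome=tab,
    )
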