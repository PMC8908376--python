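"""nCounter normalization, qPCR fold change, and expression-trait correlation.

nCounter counts are normalized against the arithmetic mean of endogenous
control genes (e.g. EF1a-5, UBQ-14, Actin-4): each sample is rescaled so
its control mean equals the grand mean of control means across samples.
qPCR relative expression uses the 2^(-ddCt) convention. Expression-trait
association across genotypes is Pearson's r with the exact t-transform
p-value and the significance stars *, **, *** at p <= 0.05, 0.01, 0.005.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fiberatlas.data_io import ValidationError

FIBER_TRAITS = (
    "fiber_length_mm",
    "uniformity_index_pct",
    "strength_g_per_tex",
    "elongation_pct",
    "micronaire_ug_per_inch",
    "boll_number",
    "boll_weight_g",
    "yield_kg",
)

DEFAULT_CONTROLS = ("EF1a-5", "UBQ-14", "Actin-4")


@dataclass
class TraitCorrelation:
    transcript_id: str
    trait: str
    n: int
    r: float
    p: float
    stars: str
    reason: str = ""


def significance_stars(p: float) -> str:
    """Map a p-value to the star convention: closed upper bounds.

    *** for p <= 0.005, ** for p <= 0.01, * for p <= 0.05, else none.
    """
    if np.isnan(p):
        return ""
    if p <= 0.005:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def normalize_ncounter(
    raw_counts: pd.DataFrame, control_ids=DEFAULT_CONTROLS
) -> pd.DataFrame:
    """Housekeeping-mean normalization of a genes x samples count table.

    Per-sample factor = (grand mean over samples of the per-sample control
    mean) / (per-sample control mean); all counts in a sample are scaled by
    its factor. Control rows are retained in the output.
    """
    control_ids = list(control_ids)
    missing = [c for c in control_ids if c not in raw_counts.index]
    if missing:
        raise ValidationError(f"control genes absent from counts: {missing}")
    if (raw_counts.to_numpy(dtype=float) < 0).any():
        raise ValidationError("raw counts must be non-negative")
    control_mean = raw_counts.loc[control_ids].mean(axis=0)
    zero = control_mean.index[control_mean == 0].tolist()
    if zero:
        raise ValidationError(
            f"control mean is zero for sample(s) {zero[:5]}; cannot normalize"
        )
    grand = float(control_mean.mean())
    factors = grand / control_mean
    return raw_counts.mul(factors, axis=1)


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by 2^(-ddCt).

    ddCt = (Ct_target - Ct_reference) in the sample minus the same
    difference in the calibrator.
    """
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))


def trait_correlation(
    expression, trait, transcript_id: str = "", trait_name: str = "",
    method: str = "t", n_perm: int = 10000, seed: int | None = None,
) -> TraitCorrelation:
    """Pearson correlation of one transcript's expression with one trait.

    Genotypes with a missing value in either vector are dropped pairwise;
    at least 3 complete pairs are required. ``method="t"`` uses the exact
    t-transform p-value (t = r sqrt((n-2)/(1-r^2))); ``method="perm"``
    uses a seeded permutation test with the add-one estimator.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("expression and trait vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        return TraitCorrelation(
            transcript_id, trait_name, n, float("nan"), float("nan"), "",
            reason="fewer than 3 complete pairs",
        )
    if np.std(x) == 0 or np.std(y) == 0:
        return TraitCorrelation(
            transcript_id, trait_name, n, float("nan"), float("nan"), "",
            reason="constant vector",
        )
    r = float(stats.pearsonr(x, y).statistic)
    if method == "perm":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            rp = float(stats.pearsonr(x, rng.permutation(y)).statistic)
            if abs(rp) >= abs(r):
                hits += 1
        p = (1 + hits) / (n_perm + 1)
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return TraitCorrelation(transcript_id, trait_name, n, r, p, significance_stars(p))


def correlation_table(
    expression: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """All transcript x trait Pearson correlations with stars.

    ``expression``: transcripts x genotypes; ``traits``: genotypes x
    traits. Genotypes are matched on the shared ids. Cells carry the
    formatted "r stars" string; long-format numeric columns are in
    ``.attrs["long"]``.
    """
    genotypes = [g for g in expression.columns if g in traits.index]
    if len(genotypes) < 3:
        raise ValidationError("fewer than 3 shared genotypes")
    long_rows = []
    formatted = pd.DataFrame(index=expression.index, columns=traits.columns, dtype=object)
    for tx in expression.index:
        for trait in traits.columns:
            tc = trait_correlation(
                expression.loc[tx, genotypes],
                traits.loc[genotypes, trait],
                transcript_id=str(tx),
                trait_name=str(trait),
            )
            long_rows.append(tc.__dict__)
            formatted.at[tx, trait] = (
                f"{tc.r:.3f}{tc.stars}" if not np.isnan(tc.r) else "NA"
            )
    formatted.attrs["long"] = pd.DataFrame(long_rows)
    return formatted
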