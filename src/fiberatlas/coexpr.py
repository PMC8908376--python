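"""Unsigned weighted co-expression networks, modules, eigengenes, hubs.

The network is built from an absolute Pearson correlation raised to a soft
threshold power (beta, default 10), then smoothed into the unsigned
topological overlap matrix (TOM), which rewards pairs that share neighbors
and is the standard similarity for weighted co-expression module detection.
Modules come from average-linkage hierarchical clustering on 1 - TOM with a
static cut plus a minimum-size filter (default 10); genes in undersized
clusters are left unassigned, mirroring outlier exclusion. The cut height
is the midpoint of the widest gap in the upper half of the sorted merge
heights, capped at the ``cut_height_quantile`` quantile: well-separated
modules leave a pronounced gap between within-module and between-module
merge heights, and the gap rule finds it whatever the module count, while
the quantile cap guarantees the extreme tail of merges is always severed. Module labels follow the conventional color ordering by
decreasing size (turquoise largest).

Conventions: adjacency has a_ii = 0 so row sums equal connectivity;
TOM_ii = 1 so a module core is maximally self-similar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from fiberatlas.data_io import ExpressionMatrix, ValidationError

BETA_DEFAULT = 10
MIN_MODULE_SIZE_DEFAULT = 10
CUT_HEIGHT_QUANTILE_DEFAULT = 0.99

MODULE_COLORS = ("turquoise", "blue", "brown", "green", "yellow", "red")
UNASSIGNED = "unassigned"


@dataclass
class ModulePartition:
    """Gene -> module assignment with eigengenes, hubs and clades."""

    assignments: pd.Series  # index gene_id, values module label or "unassigned"
    min_module_size: int = MIN_MODULE_SIZE_DEFAULT
    eigengenes: pd.DataFrame | None = None  # modules x samples
    hubs: dict[str, str] = field(default_factory=dict)
    clades: pd.Series | None = None  # index module, values clade label

    @property
    def modules(self) -> list[str]:
        sizes = self.module_sizes()
        return [m for m in sizes.index if m != UNASSIGNED]

    def module_sizes(self) -> pd.Series:
        return self.assignments.value_counts()

    def members(self, module: str) -> list[str]:
        return list(self.assignments.index[self.assignments == module])

    @property
    def n_unassigned(self) -> int:
        return int((self.assignments == UNASSIGNED).sum())


def _module_label(rank: int) -> str:
    if rank < len(MODULE_COLORS):
        return MODULE_COLORS[rank]
    return f"module{rank + 1}"


def soft_adjacency(expr_sub: ExpressionMatrix, beta: float = BETA_DEFAULT) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^beta.

    Genes must have nonzero variance across samples (filter beforehand);
    the diagonal is set to 0 so row sums equal whole-network connectivity.
    """
    mat = expr_sub.values.to_numpy(dtype=float)
    if mat.shape[1] < 3:
        raise ValidationError("need at least 3 samples for co-expression")
    if np.isnan(mat).any():
        raise ValidationError("missing values must be imputed or dropped first")
    sd = mat.std(axis=1)
    if (sd == 0).any():
        bad = [g for g, s in zip(expr_sub.feature_ids, sd) if s == 0]
        raise ValidationError(
            f"zero-variance genes must be pre-filtered: {bad[:5]}"
        )
    corr = np.corrcoef(mat)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    adj = np.clip(adj, 0.0, 1.0)
    ids = expr_sub.feature_ids
    return pd.DataFrame(adj, index=ids, columns=ids)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), where
    l_ij = sum_u a_iu a_uj over u != i, j and k_i is the connectivity
    (row sum). TOM_ii is set to 1 by convention.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # (A^2)_ij = sum_u a_iu a_uj; diag a_ii = 0 excludes u=i,j
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = MIN_MODULE_SIZE_DEFAULT,
    cut_height_quantile: float = CUT_HEIGHT_QUANTILE_DEFAULT,
) -> ModulePartition:
    """Cluster genes on 1 - TOM and label modules by decreasing size.

    Average-linkage hierarchical clustering; the tree is cut at the widest
    gap in the upper half of the sorted merge heights (midpoint), capped at
    the ``cut_height_quantile`` quantile of the heights. Clusters smaller
    than ``min_module_size`` become unassigned.
    """
    n = tom.shape[0]
    if n < min_module_size:
        raise ValidationError(
            f"{n} genes < min_module_size {min_module_size}"
        )
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    linkage = average(squareform(diss, checks=False))
    heights = np.sort(linkage[:, 2])
    if heights.size == 1 or heights[-1] == heights[0]:
        cut = float(heights[-1]) + 1.0  # degenerate tree: one cluster
    else:
        lo = heights.size // 2  # widest gap in the upper half of heights
        gaps = np.diff(heights[lo:])
        i = int(np.argmax(gaps)) + lo
        gap_cut = float((heights[i] + heights[i + 1]) / 2.0)
        cut = min(gap_cut, float(np.quantile(heights, cut_height_quantile)))
    raw = fcluster(linkage, t=cut, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    # deterministic label order: by decreasing size, ties by first member
    order = sorted(
        kept, key=lambda c: (-int(sizes[c]), int(np.argmax(raw == c)))
    )
    label_of = {c: _module_label(i) for i, c in enumerate(order)}
    labels = [label_of.get(c, UNASSIGNED) for c in raw]
    assignments = pd.Series(labels, index=tom.index, name="module")
    return ModulePartition(assignments=assignments, min_module_size=min_module_size)


def module_eigengene(
    expr_sub: ExpressionMatrix, assignments: pd.Series, module: str
) -> pd.Series:
    """First principal component of the gene-standardized module submatrix.

    Returned per sample with unit norm, sign-oriented so its correlation
    with the module's mean expression profile is >= 0 (ties broken toward
    the first member gene's profile).
    """
    members = list(assignments.index[assignments == module])
    if len(members) < 2:
        raise ValidationError(f"module {module!r} needs >= 2 genes")
    mat = expr_sub.values.loc[members].to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValidationError("need >= 2 samples for an eigengene")
    sd = mat.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise ValidationError(f"module {module!r} is all-constant")
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (mat - mat.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = mat.mean(axis=0)
    c = _safe_corr(eig, mean_profile)
    if abs(c) < 1e-12:
        c = _safe_corr(eig, z[0])
    if c < 0:
        eig = -eig
    return pd.Series(eig, index=expr_sub.sample_ids, name=module)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def hub_gene(
    adjacency_or_tom: pd.DataFrame, assignments: pd.Series, module: str
) -> str:
    """Most intramodularly connected gene of a module.

    Centrality is the within-module row sum of the similarity matrix
    (self-similarity excluded); ties break lexicographically on gene id.
    """
    members = sorted(assignments.index[assignments == module])
    if not members:
        raise ValidationError(f"module {module!r} is empty")
    sub = adjacency_or_tom.loc[members, members].to_numpy(dtype=float).copy()
    np.fill_diagonal(sub, 0.0)
    connectivity = sub.sum(axis=1)
    return members[int(np.argmax(connectivity))]


def eigengene_clades(eigengenes: pd.DataFrame, n_clades: int = 2) -> pd.Series:
    """Group module eigengenes into clades.

    Average-linkage clustering on 1 - pearson(eigengene_i, eigengene_j),
    cut into exactly ``n_clades`` groups; clades are labeled ``"clade1"``,
    ``"clade2"``, ... in order of first module appearance.
    """
    n_modules = eigengenes.shape[0]
    if n_clades > n_modules:
        raise ValidationError(
            f"n_clades {n_clades} exceeds module count {n_modules}"
        )
    if n_clades == n_modules:
        labels = np.arange(1, n_modules + 1)
    else:
        corr = np.corrcoef(eigengenes.to_numpy(dtype=float))
        diss = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        linkage = average(squareform((diss + diss.T) / 2.0, checks=False))
        labels = fcluster(linkage, t=n_clades, criterion="maxclust")
    relabel: dict[int, str] = {}
    out = []
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = f"clade{len(relabel) + 1}"
        out.append(relabel[lab])
    return pd.Series(out, index=eigengenes.index, name="clade")


def network_and_modules(
    expr_sub: ExpressionMatrix,
    beta: float = BETA_DEFAULT,
    min_module_size: int = MIN_MODULE_SIZE_DEFAULT,
    cut_height_quantile: float = CUT_HEIGHT_QUANTILE_DEFAULT,
    n_clades: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, ModulePartition]:
    """Convenience wrapper: adjacency -> TOM -> modules -> eigengenes/hubs/clades.

    Zero-variance genes are dropped (and reported via the partition's
    assignments index) before network construction.
    """
    sd = expr_sub.values.std(axis=1)
    kept = expr_sub.subset(features=list(sd.index[sd > 0]))
    adj = soft_adjacency(kept, beta=beta)
    tom = topological_overlap(adj)
    part = detect_modules(
        tom, min_module_size=min_module_size, cut_height_quantile=cut_height_quantile
    )
    dropped = sd.index[sd == 0]
    if len(dropped):
        part.assignments = pd.concat(
            [part.assignments, pd.Series(UNASSIGNED, index=dropped)]
        )
    eig = {}
    for module in part.modules:
        eig[module] = module_eigengene(kept, part.assignments, module)
        part.hubs[module] = hub_gene(adj, part.assignments, module)
    if eig:
        part.eigengenes = pd.DataFrame(eig).T
        if len(eig) >= n_clades and len(eig) >= 2:
            part.clades = eigengene_clades(part.eigengenes, n_clades=n_clades)
    return adj, tom, part
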