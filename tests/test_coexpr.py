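import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from fiberatlas.coexpr import (
    ModulePartition,
    detect_modules,
    eigengene_clades,
    hub_gene,
    module_eigengene,
    soft_adjacency,
    topological_overlap,
)
from fiberatlas.data_io import ExpressionMatrix, ValidationError


def _expr(mat, prefix="g"):
    # shift by a global scalar so values are valid (non-negative) expression;
    # a constant offset leaves every correlation unchanged
    mat = np.asarray(mat, dtype=float)
    mat = mat - min(mat.min(), 0.0)
    return ExpressionMatrix(
        pd.DataFrame(
            mat,
            index=[f"{prefix}{i:03d}" for i in range(mat.shape[0])],
            columns=[f"s{j}" for j in range(mat.shape[1])],
        ),
        unit="log2fpkm1",
    )


def _random_adjacency(rng, n):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


def tom_oracle(a):
    """Independent triple-loop evaluation of the unsigned TOM formula."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return out


class TestSoftAdjacency:
    def test_perfect_correlation_any_beta(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        e = _expr([x, 2 * x + 1])
        for beta in (1, 6, 10):
            assert soft_adjacency(e, beta=beta).iloc[0, 1] == pytest.approx(1.0)

    def test_powered_correlation_value(self):
        # two genes engineered to correlate at exactly 0.9
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(0, 1, 2000)
        # orthogonalize the residual for an exact sample correlation
        x = (x - x.mean()) / x.std()
        r = np.corrcoef(x, y)[0, 1]
        adj = soft_adjacency(_expr([x, y]), beta=10)
        assert adj.iloc[0, 1] == pytest.approx(abs(r) ** 10, rel=1e-10)

    def test_unsigned_absolute_value(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        adj_pos = soft_adjacency(_expr([x, x + 1]), beta=10)
        adj_neg = soft_adjacency(_expr([x, -x]), beta=10)
        assert adj_neg.iloc[0, 1] == pytest.approx(adj_pos.iloc[0, 1]) == 1.0

    def test_diagonal_zero(self):
        e = _expr(np.random.default_rng(1).normal(0, 1, (4, 6)))
        assert (np.diag(soft_adjacency(e).to_numpy()) == 0).all()

    def test_zero_variance_gene_rejected(self):
        e = _expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValidationError, match="zero-variance"):
            soft_adjacency(e)


class TestTopologicalOverlap:
    def test_complete_triangle_saturates(self):
        a = _random_adjacency(np.random.default_rng(0), 3)
        a.iloc[:, :] = 1.0
        np.fill_diagonal(a.values, 0.0)
        tom = topological_overlap(a)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_empty_graph_zero_overlap(self):
        a = _random_adjacency(np.random.default_rng(0), 5)
        a.iloc[:, :] = 0.0
        tom = topological_overlap(a).to_numpy()
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_star_leaves_share_hub(self):
        # K_{1,3}: node 0 is the hub; leaves i, j share only the hub
        a = np.zeros((4, 4))
        a[0, 1:] = a[1:, 0] = 1.0
        ids = list("hxyz")
        tom = topological_overlap(pd.DataFrame(a, index=ids, columns=ids))
        assert tom.at["x", "y"] == pytest.approx(0.5)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = _random_adjacency(rng, 8)
            got = topological_overlap(a).to_numpy()
            assert np.allclose(got, tom_oracle(a.to_numpy()), atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_tom_within_unit_interval(self, seed):
        a = _random_adjacency(np.random.default_rng(seed), 6)
        tom = topological_overlap(a).to_numpy()
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


def _planted_blocks(rng, sizes, n_samples=30, within_sd=0.2):
    rows = []
    for b, size in enumerate(sizes):
        latent = rng.normal(0, 1, n_samples)
        for _ in range(size):
            rows.append(latent + rng.normal(0, within_sd, n_samples))
    return np.array(rows)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        mat = _planted_blocks(rng, [20, 20])
        # distinct latents => across-block correlation ~ 0
        tom = topological_overlap(soft_adjacency(_expr(mat)))
        part = detect_modules(tom, min_module_size=10)
        sizes = part.module_sizes()
        assert sorted(sizes[m] for m in part.modules) == [20, 20]
        assert part.n_unassigned == 0
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, part.assignments) == 1.0

    def test_small_block_unassigned(self):
        rng = np.random.default_rng(6)
        mat = _planted_blocks(rng, [20, 5])
        tom = topological_overlap(soft_adjacency(_expr(mat)))
        part = detect_modules(tom, min_module_size=10)
        assert [part.module_sizes()[m] for m in part.modules] == [20]
        assert part.n_unassigned == 5

    def test_pure_noise_yields_no_pair_modules(self):
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            mat = rng.normal(0, 1, (12, 30))
            tom = topological_overlap(soft_adjacency(_expr(mat)))
            part = detect_modules(tom, min_module_size=10)
            if len(part.modules) <= 1:
                ok += 1
        assert ok >= 45

    def test_sizes_plus_unassigned_equal_input(self):
        rng = np.random.default_rng(7)
        mat = _planted_blocks(rng, [15, 12, 4])
        tom = topological_overlap(soft_adjacency(_expr(mat)))
        part = detect_modules(tom, min_module_size=10)
        assert int(part.module_sizes().sum()) == 31

    def test_too_few_genes_rejected(self):
        a = _random_adjacency(np.random.default_rng(0), 5)
        with pytest.raises(ValidationError):
            detect_modules(topological_overlap(a), min_module_size=10)


class TestModuleEigengene:
    def test_identical_profiles_rank_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        e = _expr([x, x, x])
        assign = pd.Series(["m"] * 3, index=e.feature_ids)
        eig = module_eigengene(e, assign, "m")
        z = (x - x.mean()) / x.std()
        assert np.allclose(eig, z / np.linalg.norm(z), atol=1e-10)

    def test_exact_negatives_tie_broken_toward_first_gene(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        e = _expr([x, -x + 5])
        assign = pd.Series(["m", "m"], index=e.feature_ids)
        eig = module_eigengene(e, assign, "m")
        # mean profile is constant (corr 0); orientation follows gene 0
        assert np.corrcoef(eig, x)[0, 1] > 0

    def test_recovers_planted_latent_profile(self):
        rng = np.random.default_rng(11)
        latent = rng.normal(0, 1, 25)
        mat = np.array([latent + rng.normal(0, 0.3, 25) for _ in range(15)])
        e = _expr(mat)
        assign = pd.Series(["m"] * 15, index=e.feature_ids)
        eig = module_eigengene(e, assign, "m")
        assert abs(np.corrcoef(eig, latent)[0, 1]) >= 0.95

    def test_orientation_positive_against_mean_profile(self):
        rng = np.random.default_rng(12)
        latent = rng.normal(0, 1, 20)
        mat = np.array([latent * rng.uniform(0.5, 2) + rng.normal(0, 0.2, 20) for _ in range(8)])
        e = _expr(mat)
        assign = pd.Series(["m"] * 8, index=e.feature_ids)
        eig = module_eigengene(e, assign, "m")
        assert np.corrcoef(eig, mat.mean(axis=0))[0, 1] >= 0


class TestHubGene:
    def test_star_center_wins(self):
        a = np.zeros((4, 4))
        a[0, 1:] = a[1:, 0] = 0.9
        ids = ["center", "l1", "l2", "l3"]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        assign = pd.Series(["m"] * 4, index=ids)
        assert hub_gene(adj, assign, "m") == "center"

    def test_all_equal_tie_lexicographic(self):
        ids = ["gB", "gA", "gC"]
        a = pd.DataFrame(0.5, index=ids, columns=ids)
        np.fill_diagonal(a.values, 0.0)
        assign = pd.Series(["m"] * 3, index=ids)
        assert hub_gene(a, assign, "m") == "gA"

    def test_matches_brute_force_row_sum(self):
        rng = np.random.default_rng(13)
        adj = _random_adjacency(rng, 9)
        members = list(adj.index[:6])
        assign = pd.Series(
            ["m"] * 6 + ["other"] * 3, index=list(adj.index)
        )
        # brute force: intramodular connectivity by explicit double loop
        best, best_k = None, -1.0
        for g in sorted(members):
            k = sum(adj.at[g, h] for h in members if h != g)
            if k > best_k:
                best, best_k = g, k
        assert hub_gene(adj, assign, "m") == best

    def test_invariant_under_gene_permutation(self):
        rng = np.random.default_rng(14)
        adj = _random_adjacency(rng, 7)
        assign = pd.Series(["m"] * 7, index=adj.index)
        hub = hub_gene(adj, assign, "m")
        perm = rng.permutation(7)
        adj2 = adj.iloc[perm, perm]
        assert hub_gene(adj2, assign.iloc[perm], "m") == hub


class TestEigengeneClades:
    def test_anticorrelated_pairs_split(self):
        t = np.linspace(0, 2 * np.pi, 12)
        up, down = np.sin(t), -np.sin(t)
        eig = pd.DataFrame(
            [up, up + 0.01 * np.cos(t), down, down + 0.01 * np.cos(t)],
            index=["m1", "m2", "m3", "m4"],
        )
        clades = eigengene_clades(eig, n_clades=2)
        assert clades["m1"] == clades["m2"]
        assert clades["m3"] == clades["m4"]
        assert clades["m1"] != clades["m3"]

    def test_singleton_clades_identity(self):
        eig = pd.DataFrame(
            np.random.default_rng(1).normal(0, 1, (3, 8)), index=["a", "b", "c"]
        )
        clades = eigengene_clades(eig, n_clades=3)
        assert clades.nunique() == 3

    def test_commitment_vs_elongation_shapes_separate(self):
        rng = np.random.default_rng(15)
        # 18 samples ordered through development: early peak vs late peak
        commitment = np.array([3.0] * 5 + [1.0] * 13)
        elongation = np.array([1.0] * 5 + [3.0] * 13)
        eig = pd.DataFrame(
            [commitment + rng.normal(0, 0.2, 18) for _ in range(2)]
            + [elongation + rng.normal(0, 0.2, 18) for _ in range(4)],
            index=[f"m{i}" for i in range(6)],
        )
        clades = eigengene_clades(eig, n_clades=2)
        assert clades["m0"] == clades["m1"]
        assert len(set(clades[f"m{i}"] for i in range(2, 6))) == 1
        assert clades["m0"] != clades["m2"]

    def test_too_many_clades_rejected(self):
        eig = pd.DataFrame(np.eye(2), index=["a", "b"])
        with pytest.raises(ValidationError):
            eigengene_clades(eig, n_clades=3)
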