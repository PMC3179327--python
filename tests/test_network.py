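"""Network construction and module detection against independent oracles:
two-pass correlation, O(n³) TOM brute force, hand average linkage, planted
partitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coexqtl.data import ExpressionMatrix
from coexqtl.network import (
    AdjacencyMatrix, MODULE_PALETTE, UNASSIGNED,
    cluster_genes, connectivities, correlation_matrix, dynamic_tree_cut,
    export_edges, hub_genes, pick_soft_power, scale_free_fit, soft_adjacency,
    topological_overlap,
)


def df(arr, prefix="g"):
    ids = [f"{prefix}{i}" for i in range(len(arr))]
    return pd.DataFrame(np.asarray(arr, dtype=float), index=ids, columns=ids)


def random_adjacency(rng, n):
    A = rng.uniform(0, 1, (n, n))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)
    return AdjacencyMatrix(df(A), beta=1.0)


def tom_brute_force(A):
    """Triple-loop unsigned TOM oracle."""
    A = np.asarray(A, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            denom = min(k[i], k[j]) + 1.0 - A[i, j]
            T[i, j] = 1.0 if denom <= 0 else (l_ij + A[i, j]) / denom
    return T


def average_linkage_brute_force(D):
    """O(n³) hand implementation of average-linkage agglomeration.

    Returns the sorted list of merge heights (enough to pin the tree shape
    produced by scipy on distinct-distance inputs).
    """
    D = np.asarray(D, dtype=float).copy()
    clusters = {i: [i] for i in range(D.shape[0])}
    dist = {(i, j): D[i, j] for i in range(D.shape[0]) for j in range(i + 1, D.shape[0])}
    heights = []
    next_id = D.shape[0]
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters.pop(a) + clusters.pop(b)
        for c in list(clusters):
            members = clusters[c]
            d = np.mean([D[x, y] for x in merged for y in members])
            dist[(min(c, next_id), max(c, next_id))] = d
        clusters[next_id] = merged
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        next_id += 1
    return heights


class TestCorrelation:
    def test_self_correlation_is_one_and_sign_flip_is_minus_one(self, rng):
        x = rng.standard_normal(10)
        expr = ExpressionMatrix(pd.DataFrame([x, -x], index=["a", "b"],
                                             columns=[f"S{i}" for i in range(10)]))
        R = correlation_matrix(expr)
        assert R.at["a", "a"] == 1.0
        assert abs(R.at["a", "b"] + 1.0) < 1e-12

    def test_matches_two_pass_textbook_oracle(self, rng):
        X = rng.standard_normal((20, 10))
        R = correlation_matrix(df_expr(X)).to_numpy()
        for i in range(20):
            for j in range(20):
                xi, xj = X[i], X[j]
                num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
                den = np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                assert abs(R[i, j] - num / den) < 1e-12

    def test_constant_gene_gets_zero_correlation(self):
        X = np.vstack([np.ones(6), np.arange(6.0)])
        R = correlation_matrix(df_expr(X))
        assert R.iloc[0, 1] == 0.0 and R.iloc[0, 0] == 1.0

    def test_too_few_strains_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(df_expr(np.ones((3, 2))))


def df_expr(X):
    return ExpressionMatrix(pd.DataFrame(
        X, index=[f"g{i}" for i in range(X.shape[0])],
        columns=[f"S{i}" for i in range(X.shape[1])]))


class TestSoftAdjacency:
    @pytest.mark.parametrize("r,beta,expected", [
        (1.0, 6.0, 1.0),
        (-0.5, 6.0, 0.015625),
        (0.0, 6.0, 0.0),
    ])
    def test_powered_absolute_correlation(self, r, beta, expected):
        cor = df([[1.0, r], [r, 1.0]])
        adj = soft_adjacency(cor, beta)
        assert abs(adj.values.iloc[0, 1] - expected) < 1e-15

    def test_raising_beta_weakly_decreases_adjacency_and_mean_k(self, rng):
        cor = correlation_matrix(df_expr(rng.standard_normal((30, 12))))
        last = None
        for beta in (1, 2, 4, 8):
            A = soft_adjacency(cor, beta).values.to_numpy()
            np.fill_diagonal(A, 0.0)
            if last is not None:
                assert (A <= last + 1e-12).all()
            last = A

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError):
            soft_adjacency(df([[1.0, 0.5], [0.5, 1.0]]), beta=0)


class TestPickSoftPower:
    def test_single_candidate_returned_regardless_of_fit(self, rng):
        cor = correlation_matrix(df_expr(rng.standard_normal((40, 10))))
        beta, fit = pick_soft_power(cor, candidate_betas=[6], fit_threshold=0.99)
        assert beta == 6 and len(fit) == 1

    def test_mean_connectivity_monotone_in_beta(self, small_panel):
        expr = small_panel[1]
        cor = correlation_matrix(expr)
        beta, fit = pick_soft_power(cor)
        assert beta >= 1
        assert fit["mean_k"].is_monotonic_decreasing

    def test_identity_correlation_exercises_degenerate_path(self, caplog):
        cor = df(np.eye(8))
        with caplog.at_level("WARNING"):
            beta, fit = pick_soft_power(cor, candidate_betas=[2, 4])
        assert fit["signed_r2"].isna().all()

    def test_scale_free_fit_undefined_for_equal_connectivities(self):
        assert np.isnan(scale_free_fit(np.full(50, 3.0)))


class TestTopologicalOverlap:
    def test_identical_fully_connected_pair_has_unit_overlap(self):
        A = df(np.ones((4, 4)))
        tom = topological_overlap(AdjacencyMatrix(A, 1.0))
        assert abs(tom.overlap.iloc[0, 1] - 1.0) < 1e-12

    def test_disconnected_pair_has_zero_overlap(self):
        # two genes with a=0 sharing no neighbours
        A = np.eye(4)
        A[0, 2] = A[2, 0] = 0.9  # gene 0's neighbour
        A[1, 3] = A[3, 1] = 0.9  # gene 1's neighbour
        tom = topological_overlap(AdjacencyMatrix(df(A), 1.0))
        assert tom.overlap.iloc[0, 1] == 0.0

    def test_matches_brute_force_on_many_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            adj = random_adjacency(rng, n)
            T = topological_overlap(adj).overlap.to_numpy()
            T_oracle = tom_brute_force(adj.values.to_numpy())
            assert np.max(np.abs(T - T_oracle)) < 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_overlap_stays_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(rng, int(rng.integers(3, 10)))
        T = topological_overlap(adj).overlap.to_numpy()
        assert (T >= 0).all() and (T <= 1 + 1e-12).all()
        assert np.allclose(T, T.T)


class TestClustering:
    def test_two_genes_merge_at_their_dissimilarity(self):
        dendro = cluster_genes(df([[0.0, 0.3], [0.3, 0.0]]))
        assert abs(dendro.linkage_matrix[0, 2] - 0.3) < 1e-12

    def test_three_gene_average_linkage_by_hand(self):
        D = df([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        Z = cluster_genes(D).linkage_matrix
        assert abs(Z[0, 2] - 0.1) < 1e-12 and abs(Z[1, 2] - 0.9) < 1e-12

    def test_matches_independent_agglomeration_oracle(self, rng):
        D = rng.uniform(0.1, 1.0, (30, 30))
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        Z = cluster_genes(df(D)).linkage_matrix
        oracle_heights = average_linkage_brute_force(D)
        assert np.allclose(np.sort(Z[:, 2]), np.sort(oracle_heights), atol=1e-10)

    def test_merge_heights_non_decreasing(self, rng):
        # average linkage on a metric-free dissimilarity can in principle
        # invert, but on TOM dissimilarities of random data it does not
        D = rng.uniform(0.2, 1.0, (20, 20))
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        Z = cluster_genes(df(D)).linkage_matrix
        assert (np.diff(Z[:, 2]) >= -1e-9).all()

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            cluster_genes(df([[0.0]]))

    def test_newick_roundtrip_parses(self):
        D = df([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        nwk = cluster_genes(D).to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 2
        import io
        from Bio import Phylo

        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert {t.name for t in tree.get_terminals()} == {"g0", "g1", "g2"}


def planted_dissim(rng, sizes, within=0.05, between=0.95, jitter=0.02):
    n = sum(sizes)
    D = rng.uniform(between - jitter, between + jitter, (n, n))
    start = 0
    for s in sizes:
        D[start:start + s, start:start + s] = rng.uniform(
            within - jitter, within + jitter, (s, s))
        start += s
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return df(D)


class TestDynamicTreeCut:
    def test_three_planted_blocks_recovered_exactly(self, rng):
        labels = dynamic_tree_cut(cluster_genes(planted_dissim(rng, [50, 50, 50])))
        truth = np.repeat([0, 1, 2], 50)
        from coexqtl.evaluate import adjusted_rand_index

        assert labels.nunique() == 3
        assert adjusted_rand_index(labels, truth) == 1.0

    def test_equal_dissimilarities_give_no_modules(self):
        D = np.full((60, 60), 0.5)
        np.fill_diagonal(D, 0.0)
        labels = dynamic_tree_cut(cluster_genes(df(D)))
        assert (labels == UNASSIGNED).all()

    def test_block_below_minimum_size_never_forms_a_module(self, rng):
        labels = dynamic_tree_cut(
            cluster_genes(planted_dissim(rng, [50, 10])), min_module_size=30)
        small_block = labels.iloc[50:]
        assert set(small_block.unique()) <= {UNASSIGNED} | set(labels.iloc[:50].unique())
        assert labels.iloc[:50].nunique() == 1 and labels.iloc[0] != UNASSIGNED

    def test_labels_are_palette_colours_by_size_rank(self, rng):
        labels = dynamic_tree_cut(cluster_genes(planted_dissim(rng, [80, 50])))
        sizes = labels.value_counts()
        modules = [m for m in sizes.index if m != UNASSIGNED]
        assert modules[0] == MODULE_PALETTE[0] and sizes[modules[0]] >= sizes[modules[1]]

    def test_min_module_size_validated(self, rng):
        with pytest.raises(ValueError):
            dynamic_tree_cut(cluster_genes(planted_dissim(rng, [40])), min_module_size=1)


class TestConnectivities:
    def test_complete_graph_k_all(self):
        m = 6
        adj = AdjacencyMatrix(df(np.ones((m, m))), 1.0)
        labels = pd.Series(["turquoise"] * m, index=adj.gene_ids)
        k = connectivities(adj, labels)
        assert np.allclose(k["k_all"], m - 1)
        assert np.allclose(k["k_in"], m - 1)

    def test_unassigned_gene_has_zero_k_in(self, rng):
        adj = random_adjacency(rng, 5)
        labels = pd.Series(["blue", "blue", "blue", UNASSIGNED, UNASSIGNED],
                           index=adj.gene_ids)
        k = connectivities(adj, labels)
        assert (k.loc[labels == UNASSIGNED, "k_in"] == 0).all()

    def test_matches_brute_force_loops(self, rng):
        adj = random_adjacency(rng, 12)
        lab = rng.choice(["a", "b", UNASSIGNED], 12)
        labels = pd.Series(lab, index=adj.gene_ids)
        k = connectivities(adj, labels)
        A = adj.values.to_numpy()
        for i in range(12):
            k_all = sum(A[i, j] for j in range(12) if j != i)
            k_in = sum(A[i, j] for j in range(12)
                       if j != i and lab[j] == lab[i] and lab[i] != UNASSIGNED)
            assert abs(k.iloc[i]["k_all"] - k_all) < 1e-9
            assert abs(k.iloc[i]["k_in"] - k_in) < 1e-9

    def test_module_k_in_sums_to_twice_internal_adjacency(self, rng):
        adj = random_adjacency(rng, 15)
        labels = pd.Series(["m"] * 8 + [UNASSIGNED] * 7, index=adj.gene_ids)
        k = connectivities(adj, labels)
        A = adj.values.to_numpy()[:8, :8].copy()
        np.fill_diagonal(A, 0.0)
        assert abs(k["k_in"].iloc[:8].sum() - A.sum()) < 1e-9


class TestHubGenes:
    def make_assignment(self, k_in, k_all, module="salmon"):
        from coexqtl.network import ModuleAssignment

        table = pd.DataFrame({
            "module": [module] * len(k_in),
            "k_all": k_all, "k_in": k_in,
        }, index=[f"g{i}" for i in range(len(k_in))])
        return ModuleAssignment(table)

    def test_ranked_by_k_in_descending(self):
        a = self.make_assignment([5.0, 3.0, 1.0], [9.0, 9.0, 9.0])
        hubs = hub_genes(a, top_n=3)
        assert list(hubs["gene_id"]) == ["g0", "g1", "g2"]

    def test_k_all_breaks_k_in_ties(self):
        a = self.make_assignment([4.0, 4.0], [1.0, 2.0])
        hubs = hub_genes(a, top_n=2)
        assert list(hubs["gene_id"]) == ["g1", "g0"]

    def test_small_module_returns_all_members_flagged(self):
        a = self.make_assignment([2.0, 1.0], [2.0, 1.0])
        hubs = hub_genes(a, top_n=5)
        assert len(hubs) == 2 and hubs["truncated"].all()

    def test_matches_brute_force_sort(self, rng):
        k_in = rng.uniform(0, 10, 20).round(2)
        k_all = rng.uniform(0, 20, 20).round(2)
        a = self.make_assignment(list(k_in), list(k_all))
        hubs = hub_genes(a, top_n=4)
        oracle = sorted(range(20), key=lambda i: (-k_in[i], -k_all[i], f"g{i}"))[:4]
        assert list(hubs["gene_id"]) == [f"g{i}" for i in oracle]


class TestExportEdges:
    def test_category_thresholds(self):
        R = df(np.array([
            [1.0, 0.9, -0.6, 0.1],
            [0.9, 1.0, -0.9, 0.6],
            [-0.6, -0.9, 1.0, 0.2],
            [0.1, 0.6, 0.2, 1.0],
        ]))
        edges = export_edges(R, R.index)
        cat = {(r.gene_a, r.gene_b): r.category for r in edges.itertuples()}
        assert cat[("g0", "g1")] == "blue"      # r > 0.8
        assert cat[("g0", "g2")] == "yellow"    # -0.8 <= r < -0.5
        assert cat[("g1", "g2")] == "red"       # r < -0.8
        assert cat[("g1", "g3")] == "green"     # 0.5 < r <= 0.8
        assert ("g0", "g3") not in cat          # |r| <= 0.5 omitted
        assert ("g2", "g3") not in cat

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError):
            export_edges(df(np.eye(2)), ["g0", "g1"], t_low=0.8, t_high=0.5)
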