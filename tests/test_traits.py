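"""Gene/module significance, the correlation p-value, eigengenes, and
trait-trait correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexqtl.data import ExpressionMatrix, TraitTable
from coexqtl.traits import (
    average_replicates, critical_r, gene_significance, gene_significance_table,
    module_eigengene, module_significance, module_trait_table, ms_pvalue,
    trait_trait_correlation,
)


def series(values, prefix="S"):
    return pd.Series(np.asarray(values, dtype=float),
                     index=[f"{prefix}{i}" for i in range(len(values))])


class TestAverageReplicates:
    def test_two_replicates_average(self):
        reps = pd.DataFrame({
            "strain": ["A", "A", "B"], "mouse_id": ["m1", "m2", "m1"],
            "bmd": [10.0, 12.0, 7.0],
        })
        out = average_replicates(reps)
        assert out.values.loc["A", "bmd"] == 11.0
        assert out.values.loc["B", "bmd"] == 7.0

    def test_missing_values_averaged_over_available(self):
        reps = pd.DataFrame({
            "strain": ["A", "A"], "mouse_id": ["m1", "m2"],
            "bmd": [np.nan, 8.0], "femur_length": [15.0, 16.0],
        })
        out = average_replicates(reps.fillna({"bmd": 8.0}))
        assert out.values.loc["A", "femur_length"] == 15.5

    def test_matches_group_mean_oracle(self, rng):
        reps = pd.DataFrame({
            "strain": rng.choice(["A", "B", "C"], 60),
            "bmd": rng.standard_normal(60),
        })
        out = average_replicates(reps)
        for s in ("A", "B", "C"):
            assert abs(out.values.loc[s, "bmd"] -
                       reps.loc[reps.strain == s, "bmd"].mean()) < 1e-12


class TestGeneSignificance:
    def test_perfect_and_zero_correlation(self):
        x = series([1.0, 2.0, 3.0, 4.0])
        assert abs(gene_significance(x, x) - 1.0) < 1e-12
        orthogonal = series([1.0, -1.0, -1.0, 1.0])  # orthogonal to centered ramp
        assert gene_significance(series([1, 2, 3, 4]), orthogonal) < 1e-12

    def test_hand_computed_four_point_case(self):
        # cor((1,2,3,4), (1,2,4,3)) = 0.8
        assert abs(gene_significance(series([1, 2, 3, 4]), series([1, 2, 4, 3])) - 0.8) < 1e-12

    def test_constant_vector_gives_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            gs = gene_significance(series([1, 1, 1, 1]), series([1, 2, 3, 4]))
        assert gs == 0.0

    def test_alignment_by_strain_intersection(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=["a", "b", "c", "d"])
        y = pd.Series([4.0, 3.0, 2.0, 1.0, 9.0], index=["d", "c", "b", "a", "zzz"])
        assert abs(gene_significance(x, y) - 1.0) < 1e-12

    def test_table_matches_scalar_function(self, rng):
        X = rng.standard_normal((15, 10))
        strains = [f"S{i}" for i in range(10)]
        expr = ExpressionMatrix(pd.DataFrame(X, index=[f"g{i}" for i in range(15)],
                                             columns=strains))
        traits = TraitTable(pd.DataFrame({"bmd": rng.standard_normal(10)}, index=strains))
        table = gene_significance_table(expr, traits)
        for g in expr.gene_ids:
            assert abs(table.loc[g, "bmd"] -
                       gene_significance(expr.values.loc[g], traits.values["bmd"])) < 1e-12


class TestModuleSignificance:
    def test_mean_of_gs(self):
        assert module_significance([0.42, 0.42, 0.42]) == pytest.approx(0.42)
        assert module_significance([0.2, 0.6]) == pytest.approx(0.4)

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            module_significance([])


class TestMsPvalue:
    def test_zero_ms_gives_p_one(self):
        assert ms_pvalue(0.0, 27) == 1.0

    def test_ms_040_significant_at_27_strains(self):
        # the field's rule of thumb: MS of 0.40 clears p = 0.05 with n = 27
        assert ms_pvalue(0.40, 27) < 0.05

    def test_matches_t_distribution_oracle(self):
        r, n = 0.8, 27
        t = r * np.sqrt((n - 2) / (1 - r**2))
        oracle = 2 * (1 - stats.t.cdf(t, n - 2))
        assert abs(ms_pvalue(r, n) - oracle) < 1e-10

    def test_fisher_z_variant(self):
        r, n = 0.5, 27
        z = np.arctanh(r) * np.sqrt(n - 3)
        oracle = 2 * stats.norm.sf(z)
        assert abs(ms_pvalue(r, n, method="z") - oracle) < 1e-10

    def test_strictly_decreasing_in_ms_and_n(self):
        ps = [ms_pvalue(r, 27) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        pn = [ms_pvalue(0.4, n) for n in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(pn, pn[1:]))

    def test_ms_one_reports_smallest_positive_float(self):
        import sys

        assert ms_pvalue(1.0, 27) == sys.float_info.min

    def test_critical_r_inverts_the_pvalue(self):
        r = critical_r(27, 0.05)
        assert abs(ms_pvalue(r, 27) - 0.05) < 1e-10


class TestModuleEigengene:
    def expr_of(self, X):
        return ExpressionMatrix(pd.DataFrame(
            X, index=[f"g{i}" for i in range(X.shape[0])],
            columns=[f"S{i}" for i in range(X.shape[1])]))

    def test_identical_profiles_fully_explained(self, rng):
        base = rng.standard_normal(12)
        X = np.tile(base, (5, 1)) * rng.uniform(0.5, 2.0, (5, 1))
        expr = self.expr_of(X)
        eig, ve = module_eigengene(expr, expr.gene_ids)
        assert ve == pytest.approx(1.0)
        assert abs(np.corrcoef(eig, base)[0, 1]) == pytest.approx(1.0)

    def test_orientation_follows_mean_expression(self, rng):
        X = rng.standard_normal((6, 10)) + 0.0
        expr = self.expr_of(X)
        eig, _ = module_eigengene(expr, expr.gene_ids)
        Z = ((X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True))
        assert np.dot(eig, Z.mean(0)) >= 0
        flipped, _ = module_eigengene(self.expr_of(-X), expr.gene_ids)
        assert np.allclose(flipped, -eig, atol=1e-9)

    def test_variance_explained_matches_svd_oracle(self, rng):
        X = rng.standard_normal((8, 12))
        expr = self.expr_of(X)
        _, ve = module_eigengene(expr, expr.gene_ids)
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        s = np.linalg.svd(Z, compute_uv=False)
        assert ve == pytest.approx(s[0] ** 2 / np.sum(s**2), abs=1e-12)

    def test_degenerate_module_rejected(self):
        with pytest.raises(ValueError):
            module_eigengene(self.expr_of(np.ones((3, 5))), ["g0", "g1", "g2"])


class TestTraitTraitCorrelation:
    def test_identical_trait_perfectly_correlated(self, rng):
        v = rng.standard_normal(10)
        traits = TraitTable(pd.DataFrame({"a": v, "b": v},
                                         index=[f"S{i}" for i in range(10)]))
        out = trait_trait_correlation(traits)
        row = out[(out.trait_a == "a") & (out.trait_b == "b")].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_hand_vectors_match_oracle(self):
        traits = TraitTable(pd.DataFrame({
            "a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 4.0, 3.0]},
            index=["s1", "s2", "s3", "s4"]))
        out = trait_trait_correlation(traits)
        row = out[(out.trait_a == "a") & (out.trait_b == "b")].iloc[0]
        assert row.r == pytest.approx(0.8)
        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert row.p == pytest.approx(2 * stats.t.sf(t, 2), abs=1e-12)

    def test_null_traits_yield_uniformish_pvalues(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            traits = TraitTable(pd.DataFrame(
                {"a": rng.standard_normal(27), "b": rng.standard_normal(27)},
                index=[f"S{i}" for i in range(27)]))
            out = trait_trait_correlation(traits)
            ps.append(float(out[(out.trait_a == "a") & (out.trait_b == "b")].p.iloc[0]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestModuleTraitIntegration:
    def test_trait_driving_module_attains_top_ms(self, small_panel):
        from coexqtl.network import assign_modules, correlation_matrix, soft_adjacency

        geno, expr, traits, truth = small_panel
        adj = soft_adjacency(correlation_matrix(expr), 6.0)
        assignment = assign_modules(adj)
        mt = module_trait_table(expr, assignment, traits)
        top = mt.groupby("module")["MS"].mean().idxmax()
        driven = set(truth.module_genes(truth.trait_module_id))
        assert len(set(assignment.members(top)) & driven) > len(assignment.members(top)) / 2

    def test_eigengene_and_ms_rank_modules_consistently_on_clean_data(self):
        # noise-free panel: |cor(eigengene, trait)| and MS order modules alike
        from coexqtl.simulate import SimConfig, simulate_panel
        from coexqtl.network import assign_modules, correlation_matrix, soft_adjacency

        cfg = SimConfig(n_genes=150, module_sizes=(40, 40, 40), n_modules=3,
                        n_markers_per_chr=5, noise_sd=0.0, trait_cor=0.7, seed=9)
        geno, expr, traits, truth = simulate_panel(cfg)
        adj = soft_adjacency(correlation_matrix(expr), 6.0)
        assignment = assign_modules(adj, min_module_size=20)
        mt = module_trait_table(expr, assignment, traits)
        ms_rank = mt[mt.trait == "bmd"].set_index("module")["MS"].rank()
        eig_cor = {}
        for module in assignment.module_names:
            eig, _ = module_eigengene(expr, assignment.members(module))
            eig_cor[module] = abs(np.corrcoef(eig, traits.values["bmd"])[0, 1])
        eig_rank = pd.Series(eig_cor).rank()
        assert (ms_rank.sort_index() == eig_rank.sort_index()).all()
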