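import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methagen as mg
from methagen.mixed import build_design, design_z


def toy_map(positions, chrom=None):
    m = len(positions)
    return pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else [1] * m,
            "pos": positions,
        }
    )


class TestBacksolve:
    def test_square_nonsingular_reconstructs_exactly(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((6, 6)) + np.eye(6)
        a = rng.standard_normal(6)
        beta = mg.backsolve_snp_effects(a, W, pseudo_inverse=True)
        assert np.allclose(W @ beta, a, atol=1e-10)

    def test_uniform_weight_rescaling_cancels(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((5, 12))
        d = rng.uniform(0.5, 2.0, 12)
        a = rng.standard_normal(5)
        b1 = mg.backsolve_snp_effects(a, W, d, pseudo_inverse=True)
        b2 = mg.backsolve_snp_effects(a, W, 3.5 * d, pseudo_inverse=True)
        assert np.allclose(b1, b2)

    def test_matches_minimum_norm_oracle(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((5, 8))
        d = rng.uniform(0.5, 2.0, 8)
        a = rng.standard_normal(5)
        beta = mg.backsolve_snp_effects(a, W, d)
        # explicit generalized-inverse solve in the D^1/2-scaled coordinates
        Wd = W * np.sqrt(d)
        oracle = np.sqrt(d) * (np.linalg.pinv(Wd) @ a)
        assert np.allclose(beta, oracle, atol=1e-10)
        assert np.allclose(W @ beta, a, atol=1e-8)  # m > n reconstruction

    def test_singular_without_flag_raises(self):
        W = np.ones((4, 3))  # rank 1
        with pytest.raises(np.linalg.LinAlgError):
            mg.backsolve_snp_effects(np.ones(4), W)


class TestRefineWeights:
    def test_symmetric_input_gives_uniform(self):
        d = mg.refine_weights(np.full(10, 0.3), np.full(10, 0.25))
        assert np.allclose(d, 1.0)

    def test_single_nonzero_effect_concentrates(self):
        beta = np.zeros(50)
        beta[7] = 1.0
        d = mg.refine_weights(beta, np.full(50, 0.3))
        assert d[7] == pytest.approx(50.0, rel=1e-4)
        assert d.sum() == pytest.approx(50.0)

    def test_all_zero_effects_uniform(self):
        assert np.allclose(mg.refine_weights(np.zeros(9), np.full(9, 0.2)), 1.0)

    def test_hand_formula(self):
        beta = np.array([1.0, 2.0])
        p = np.array([0.5, 0.25])
        raw = beta**2 * 2 * p * (1 - p)  # (0.5, 1.5)
        expect = raw * 2 / raw.sum()
        assert np.allclose(mg.refine_weights(beta, p), expect)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 30), st.integers(0, 10_000))
    def test_total_weight_preserved(self, m, seed):
        rng = np.random.default_rng(seed)
        beta = rng.standard_normal(m)
        p = rng.uniform(0.01, 0.5, m)
        d = mg.refine_weights(beta, p)
        assert d.sum() == pytest.approx(m)
        assert (d > 0).all()


class TestWindowVariance:
    def test_zero_effects_zero_percent(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((10, 5))
        win = mg.window_variance(np.zeros(5), W, toy_map([1, 2, 3, 4, 5]), sigma_a2=1.0)
        assert (win["variance_pct"] == 0).all()

    def test_single_window_equals_gebv_variance_ratio(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((30, 8))
        beta = rng.standard_normal(8)
        sigma_a2 = 2.5
        win = mg.window_variance(beta, W, toy_map(list(range(1, 9))), sigma_a2)
        g = W @ beta
        expect = np.var(g, ddof=1) / sigma_a2 * 100
        assert win["variance_pct"].iloc[0] == pytest.approx(expect)
        assert win["n_snps"].iloc[0] == 8

    def test_windows_anchor_at_every_snp_and_respect_span(self):
        pos = [1, 40_000, 90_000, 160_000, 300_000]
        win = mg.window_variance(np.ones(5), np.random.default_rng(0).standard_normal((12, 5)), toy_map(pos), 1.0)
        assert len(win) == 5
        assert win["n_snps"].tolist() == [3, 2, 2, 1, 1]  # [pos, pos + 100kb)

    def test_distant_independent_snps_additive(self):
        rng = np.random.default_rng(6)
        n = 4000
        W = rng.standard_normal((n, 2))
        beta = np.array([0.7, -1.1])
        win = mg.window_variance(beta, W, toy_map([1, 10_000_000]), sigma_a2=1.0)
        combined = np.var(W @ beta, ddof=1) * 100
        assert win["variance_pct"].sum() == pytest.approx(combined, rel=0.05)

    def test_unsorted_map_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            mg.window_variance(np.zeros(2), np.zeros((3, 2)), toy_map([5, 1]), 1.0)


class TestQtlRegions:
    def windows_df(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "first_snp", "last_snp", "variance_pct"]
        )

    def test_no_window_above_threshold(self):
        win = self.windows_df([(1, 0, 100_000, 2, 0, 1, 4.9)])
        assert mg.qtl_regions(win) == []

    def test_overlapping_windows_merge_with_max(self):
        win = self.windows_df(
            [
                (1, 0, 100_000, 2, 0, 1, 6.0),
                (1, 50_000, 150_000, 2, 1, 2, 9.0),
                (1, 120_000, 220_000, 2, 2, 3, 7.0),
            ]
        )
        regions = mg.qtl_regions(win)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (0, 220_000)
        assert r.max_variance_pct == 9.0
        assert r.n_snps == 4

    def test_separated_clusters_stay_separate(self):
        win = self.windows_df(
            [
                (1, 0, 100_000, 1, 0, 0, 6.0),
                (1, 500_000, 600_000, 1, 5, 5, 8.0),
                (2, 0, 100_000, 1, 10, 10, 7.0),
            ]
        )
        regions = mg.qtl_regions(win)
        assert [(r.chrom, r.start_bp) for r in regions] == [(1, 0), (1, 500_000), (2, 0)]
        assert [r.max_variance_pct for r in regions] == [6.0, 8.0, 7.0]


class TestPvalues:
    def test_zero_effect_p_one(self):
        p = mg.snp_pvalues(np.array([0.0]), np.array([1.0]))
        assert p[0] == 1.0

    def test_z_of_1p96_gives_five_percent(self):
        p = mg.snp_pvalues(np.array([1.96]), np.array([1.0]))
        assert p[0] == pytest.approx(0.05, abs=5e-4)

    def test_zero_sd_warns_and_sets_one(self):
        with pytest.warns(UserWarning, match="zero effect SD"):
            p = mg.snp_pvalues(np.array([0.5]), np.array([0.0]))
        assert p[0] == 1.0

    def test_var_beta_matches_direct_quadratic_form(self):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((6, 10))
        d = rng.uniform(0.5, 1.5, 10)
        V = rng.standard_normal((6, 6))
        V = V @ V.T
        T = (W * d) @ W.T
        Q = d[:, None] * (W.T @ np.linalg.inv(T))
        expect = np.diag(Q @ V @ Q.T)
        assert np.allclose(mg.var_beta(W, d, V), expect)


class TestBonferroni:
    @pytest.mark.parametrize("m,alpha,expect", [(10, 0.05, 0.005), (1, 0.05, 0.05)])
    def test_simple_division(self, m, alpha, expect):
        assert mg.bonferroni_threshold(m, alpha) == pytest.approx(expect)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            mg.bonferroni_threshold(0)


class TestPipeline:
    def test_zero_weight_iters_equals_single_backsolve(self, small_population):
        pop = small_population
        res0 = mg.run_ssgwas(
            pop["phenotypes"], pop["pedigree"], pop["panel"], "CH4",
            variance_components=(148.3, 102.8), n_weight_iters=0,
        )
        assert np.allclose(res0.weights, 1.0)
        # recompute the single unweighted backsolve directly
        from methagen.genomic import blend_g, h_matrix, vanraden_g
        from methagen.pedigree import nrm

        ped, panel = pop["pedigree"], pop["panel"]
        A = nrm(ped).matrix
        gi = ped.indices(panel.ids)
        grm = vanraden_g(panel)
        gstar = blend_g(grm.matrix, A[np.ix_(gi, gi)], 0.05)
        H = h_matrix(A, gi, gstar)
        X, _, rec = build_design(pop["phenotypes"], pedigree=ped)
        y = pop["phenotypes"]["CH4"].to_numpy()
        sol = mg.solve_mme(
            X, design_z(rec, ped.n), mg.h_inverse(mg.nrm_inverse(ped), A[np.ix_(gi, gi)], gstar, gi),
            148.3, 102.8, y,
        )
        W = panel.dosages - 2 * grm.freqs
        beta = mg.backsolve_snp_effects(sol.u[gi], W, relationship=(gstar, grm.scale))
        assert np.allclose(res0.snp_table.sort_index()["beta"].to_numpy(), beta, atol=1e-6)

    def test_gls_blup_equals_mme_solution(self, small_population):
        """The fast single-step solver agrees with Henderson's equations."""
        pop = small_population
        from methagen.genomic import blend_g, h_matrix, vanraden_g
        from methagen.pedigree import nrm

        ped, panel = pop["pedigree"], pop["panel"]
        A = nrm(ped).matrix
        gi = ped.indices(panel.ids)
        grm = vanraden_g(panel)
        gstar = blend_g(grm.matrix, A[np.ix_(gi, gi)], 0.05)
        H = h_matrix(A, gi, gstar)
        model = mg.SingleStepGWAS(
            pop["phenotypes"], ped, panel, "CH4", variance_components=(148.3, 102.8)
        )
        b, a_g, var_a = model._blup(H, 148.3, 102.8, want_var=True)
        X, _, rec = build_design(pop["phenotypes"], pedigree=ped)
        Hinv = mg.h_inverse(mg.nrm_inverse(ped), A[np.ix_(gi, gi)], gstar, gi)
        sol = mg.solve_mme(
            X, design_z(rec, ped.n), Hinv, 148.3, 102.8,
            pop["phenotypes"]["CH4"].to_numpy(), compute_inverse=True,
        )
        assert np.allclose(a_g, sol.u[gi], atol=1e-6)
        assert np.allclose(b, sol.b, atol=1e-6)
        # Var(a_g) identity: G* sa2 - PEV from the dense MME inverse
        p = X.shape[1]
        Cuu = sol.coeff_inverse[p:, p:][np.ix_(gi, gi)]
        var_mme = gstar * 148.3 - Cuu * 102.8
        assert np.max(np.abs(var_a - var_mme)) < 1e-6 * np.max(np.abs(var_mme))

    def test_ssgblup_reduces_to_pedigree_blup_when_g_is_a22(self, small_population):
        pop = small_population
        ped, panel = pop["pedigree"], pop["panel"]
        from methagen.pedigree import nrm

        A = nrm(ped).matrix
        gi = ped.indices(panel.ids)
        A22 = A[np.ix_(gi, gi)]
        model = mg.SingleStepGWAS(
            pop["phenotypes"], ped, panel, "CH4", variance_components=(148.3, 102.8)
        )
        H = mg.h_matrix(A, gi, A22.copy())
        _, a_h, _ = model._blup(H, 148.3, 102.8)
        _, a_a, _ = model._blup(A, 148.3, 102.8)
        assert np.allclose(a_h, a_a, atol=1e-8)

    def test_results_tables_sorted_and_deterministic(self, small_population):
        pop = small_population
        res = mg.run_ssgwas(
            pop["phenotypes"], pop["pedigree"], pop["panel"], "CH4",
            variance_components=(148.3, 102.8),
        )
        st_ = res.snp_table
        assert (st_.sort_values(["chrom", "pos"]).index == st_.index).all()
        res2 = mg.run_ssgwas(
            pop["phenotypes"], pop["pedigree"], pop["panel"], "CH4",
            variance_components=(148.3, 102.8),
        )
        pd.testing.assert_frame_equal(res.snp_table, res2.snp_table)
        assert (res.snp_table["pvalue"] > 0).all() and (res.snp_table["pvalue"] <= 1).all()

    def test_window_percents_invariant_to_weight_scale(self, small_population):
        """Uniformly rescaled SNP weights leave effects and window percents unchanged."""
        pop = small_population
        from methagen.genomic import vanraden_g

        panel = pop["panel"]
        grm = vanraden_g(panel)
        W = panel.dosages - 2 * grm.freqs
        rng = np.random.default_rng(8)
        d = rng.uniform(0.5, 2.0, panel.n_snps)
        a = rng.standard_normal(panel.n_animals)
        b1 = mg.backsolve_snp_effects(a, W, d, pseudo_inverse=True)
        b2 = mg.backsolve_snp_effects(a, W, 4.0 * d, pseudo_inverse=True)
        w1 = mg.window_variance(b1, W, panel.snp_map, 148.3)
        w2 = mg.window_variance(b2, W, panel.snp_map, 148.3)
        pd.testing.assert_frame_equal(w1, w2)
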