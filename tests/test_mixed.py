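import numpy as np
import pandas as pd
import pytest

import methagen as mg
from methagen.mixed import design_z, reml_loglik_dense


@pytest.fixture()
def toy_data():
    """30 records on 30 animals from a random pedigree, known components."""
    rng = np.random.default_rng(21)
    triples = [(f"F{i}", "0", "0") for i in range(10)]
    for i in range(20):
        s, d = rng.choice(10, size=2, replace=False)
        triples.append((f"A{i}", f"F{s}", f"F{d}"))
    ped = mg.Pedigree.from_triples(triples)
    K = mg.nrm(ped).matrix
    n = ped.n
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    su2, se2 = 2.0, 3.0
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
    u = L @ rng.standard_normal(n) * np.sqrt(su2)
    y = X @ np.array([1.0, 0.5]) + u + rng.standard_normal(n) * np.sqrt(se2)
    return ped, K, X, y, su2, se2


class TestBuildDesign:
    def test_indicators_plus_centered_age(self):
        phen = pd.DataFrame(
            {"animal_id": list("abcd"), "cg": ["g1", "g1", "g2", "g2"], "age": [250.0, 260, 270, 280]}
        )
        X, names, _ = mg.build_design(phen)
        assert X.shape == (4, 3)
        assert np.linalg.matrix_rank(X) == 3
        assert X[:, -1].sum() == pytest.approx(0.0)  # centered age
        assert (X[:, :2].sum(axis=1) == 1).all()  # one group per record

    def test_saturated_design_warns(self):
        phen = pd.DataFrame({"animal_id": list("abc"), "cg": list("xyz"), "age": [1.0, 2, 3]})
        with pytest.warns(UserWarning, match="saturated"):
            mg.build_design(phen)

    def test_hand_built_indicator_matrix(self):
        phen = pd.DataFrame(
            {"animal_id": list("abcde"), "cg": ["u", "v", "u", "w", "v"], "age": [1.0, 2, 3, 4, 5]}
        )
        X, names, _ = mg.build_design(phen)
        expected = np.zeros((5, 3))
        for i, g in enumerate(["u", "v", "u", "w", "v"]):
            expected[i, ["u", "v", "w"].index(g)] = 1
        assert np.array_equal(X[:, :3], expected)

    def test_unknown_animal_errors(self, trio):
        phen = pd.DataFrame({"animal_id": ["ghost"], "cg": ["g"], "age": [1.0]})
        with pytest.raises(mg.PedigreeError):
            mg.build_design(phen, pedigree=trio)


class TestSolveMme:
    def test_infinite_shrinkage_zeroes_breeding_values(self, toy_data):
        ped, K, X, y, *_ = toy_data
        Z = np.eye(ped.n)
        sol = mg.solve_mme(X, Z, np.linalg.inv(K), sigma_u2=1e-8, sigma_e2=1.0, y=y)
        assert np.linalg.norm(sol.u) < 1e-3

    def test_ridge_oracle_identity_kinship(self):
        rng = np.random.default_rng(9)
        n = 25
        X = np.ones((n, 1))
        Z = np.eye(n)
        y = rng.standard_normal(n) + 3.0
        su2, se2 = 1.5, 2.5
        lam = se2 / su2
        sol = mg.solve_mme(X, Z, np.eye(n), su2, se2, y)
        # closed-form ridge given the fixed-effect GLS solution
        V = Z @ Z.T * su2 + np.eye(n) * se2
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = su2 * Z.T @ Vi @ (y - X @ b)
        assert np.allclose(sol.b, b)
        assert np.allclose(sol.u, u)

    def test_gls_oracle_with_pedigree_kinship(self, toy_data):
        ped, K, X, y, su2, se2 = toy_data
        Z = np.eye(ped.n)
        sol = mg.solve_mme(X, Z, np.linalg.inv(K), su2, se2, y)
        V = K * su2 + np.eye(ped.n) * se2
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(sol.b, b, atol=1e-8)

    def test_animals_without_records_predicted_through_kinship(self, toy_data):
        ped, K, X, y, su2, se2 = toy_data
        rec = np.arange(10, ped.n)  # only non-founders recorded
        Z = design_z(rec, ped.n)
        sol = mg.solve_mme(X[rec], Z, np.linalg.inv(K), su2, se2, y[rec])
        founder_u = sol.u[:10]
        assert np.linalg.norm(founder_u) > 0  # founders picked up via kinship

    def test_confounded_columns_named(self, toy_data):
        ped, K, X, y, su2, se2 = toy_data
        Xbad = np.column_stack([X, X[:, 0]])
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            mg.solve_mme(
                Xbad, np.eye(ped.n), np.linalg.inv(K), su2, se2, y,
                column_names=["int", "x", "dup"],
            )


class TestRemlSingle:
    def test_grid_search_oracle(self, toy_data):
        """REML optimum matches a dense log-likelihood grid (60 records)."""
        rng = np.random.default_rng(33)
        ped, K, X, y, su2, se2 = toy_data
        n = 60
        # build 60 records on the 30 animals (2 each) -> use Kronecker lift
        rec = np.tile(np.arange(ped.n), 2)
        Z = design_z(rec, ped.n)
        M = K[np.ix_(rec, rec)]
        Xr = np.column_stack([np.ones(n), rng.standard_normal(n)])
        L = np.linalg.cholesky(K + 1e-10 * np.eye(ped.n))
        u = L @ rng.standard_normal(ped.n) * np.sqrt(2.0)
        yr = Xr @ np.array([1.0, -0.3]) + u[rec] + rng.standard_normal(n) * np.sqrt(3.0)

        vc = mg.reml_single(yr, Xr, M)
        grid = np.linspace(0.2, 8.0, 40)
        best, best_ll = None, -np.inf
        for gu in grid:
            for ge in grid:
                V = M * gu + np.eye(n) * ge
                ll = reml_loglik_dense(yr, Xr, V)
                if ll > best_ll:
                    best, best_ll = (gu, ge), ll
        step = grid[1] - grid[0]
        assert abs(vc.sigma_u2 - best[0]) <= step
        assert abs(vc.sigma_e2 - best[1]) <= step
        assert vc.loglik >= best_ll - 1e-6

    def test_null_heritability_recovery(self):
        """Data with no genetic variance: h2 estimated near zero."""
        hits = 0
        for r in range(6):
            cfg = mg.PopulationConfig(
                n_sires=100, progeny_per_sire=10, n_cg=20, n_chromosomes=1, n_snps_per_chrom=10,
                traits={"T": mg.TraitSpec(10.0, 1e-6, 1.0, cg_sd=0.5)}, seed=400 + r,
            )
            ped, meta = mg.simulate_pedigree(cfg)
            phen, _ = mg.simulate_phenotypes(ped, meta, cfg, np.random.default_rng(cfg.seed))
            res = mg.AnimalModel.from_dataframe(phen, "T", ped).fit()
            hits += res.h2 < 0.05
        assert hits >= 5

    def test_a_and_h_paths_identical_when_g_is_a22(self, small_population):
        pop = small_population
        ped, panel = pop["pedigree"], pop["panel"]
        A = mg.nrm(ped).matrix
        gi = ped.indices(panel.ids)
        H = mg.h_matrix(A, gi, A[np.ix_(gi, gi)].copy())
        assert np.max(np.abs(H - A)) < 1e-8
        fit_a = mg.AnimalModel.from_dataframe(pop["phenotypes"], "CH4", ped, kinship=A).fit()
        fit_h = mg.AnimalModel.from_dataframe(pop["phenotypes"], "CH4", ped, kinship=H).fit()
        assert fit_a.sigma_u2 == pytest.approx(fit_h.sigma_u2, abs=1e-6)
        assert fit_a.sigma_e2 == pytest.approx(fit_h.sigma_e2, abs=1e-6)

    def test_loglik_trace_non_decreasing(self, small_population):
        res = mg.AnimalModel.from_dataframe(
            small_population["phenotypes"], "CH4", small_population["pedigree"]
        ).fit()
        lls = [ll for _, ll in res.vc.trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_mme_solution_matches_reml_blup(self, small_population):
        """BLUP from the fitted model equals the MME solution at the same components."""
        pop = small_population
        ped = pop["pedigree"]
        res = mg.AnimalModel.from_dataframe(pop["phenotypes"], "CH4", ped).fit()
        X, names, rec_idx = mg.build_design(pop["phenotypes"], pedigree=ped)
        Z = design_z(rec_idx, ped.n)
        sol = mg.solve_mme(
            X, Z, mg.nrm_inverse(ped), res.sigma_u2, res.sigma_e2,
            pop["phenotypes"]["CH4"].to_numpy(),
        )
        assert np.allclose(sol.u, res.u, atol=1e-6)
        assert np.allclose(sol.b, res.b, atol=1e-6)


class TestRemlBivariate:
    def test_duplicated_trait_hits_unit_correlations_without_crash(self):
        cfg = mg.PopulationConfig(
            n_sires=60, progeny_per_sire=6, n_cg=10, n_chromosomes=1, n_snps_per_chrom=10,
            traits={"T": mg.TraitSpec(10.0, 2.0, 2.0, cg_sd=0.5)}, seed=600,
        )
        ped, meta = mg.simulate_pedigree(cfg)
        phen, _ = mg.simulate_phenotypes(ped, meta, cfg, np.random.default_rng(cfg.seed))
        phen["T2"] = phen["T"]
        vc = mg.BivariateAnimalModel.from_dataframe(phen, ("T", "T2"), ped).fit()
        assert vc.genetic_correlation > 0.99
        # the likelihood ridge may drain the residual covariance to ~0
        # instead of driving its correlation to 1; both are boundary-valid
        assert vc.residual_correlation > 0.99 or vc.R0[0, 0] < 1e-3 * vc.G0[0, 0]

    def test_null_genetic_correlation(self):
        ests = []
        for r in range(4):
            cfg = mg.PopulationConfig(
                n_sires=150, progeny_per_sire=8, n_cg=20, n_chromosomes=1, n_snps_per_chrom=10,
                traits={
                    "T1": mg.TraitSpec(10.0, 4.0, 6.0, cg_sd=1.0),
                    "T2": mg.TraitSpec(50.0, 9.0, 9.0, cg_sd=2.0),
                },
                seed=700 + r,
            )
            ped, meta = mg.simulate_pedigree(cfg)
            phen, _ = mg.simulate_phenotypes(ped, meta, cfg, np.random.default_rng(cfg.seed))
            vc = mg.BivariateAnimalModel.from_dataframe(phen, ("T1", "T2"), ped).fit()
            ests.append(vc.genetic_correlation)
        mean = np.mean(ests)
        mcse = np.std(ests, ddof=1) / 2
        assert abs(mean) <= max(2 * mcse, 0.15)

    def test_moderate_correlation_recovery(self):
        gc = np.array([[1.0, 0.5], [0.5, 1.0]])
        rc = np.array([[1.0, 0.2], [0.2, 1.0]])
        ests = []
        for r in range(4):
            cfg = mg.PopulationConfig(
                n_sires=200, progeny_per_sire=8, n_cg=30, n_chromosomes=1, n_snps_per_chrom=10,
                traits={
                    "T1": mg.TraitSpec(10.0, 4.0, 6.0, cg_sd=1.0),
                    "T2": mg.TraitSpec(50.0, 9.0, 9.0, cg_sd=2.0),
                },
                genetic_corr=gc, residual_corr=rc, seed=50 + r,
            )
            ped, meta = mg.simulate_pedigree(cfg)
            phen, _ = mg.simulate_phenotypes(ped, meta, cfg, np.random.default_rng(cfg.seed))
            vc = mg.BivariateAnimalModel.from_dataframe(phen, ("T1", "T2"), ped).fit()
            assert vc.converged
            ests.append(vc.genetic_correlation)
        assert abs(np.mean(ests) - 0.5) < 0.15
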