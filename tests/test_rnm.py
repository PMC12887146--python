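import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from heatnorm import kinship, rnm, simulate
from heatnorm.rnm import ChainConfig, GeneticCovariances, ModelSpec


class TestLegendre:
    def test_midpoint_order_one(self):
        row = rnm.legendre_row(70.0, 60, 80, 1)
        assert row == pytest.approx([np.sqrt(0.5), 0.0])

    def test_upper_end_order_one(self):
        row = rnm.legendre_row(80.0, 60, 80, 1)
        assert row == pytest.approx([0.70710678, 1.22474487])

    def test_lower_end_order_three(self):
        row = rnm.legendre_row(5.0, 5, 305, 3)
        assert row == pytest.approx([0.70710678, -1.22474487, 1.58113883, -1.87082869])

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rnm.legendre_row(3.0, 5, 305, 3)


def small_covs(resid=1.0):
    return GeneticCovariances(
        G_dim=np.eye(4) * 0.5,
        G_thi=np.array([[0.4, 0.05], [0.05, 0.2]]),
        G_cross=np.zeros((4, 2)),
        P_dim=np.eye(4) * 0.3,
        P_thi=np.eye(2) * 0.2,
        P_cross=np.zeros((4, 2)),
        resid_var=np.full(6, resid),
    )


def toy_frame(rng, n_animals=5, n_records=20):
    ped = kinship.Pedigree(
        np.array([f"a{i}" for i in range(n_animals)], dtype=object),
        np.full(n_animals, -1),
        np.full(n_animals, -1),
    )
    rec = pd.DataFrame(
        {
            "animal": [f"a{i % n_animals}" for i in range(n_records)],
            "herd": "h1",
            "date": pd.Timestamp("2005-06-01"),
            "dim": rng.integers(5, 306, n_records),
            "milk_kg": rng.normal(8, 2, n_records),
            "age_months": rng.uniform(24, 50, n_records),
            "milking_freq": "2x",
            "cg": "g1",
        }
    )
    rec["dim_class"] = [((d - 5) // 50) + 1 if d < 255 else 6 for d in rec["dim"]]
    rec["dim_class"] = rec["dim_class"].clip(upper=6)
    rec["thi_class"] = rng.choice(np.arange(60, 81, 2), n_records)
    from heatnorm.editing import assign_residual_class

    rec["resid_class"] = assign_residual_class(
        rec["dim_class"].to_numpy(), rec["thi_class"].to_numpy()
    )
    return rnm.build_model_frame(rec, ped), ped, rec


class TestModelFrame:
    def test_random_effect_row_closed_form(self, rng):
        frame, ped, _ = toy_frame(rng, n_animals=2, n_records=4)
        rec = pd.DataFrame(
            {
                "animal": ["a0"],
                "herd": ["h1"],
                "date": [pd.Timestamp("2005-06-01")],
                "dim": [155],
                "milk_kg": [8.0],
                "age_months": [30.0],
                "cg": ["g1"],
                "dim_class": [4],
                "thi_class": [70],
                "resid_class": [4],
            }
        )
        f = rnm.build_model_frame(rec, ped)
        za = f.W[:, f.n_fixed : f.n_fixed + 6].toarray()[0]
        assert za == pytest.approx([0.70710678, 0, -0.79056942, 0, 0.70710678, 0])

    def test_empty_records_conformable(self, rng):
        frame, ped, rec = toy_frame(rng)
        empty = pd.DataFrame(
            columns=["animal", "herd", "date", "dim", "milk_kg", "age_months",
                     "cg", "dim_class", "thi_class", "resid_class"]
        )
        f = rnm.build_model_frame(empty, ped)
        assert f.W.shape[0] == 0
        assert f.W.shape[1] == f.n_fixed + 6 * len(ped)

    def test_fixed_column_count(self, rng):
        frame, _, _ = toy_frame(rng, n_animals=4, n_records=30)
        # cg (1) + mfreq x dimclass (levels - 1) + age (2) + herd-2yr (3) + thi-in-dimc
        n_dimc = frame.fixed_names
        counted = (
            1
            + sum(1 for n in n_dimc if n.startswith("mfreq"))
            + 2
            + 3
            + sum(1 for n in n_dimc if n.startswith("thi_in"))
        )
        assert frame.n_fixed == counted


def dense_mme_solution(frame, covs, kinv_dense):
    """Independent dense MME oracle built with numpy kron."""
    W = frame.W.toarray()
    Rinv = np.diag(1.0 / covs.resid_var[frame.resid_class])
    Ga_inv = np.linalg.inv(covs.joint_additive)
    P_inv = np.linalg.inv(covs.joint_pe)
    nf = frame.n_fixed
    Q = np.zeros((frame.n_coef, frame.n_coef))
    na = 6 * frame.n_ped
    Q[nf : nf + na, nf : nf + na] = np.kron(kinv_dense, Ga_inv)
    Q[nf + na :, nf + na :] = np.kron(np.eye(frame.n_rec_animals), P_inv)
    C = W.T @ Rinv @ W + Q
    rhs = W.T @ Rinv @ frame.y
    return np.linalg.lstsq(C, rhs, rcond=None)[0]


class TestSolveMme:
    def test_matches_dense_oracle(self, rng):
        frame, ped, rec = toy_frame(rng)
        covs = small_covs()
        Ainv, _ = kinship.build_A_inverse(ped)
        sol = rnm.solve_mme(frame, covs, Ainv)
        theta = np.concatenate([sol.fixed, sol.additive.ravel(), sol.pe.ravel()])
        oracle = dense_mme_solution(frame, covs, Ainv.toarray())
        assert np.abs(theta - oracle).max() < 1e-6

    def test_gls_limit_intercept_is_weighted_mean(self, rng):
        frame, ped, rec = toy_frame(rng)
        covs = small_covs(resid=2.0)
        # shrink random effects to zero: intercept-only GLS limit
        tiny = GeneticCovariances(
            G_dim=np.eye(4) * 1e-8, G_thi=np.eye(2) * 1e-8, G_cross=np.zeros((4, 2)),
            P_dim=np.eye(4) * 1e-8, P_thi=np.eye(2) * 1e-8, P_cross=np.zeros((4, 2)),
            resid_var=covs.resid_var,
        )
        Ainv, _ = kinship.build_A_inverse(ped)
        sol = rnm.solve_mme(frame, tiny, Ainv)
        # single CG carries the intercept; remaining fixed effects perturb it,
        # so compare fitted values to records instead
        fitted = frame.W @ np.concatenate(
            [sol.fixed, sol.additive.ravel(), sol.pe.ravel()]
        )
        resid = frame.y - fitted
        # residuals must be orthogonal to the fixed design under R^-1
        X = frame.W[:, : frame.n_fixed].toarray()
        w = 1.0 / covs.resid_var[frame.resid_class]
        assert np.abs(X.T @ (w * resid)).max() < 1e-6

    def test_record_duplication_sufficiency(self, rng):
        # duplicating every record while doubling the residual variances
        # carries identical information, so the solutions are unchanged
        frame, ped, rec = toy_frame(rng)
        covs = small_covs(resid=1.0)
        Ainv, _ = kinship.build_A_inverse(ped)
        sol1 = rnm.solve_mme(frame, covs, Ainv)
        rec2 = pd.concat([rec] * 2, ignore_index=True)
        f2 = rnm.build_model_frame(rec2, ped)
        sol2 = rnm.solve_mme(f2, small_covs(resid=2.0), Ainv)
        assert np.abs(sol1.additive - sol2.additive).max() < 1e-5


class TestChainBookkeeping:
    def test_published_configuration_retains_4000(self):
        cfg = ChainConfig(length=1_000_000, burn_in=600_000, thin=100)
        assert cfg.n_retained == 4000

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ChainConfig(length=100, burn_in=100, thin=1)
        with pytest.raises(ValueError):
            ChainConfig(length=100, burn_in=50, thin=0)


class TestGibbs:
    def test_seed_determinism_and_pedigree_equivalence(self, rng):
        sc = simulate.SimScenario(n_founders=30, n_generations=1, n_herds=2, seed=7)
        sim = simulate.simulate_dataset(sc)
        frame = rnm.build_model_frame(sim.records, sim.ped)
        Ainv, _ = kinship.build_A_inverse(sim.ped)
        cfg = ChainConfig(length=400, burn_in=200, thin=10)
        p1, s1 = rnm.gibbs_sample(frame, Ainv, cfg, seed=5)
        p2, s2 = rnm.gibbs_sample(frame, Ainv, cfg, seed=5)
        assert np.array_equal(p1.additive, p2.additive)
        assert np.array_equal(s1.additive, s2.additive)
        # H^-1 with no genotyped animals is A^-1: bitwise identical chain
        Hinv = kinship.build_H_inverse(
            Ainv, np.zeros((0, 0)), np.zeros((0, 0)), np.array([], dtype=int)
        )
        p3, _ = rnm.gibbs_sample(frame, Hinv, cfg, seed=5)
        assert np.array_equal(p1.additive, p3.additive)

    def test_posterior_mean_solutions_track_solve_mme(self, rng):
        sc = simulate.SimScenario(n_founders=40, n_generations=1, n_herds=2, seed=9)
        sim = simulate.simulate_dataset(sc)
        frame = rnm.build_model_frame(sim.records, sim.ped)
        Ainv, _ = kinship.build_A_inverse(sim.ped)
        cfg = ChainConfig(length=3000, burn_in=1000, thin=5)
        post, sol = rnm.gibbs_sample(frame, Ainv, cfg, seed=2)
        ref = rnm.solve_mme(frame, post.mean_covariances(), Ainv)
        r = np.corrcoef(sol.additive.ravel(), ref.additive.ravel())[0, 1]
        assert r > 0.95

    def test_sampled_matrices_positive_definite(self, rng):
        sc = simulate.SimScenario(n_founders=30, n_generations=1, n_herds=2, seed=3)
        sim = simulate.simulate_dataset(sc)
        frame = rnm.build_model_frame(sim.records, sim.ped)
        Ainv, _ = kinship.build_A_inverse(sim.ped)
        post, _ = rnm.gibbs_sample(
            frame, Ainv, ChainConfig(length=300, burn_in=100, thin=5), seed=1
        )
        for s in range(post.n_retained):
            assert np.linalg.eigvalsh(post.additive[s]).min() > 0
            assert np.linalg.eigvalsh(post.pe[s]).min() > 0
            assert post.resid[s].min() > 0


class TestDiagnostics:
    def test_iid_chain(self):
        x = np.random.default_rng(0).standard_normal(5000)
        assert abs(rnm.geweke_z(x)) < 3.0
        ess = rnm.effective_sample_size(x)
        assert 0.8 * 5000 < ess < 1.25 * 5000

    def test_constant_chain(self):
        x = np.ones(200)
        assert rnm.geweke_z(x) == 0.0
        assert rnm.effective_sample_size(x) == 200.0

    def test_ar1_effective_size(self):
        rho = 0.9
        g = np.random.default_rng(1)
        n = 20000
        x = np.empty(n)
        x[0] = g.standard_normal()
        e = g.standard_normal(n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + e[i]
        expected = n * (1 - rho) / (1 + rho)
        assert rnm.effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_ess_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        x = np.random.default_rng(3).standard_normal(4000)
        ours = rnm.effective_sample_size(x)
        theirs = float(arviz.ess(x))
        assert ours == pytest.approx(theirs, rel=0.25)

    def test_hpd_contains_mass(self):
        x = np.random.default_rng(4).standard_normal(10000)
        lo, hi = rnm.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.15)
        assert hi == pytest.approx(1.96, abs=0.15)
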