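import numpy as np
import pandas as pd
import pytest

from heatnorm import editing, kinship, simulate, thermal
from heatnorm.rnm import GeneticCovariances
from heatnorm.simulate import SimScenario


class TestPedigreeSimulation:
    def test_degenerate_no_generations(self):
        ped = simulate.simulate_pedigree(
            SimScenario(n_founders=2, n_generations=0), np.random.default_rng(0)
        )
        assert len(ped.ped) == 2
        assert ped.ped.is_founder.all()

    def test_seed_determinism(self):
        a = simulate.simulate_pedigree(SimScenario(n_founders=10, n_generations=3),
                                       np.random.default_rng(1))
        b = simulate.simulate_pedigree(SimScenario(n_founders=10, n_generations=3),
                                       np.random.default_rng(1))
        assert np.array_equal(a.ped.sire, b.ped.sire)
        assert np.array_equal(a.ped.dam, b.ped.dam)

    def test_output_passes_pedigree_validator(self):
        info = simulate.simulate_pedigree(SimScenario(n_founders=20, n_generations=2),
                                          np.random.default_rng(2))
        # constructor enforces the invariants (parents precede offspring)
        kinship.Pedigree(info.ped.ids, info.ped.sire, info.ped.dam)
        assert len(info.ped) == 60

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            SimScenario(n_founders=1)


class TestGenotypeSimulation:
    def test_mendelian_consistency(self):
        info = simulate.simulate_pedigree(SimScenario(n_founders=30, n_generations=2),
                                          np.random.default_rng(3))
        g = simulate.simulate_genotypes(info, SimScenario(n_founders=30, n_snps=50),
                                        np.random.default_rng(3))
        X = g.X
        for i in range(len(info.ped)):
            s, d = info.ped.sire[i], info.ped.dam[i]
            if s < 0 or d < 0:
                continue
            both0 = (X[s] == 0) & (X[d] == 0)
            both2 = (X[s] == 2) & (X[d] == 2)
            assert np.all(X[i][both0] == 0)
            assert np.all(X[i][both2] == 2)

    def test_realised_founder_frequency(self):
        sc = SimScenario(n_founders=500, n_generations=0, n_snps=200)
        rng = np.random.default_rng(7)
        info = simulate.simulate_pedigree(sc, rng)
        # reproduce the drawn frequencies with the same stream position
        rng2 = np.random.default_rng(7)
        simulate.simulate_pedigree(sc, rng2)
        p_drawn = rng2.uniform(*sc.maf_range, size=sc.n_snps)
        g = simulate.simulate_genotypes(info, sc, rng)
        assert np.abs(g.allele_freq() - p_drawn).max() < 0.05


class TestCoefficientSimulation:
    def test_zero_matrix_zero_vectors(self):
        info = simulate.simulate_pedigree(SimScenario(n_founders=10, n_generations=1),
                                          np.random.default_rng(0))
        covs = GeneticCovariances(
            G_dim=np.zeros((4, 4)), G_thi=np.zeros((2, 2)), G_cross=np.zeros((4, 2)),
            P_dim=np.eye(4), P_thi=np.eye(2), P_cross=np.zeros((4, 2)),
            resid_var=np.ones(6),
        )
        a, _ = simulate.simulate_coefficients(info.ped, covs, np.random.default_rng(1))
        assert np.allclose(a, 0.0)

    def test_founder_sample_covariance(self):
        sc = SimScenario(n_founders=10000, n_generations=0)
        info = simulate.simulate_pedigree(sc, np.random.default_rng(5))
        covs = simulate.default_true_covariances()
        a, _ = simulate.simulate_coefficients(info.ped, covs, np.random.default_rng(5))
        S = np.cov(a.T)
        target = covs.joint_additive
        err = np.linalg.norm(S - target) / np.linalg.norm(target)
        assert err < 0.10

    def test_full_sib_intercept_correlation(self):
        # many independent full-sib pairs; their coefficients correlate ~0.5
        n_pairs = 2000
        ids = []
        sire, dam = [], []
        for k in range(n_pairs):
            base = 4 * k
            ids += [f"s{k}", f"d{k}", f"x{k}", f"y{k}"]
            sire += [-1, -1, base, base]
            dam += [-1, -1, base + 1, base + 1]
        ped = kinship.Pedigree(np.array(ids, dtype=object), np.array(sire), np.array(dam))
        covs = simulate.default_true_covariances()
        a, _ = simulate.simulate_coefficients(ped, covs, np.random.default_rng(6))
        x = a[2::4, 0]
        y = a[3::4, 0]
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.5, abs=0.06)


class TestTestDayRecords:
    def test_all_zero_scenario_gives_zero_records(self):
        zero = GeneticCovariances(
            G_dim=np.zeros((4, 4)), G_thi=np.zeros((2, 2)), G_cross=np.zeros((4, 2)),
            P_dim=np.zeros((4, 4)), P_thi=np.zeros((2, 2)), P_cross=np.zeros((4, 2)),
            resid_var=np.full(6, 1e-18),
        )
        sc = SimScenario(n_founders=20, n_generations=1, n_herds=2, mean_yield=0.0,
                         cg_sd=0.0, fixed_scale=0.0, true_covariances=zero, seed=3)
        sim = simulate.simulate_dataset(sc)
        assert np.abs(sim.records["milk_kg"]).max() < 1e-6

    def test_residual_only_class_variances(self):
        zero_gen = GeneticCovariances(
            G_dim=np.zeros((4, 4)), G_thi=np.zeros((2, 2)), G_cross=np.zeros((4, 2)),
            P_dim=np.zeros((4, 4)), P_thi=np.zeros((2, 2)), P_cross=np.zeros((4, 2)),
            resid_var=np.array([3.5, 3.0, 2.8, 2.6, 3.0, 2.7]),
        )
        sc = SimScenario(n_founders=3000, n_generations=0, n_herds=6, mean_yield=0.0,
                         cg_sd=0.0, fixed_scale=0.0, true_covariances=zero_gen, seed=4)
        sim = simulate.simulate_dataset(sc)
        rec = sim.records
        for cls in range(1, 7):
            sel = rec["resid_class"] == cls
            assert sel.sum() > 300
            v = rec.loc[sel, "milk_kg"].var()
            assert v == pytest.approx(zero_gen.resid_var[cls - 1], rel=0.10)

    def test_doubling_slope_variance_doubles_reaction_norm_spread(self):
        covs = simulate.default_true_covariances()
        covs2 = simulate.replace_slope_variance(covs, 2 * covs.G_thi[1, 1])
        rng = np.random.default_rng(8)
        info = simulate.simulate_pedigree(SimScenario(n_founders=4000, n_generations=0), rng)
        a1, _ = simulate.simulate_coefficients(info.ped, covs, np.random.default_rng(9))
        a2, _ = simulate.simulate_coefficients(info.ped, covs2, np.random.default_rng(9))
        from heatnorm.rnm import ModelSpec, phi_thi

        spec = ModelSpec()
        thi = np.arange(60, 81, 2, dtype=float)
        Pt = phi_thi(thi, spec)

        def across_thi_var(a):
            norms = a[:, 4:] @ Pt.T  # (n, 11) true reaction norms
            return norms.var(axis=1).mean()

        # slope drives the across-THI spread; intercept adds none
        base = across_thi_var(a1)
        doubled = across_thi_var(a2)
        assert doubled == pytest.approx(2 * base, rel=0.05)

    def test_generated_records_survive_editing(self):
        # founder cows have unknown parents, so only their lactations fall to
        # the known-parent rule; everything else passes (rare >3 SD draws aside)
        sc = SimScenario(n_founders=60, n_generations=1, n_herds=2, seed=11)
        sim = simulate.simulate_dataset(sc)
        raw = sim.records.drop(columns=["cg", "dim_class", "resid_class"])
        out, rep = editing.edit_records(raw, sim.parents, min_cg_size=1)
        founders = set(sim.ped.ids[sim.ped.is_founder])
        n_founder_records = raw["animal"].isin(founders).sum()
        steps = {s["rule"]: s["records_removed"] for s in rep.steps}
        assert steps["at least one known parent"] == n_founder_records
        non_parent_removals = rep.total_removed - n_founder_records
        assert non_parent_removals <= 0.01 * len(raw)
        assert not out["animal"].isin(founders).any()

    def test_thi_structure_matches_study_conditions(self):
        sim = simulate.simulate_dataset(SimScenario(seed=1))
        thi = sim.records["thi"]
        assert thi.min() > 55 and thi.max() < 85
        assert 0.6 < (thi > 70).mean() < 0.8
        assert sim.records["thi_class"].nunique() == 11

    def test_genotyped_subset_is_youngest(self):
        sim = simulate.simulate_dataset(SimScenario(n_founders=40, n_generations=2, seed=2))
        births = sim.pedinfo.birth_dates
        genotyped = set(sim.genotyped_ids)
        oldest_genotyped = births.loc[list(genotyped)].min()
        not_genotyped = births.drop(list(genotyped))
        assert (not_genotyped <= oldest_genotyped).all()


class TestWriters:
    def test_round_trip(self, tmp_path):
        sim = simulate.simulate_dataset(
            SimScenario(n_founders=20, n_generations=1, n_snps=30, n_herds=2, seed=5)
        )
        simulate.write_dataset(sim, tmp_path)
        geno = kinship.read_plink_raw(tmp_path / "genotypes.raw", tmp_path / "genotypes.map")
        assert np.array_equal(geno.X, sim.genotypes.X)
        assert list(geno.ids) == list(sim.genotypes.ids)
        ped = kinship.Pedigree.from_frame(pd.read_csv(tmp_path / "pedigree.csv"))
        assert len(ped) == len(sim.ped)
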