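import numpy as np
import pandas as pd
import pytest

from heatnorm import gwas, kinship
from heatnorm.kinship import GenotypeMatrix


def _geno(rng, n=8, m=12, chrom=None):
    # intermediate-frequency draws; redraw any monomorphic column
    X = rng.binomial(2, 0.5, size=(n, m)).astype(np.int8)
    for j in range(m):
        while X[:, j].min() == X[:, j].max():
            X[:, j] = rng.binomial(2, 0.5, size=n)
    return GenotypeMatrix(
        ids=np.array([f"g{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"s{j}" for j in range(m)]),
        chrom=np.array(chrom if chrom is not None else [1] * m, dtype=object),
        pos=np.arange(1, m + 1) * 100_000,
        X=X,
    )


class TestBacksolve:
    def test_zero_gebvs_zero_effects(self, rng):
        g = _geno(rng)
        p = g.allele_freq()
        Z = kinship.center_dosages(g, p)
        G = kinship.build_G(g, p=p)
        u = gwas.backsolve_snp_effects(np.zeros(8), G + 1e-6 * np.eye(8), Z, None, p)
        assert np.allclose(u, 0.0)

    def test_projection_identity_full_rank(self, rng):
        # more SNPs than animals, external allele frequencies (sample-centred
        # Z would satisfy Z'1 = 0, making G exactly singular)
        g = _geno(rng, n=4, m=10)
        p = np.full(10, 0.5)
        Z = kinship.center_dosages(g, p)
        G = kinship.build_G(g, p=p)
        assert np.linalg.matrix_rank(G) == 4
        a = rng.normal(size=4)
        u = gwas.backsolve_snp_effects(a, G, Z, None, p)
        assert np.abs(Z @ u - a).max() < 1e-8

    def test_linearity(self, rng):
        g = _geno(rng, n=4, m=10)
        p = np.full(10, 0.5)
        Z = kinship.center_dosages(g, p)
        G = kinship.build_G(g, p=p)
        a = rng.normal(size=4)
        u1 = gwas.backsolve_snp_effects(a, G, Z, None, p)
        u2 = gwas.backsolve_snp_effects(2 * a, G, Z, None, p)
        assert np.allclose(u2, 2 * u1)


class TestUpdateWeights:
    def test_uniform_inputs_uniform_weights(self):
        p = np.full(10, 0.5)
        u = np.full(10, 0.3)
        assert np.allclose(gwas.update_weights(u, p), 1.0)

    def test_proportional_to_squared_effect(self):
        p = np.full(3, 0.5)
        u = np.array([1.0, 1.0, np.sqrt(10.0)])
        d = gwas.update_weights(u, p)
        assert d[2] / d[0] == pytest.approx(10.0)

    def test_rescaled_to_snp_count(self, rng):
        p = rng.uniform(0.05, 0.5, 25)
        u = rng.normal(size=25)
        assert gwas.update_weights(u, p).sum() == pytest.approx(25.0)

    def test_all_zero_effects_warn_uniform(self):
        with pytest.warns(UserWarning):
            d = gwas.update_weights(np.zeros(5), np.full(5, 0.3))
        assert np.allclose(d, 1.0)


class TestWindowVariance:
    def test_sliding_count(self, rng):
        g = _geno(rng, n=10, m=12)
        snp_map = pd.DataFrame({"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos})
        Z = kinship.center_dosages(g)
        w = gwas.window_variance(rng.normal(size=12), Z, snp_map)
        assert len(w) == 12 - 4

    def test_single_source_window_dominates(self, rng):
        g = _geno(rng, n=40, m=20)
        Z = kinship.center_dosages(g)
        snp_map = pd.DataFrame({"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos})
        u = np.zeros(20)
        u[5:10] = rng.normal(size=5)
        w = gwas.window_variance(u, Z, snp_map)
        source = w[w["snp_indices"].apply(lambda s: s == list(range(5, 10)))]
        assert source["share_pct"].iloc[0] == pytest.approx(100.0, abs=15.0)
        top = w.loc[w["share_pct"].idxmax()]
        assert set(top["snp_indices"]) & set(range(5, 10))

    def test_windows_do_not_cross_chromosomes(self, rng):
        chrom = [1] * 7 + [2] * 5
        g = _geno(rng, n=10, m=12, chrom=chrom)
        snp_map = pd.DataFrame({"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos})
        Z = kinship.center_dosages(g)
        w = gwas.window_variance(rng.normal(size=12), Z, snp_map)
        assert len(w) == (7 - 4) + (5 - 4)

    def test_short_chromosome_emits_nothing(self, rng):
        g = _geno(rng, n=10, m=4)
        snp_map = pd.DataFrame({"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos})
        Z = kinship.center_dosages(g)
        w = gwas.window_variance(rng.normal(size=4), Z, snp_map)
        assert len(w) == 0

    def test_stride_five_shares_approach_total(self, rng):
        # for unlinked SNPs the non-overlapping window shares approach 100%
        def total_share(n):
            X = rng.binomial(2, 0.5, size=(n, 50)).astype(np.int8)
            g = GenotypeMatrix(
                ids=np.array([f"g{i}" for i in range(n)], dtype=object),
                snp_ids=np.array([f"s{j}" for j in range(50)]),
                chrom=np.array([1] * 50, dtype=object),
                pos=np.arange(1, 51) * 1000, X=X,
            )
            Z = kinship.center_dosages(g)
            snp_map = pd.DataFrame({"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos})
            u = rng.normal(size=50)
            w = gwas.window_variance(u, Z, snp_map, stride=5)
            return abs(w["share_pct"].sum() - 100.0)

        small = np.mean([total_share(25) for _ in range(3)])
        large = np.mean([total_share(400) for _ in range(3)])
        assert large < small


class TestRegions:
    def _windows(self, shares, starts=None, chrom="1"):
        starts = starts or [i * 1000 for i in range(len(shares))]
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": [s + 4000 for s in starts],
                "share_pct": shares,
                "snp_indices": [[i] for i in range(len(shares))],
            }
        )

    def test_threshold_filter(self):
        w = self._windows([0.5, 1.2, 3.0], starts=[0, 100_000, 200_000])
        out = gwas.call_regions(w)
        assert len(out) == 2

    def test_all_below_threshold(self):
        assert len(gwas.call_regions(self._windows([0.2, 0.9]))) == 0

    def test_overlapping_windows_merge(self):
        w = self._windows([2.0, 3.0], starts=[1000, 3000])
        out = gwas.call_regions(w)
        assert len(out) == 1
        assert out.iloc[0]["start"] == 1000 and out.iloc[0]["end"] == 7000
        assert out.iloc[0]["share_pct"] == pytest.approx(3.0)

    def test_monotone_in_threshold(self, rng):
        # raising the threshold never adds coverage: every higher-threshold
        # region lies inside some lower-threshold region
        w = self._windows(list(rng.uniform(0, 3, 30)))
        prev = gwas.call_regions(w, threshold=0.5)
        for thr in (1.0, 1.5, 2.0):
            cur = gwas.call_regions(w, threshold=thr)
            for _, r in cur.iterrows():
                assert any(
                    (p["start"] <= r["start"]) and (r["end"] <= p["end"])
                    for _, p in prev.iterrows()
                )
            prev = cur


class TestAnnotateGenes:
    def _regions(self):
        return pd.DataFrame(
            {"chrom": ["1"], "start": [1_000_000], "end": [1_050_000],
             "share_pct": [2.0], "snp_indices": [[0]]}
        )

    def test_boundary_inclusion(self):
        genes = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [700_000, 600_000],
                "end": [800_000, 799_999],  # ends exactly at / 1 bp beyond flank
                "name": ["at_flank", "beyond_flank"],
            }
        )
        out = gwas.annotate_genes(self._regions(), genes, flank=200_000)
        assert out.iloc[0]["genes"] == ["at_flank"]

    def test_inside_straddle_far(self):
        genes = pd.DataFrame(
            {
                "chrom": ["1", "1", "2"],
                "start": [1_010_000, 990_000, 1_000_000],
                "end": [1_020_000, 1_005_000, 1_020_000],
                "name": ["inside", "straddle", "wrong_chrom"],
            }
        )
        out = gwas.annotate_genes(self._regions(), genes)
        assert sorted(out.iloc[0]["genes"]) == ["inside", "straddle"]

    def test_chr_prefix_normalised(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [1_000_000], "end": [1_010_000], "name": ["g"]}
        )
        out = gwas.annotate_genes(self._regions(), genes)
        assert out.iloc[0]["genes"] == ["g"]


class TestRunWssgwas:
    def test_single_iteration_is_unweighted(self):
        from heatnorm import rnm, simulate

        simq = simulate.simulate_qtl_slope_dataset(n_animals=60, n_snps=120, seed=4)
        frame = rnm.build_model_frame(simq.records, simq.ped)
        covs = simq.scenario.true_covariances
        r1 = gwas.run_wssgwas(frame, covs, simq.genotypes, n_iterations=1)
        assert len(r1.iterations) == 1
        assert np.allclose(r1.iterations[0].weights, 1.0)
        # determinism: same inputs give identical effects
        r2 = gwas.run_wssgwas(frame, covs, simq.genotypes, n_iterations=1)
        assert np.array_equal(r1.final.snp_effects, r2.final.snp_effects)
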