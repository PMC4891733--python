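import numpy as np
import pytest
from scipy import stats

from droneselect import flk, popstats, synthetic_data as sd
from conftest import random_psd_kinship


class TestEstimateP0:
    def test_isotropic_limit_is_mean(self, rng):
        p = rng.uniform(0.1, 0.9, size=4)
        assert flk.estimate_p0(p, 0.2 * np.eye(4)) == pytest.approx(p.mean())

    def test_worked_example(self):
        assert flk.estimate_p0(
            np.array([0.5, 0.5, 0.8]), 0.1 * np.eye(3)
        ) == pytest.approx(0.6)

    def test_gls_minimizer_against_grid(self, rng):
        for _ in range(10):
            F = random_psd_kinship(rng)
            p = rng.uniform(0.1, 0.9, size=3)
            Fi = np.linalg.inv(F)
            grid = np.linspace(0.01, 0.99, 4001)
            obj = [
                (p - c) @ Fi @ (p - c) for c in grid
            ]
            c_star = grid[int(np.argmin(obj))]
            assert flk.estimate_p0(p, F) == pytest.approx(c_star, abs=5e-4)


class TestFlkStatistic:
    def test_constant_vector_gives_zero(self):
        F = 0.05 * np.eye(3)
        T, u = flk.flk_statistic(np.full(3, 0.4), F)
        assert T == pytest.approx(0.0, abs=1e-20)

    def test_worked_example_hand_derived(self):
        T, u = flk.flk_statistic(np.array([0.5, 0.5, 0.8]), 0.1 * np.eye(3))
        assert T == pytest.approx(2.5, abs=1e-9)
        assert (u ** 2).sum() == pytest.approx(2.5, abs=1e-9)
        assert sorted(np.round(np.abs(u), 4)) == [0.6455, 0.6455, 1.291]

    def test_quadratic_form_oracle(self, rng):
        for _ in range(25):
            F = random_psd_kinship(rng)
            p = rng.uniform(0.05, 0.95, size=3)
            T, u = flk.flk_statistic(p, F)
            p0 = flk.estimate_p0(p, F)
            ptil = (p - p0) / np.sqrt(p0 * (1 - p0))
            assert T == pytest.approx(ptil @ np.linalg.inv(F) @ ptil, abs=1e-10)
            assert abs(T - (u ** 2).sum()) < 1e-10

    def test_population_relabeling_invariance(self, rng):
        F = random_psd_kinship(rng, npop=4)
        p = rng.uniform(0.1, 0.9, size=4)
        perm = rng.permutation(4)
        T1, _ = flk.flk_statistic(p, F)
        T2, _ = flk.flk_statistic(p[perm], F[np.ix_(perm, perm)])
        assert T1 == pytest.approx(T2, rel=1e-10)


class TestEigenSystem:
    def test_orthogonality_and_reconstruction(self, rng):
        F = random_psd_kinship(rng)
        kin = popstats.KinshipMatrix(["a", "b", "c"], F)
        es = flk.eigensystem(kin)
        assert np.allclose(es.Q @ es.Q.T, np.eye(3), atol=1e-10)
        assert np.allclose(es.Q.T @ np.diag(es.D) @ es.Q, F, atol=1e-10)


class TestClusterModel:
    def test_identical_haplotypes_modeled_exactly(self, rng):
        # degenerate input: every occupied cluster converges to the single
        # haplotype (label-degenerate optimum) and the likelihood is maximal
        hap = rng.integers(0, 2, 30).astype(np.int8)
        G = np.tile(hap, (12, 1))
        (model,) = flk.fit_cluster_model(G, K=2, n_fits=1, seed=0)
        gamma = flk.cluster_posteriors(G, model)
        predicted = np.einsum("nlk,lk->l", gamma, model.theta) / 12
        assert np.allclose(predicted, hap, atol=1e-3)
        # maximal achievable log-likelihood given the theta clipping bound
        assert model.loglik_trace[-1] >= 12 * 30 * np.log(1 - 1e-5) - 1e-6

    def test_two_haplotype_mixture_recovered(self, rng):
        h1 = rng.integers(0, 2, 40).astype(np.int8)
        h2 = (1 - h1).astype(np.int8)
        G = np.vstack([np.tile(h1, (10, 1)), np.tile(h2, (10, 1))])
        (model,) = flk.fit_cluster_model(G, K=2, n_fits=1, seed=1)
        gamma = flk.cluster_posteriors(G, model)
        freqs = gamma.mean(axis=0)  # (L, K)
        assert np.allclose(freqs, 0.5, atol=0.02)

    def test_loglik_nondecreasing_on_random_data(self, rng):
        G = rng.integers(0, 2, size=(20, 60)).astype(np.int8)
        models = flk.fit_cluster_model(G, K=3, n_fits=3, seed=2)
        for m in models:
            ll = np.array(m.loglik_trace)
            assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_missing_input_rejected(self):
        G = np.array([[0, 1, -1]], dtype=np.int8)
        with pytest.raises(ValueError, match="0/1"):
            flk.fit_cluster_model(G, K=2, n_fits=1)


class TestHapflk:
    def _kin(self):
        return popstats.KinshipMatrix(
            ["P1", "P2"], np.array([[0.05, 0.01], [0.01, 0.05]])
        )

    def test_identical_populations_give_zero(self, rng):
        hap = rng.integers(0, 2, size=(6, 30)).astype(np.int8)
        G = np.vstack([hap, hap])  # same haplotypes in both populations
        labels = np.array(["P1"] * 6 + ["P2"] * 6)
        models = flk.fit_cluster_model(G, K=3, n_fits=2, seed=3)
        vals = flk.hapflk_statistic(models, G, labels, self._kin())
        assert np.allclose(vals, 0.0, atol=1e-8)

    def test_single_cluster_monomorphic_zero(self):
        G = np.zeros((8, 20), dtype=np.int8)
        labels = np.array(["P1"] * 4 + ["P2"] * 4)
        models = flk.fit_cluster_model(G, K=2, n_fits=1, seed=4)
        vals = flk.hapflk_statistic(models, G, labels, self._kin())
        assert np.allclose(vals, 0.0, atol=1e-8)

    def test_tiny_population_rejected(self, rng):
        G = rng.integers(0, 2, size=(5, 10)).astype(np.int8)
        labels = np.array(["P1"] * 4 + ["P2"])
        models = flk.fit_cluster_model(G, K=2, n_fits=1, seed=5)
        with pytest.raises(ValueError, match="fewer than 2"):
            flk.hapflk_statistic(models, G, labels, self._kin())

    def test_neutral_false_positive_control(self):
        # 20k loci, no sweep: region count at alpha 1e-4 below twice the
        # expected number of significant sites (20k * 1e-4 = 2)
        model = sd.DriftModel(nsites=20_000, seed=11)
        freqs, _ = sd.simulate_frequencies(model)
        gm = sd.simulate_haplotypes(freqs, 20, seed=12)
        kin = popstats.KinshipMatrix(["P1", "P2", "P3"], model.kinship_true)
        haps = flk.haplotypes_from_gm(gm)
        labels = gm.samples.df["population"].to_numpy()
        models = flk.fit_cluster_model(haps, K=10, n_fits=2, seed=13)
        vals = flk.hapflk_statistic(models, haps, labels, kin)
        pv, a, d = flk.pvalues_from_chi2(vals)
        regions = flk.call_regions(
            gm.sites["chrom"].to_numpy(), gm.sites["pos"].to_numpy(), pv
        )
        assert len(regions) < 4


class TestPvalueCalibration:
    def test_chi2_recovery_and_uniformity(self, rng):
        draws = rng.chisquare(4, size=50_000)
        pv, a, d = flk.pvalues_from_chi2(draws)
        assert abs(a - 1) < 0.1
        assert abs(d - 4) < 0.4
        ks = stats.kstest(pv, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            flk.pvalues_from_chi2(np.full(2000, 3.0))

    def test_scale_equivariance(self, rng):
        draws = rng.chisquare(6, size=20_000)
        pv1, a1, d1 = flk.pvalues_from_chi2(draws)
        pv3, a3, d3 = flk.pvalues_from_chi2(3 * draws)
        assert a3 == pytest.approx(3 * a1, rel=1e-6)
        assert d3 == pytest.approx(d1, rel=1e-6)
        assert np.allclose(pv1, pv3, atol=1e-12)


class TestRegions:
    def test_no_significant_positions(self):
        regions = flk.call_regions(
            np.array(["1", "1"]), np.array([100, 200]), np.array([0.5, 0.9])
        )
        assert regions == []

    def test_hand_traced_chaining_and_flanks(self):
        pos = np.array([100_000, 101_500, 140_000])
        pv = np.array([1e-5, 5e-5, 1e-6])
        regions = flk.call_regions(np.repeat("1", 3), pos, pv)
        assert [(r.start, r.end) for r in regions] == [
            (90_000, 111_500),
            (130_000, 150_000),
        ]
        assert regions[0].peak_pos == 100_000
        assert regions[1].peak_pos == 140_000

    def test_merged_regions_pairwise_disjoint(self, rng):
        for _ in range(20):
            pos = np.sort(rng.choice(np.arange(1, 500_000, 100), 300, replace=False))
            pv = rng.uniform(0, 1, size=300) ** 8
            regions = flk.call_regions(np.repeat("1", 300), pos, pv, alpha=1e-3)
            spans = sorted((r.start, r.end) for r in regions)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 > e1


def _mock_flk_result(u, chrom=None, pops=("A", "B", "C")):
    """FlkResult with prescribed u-vectors (T consistent by construction)."""
    import pandas as pd

    n = u.shape[0]
    F = np.diag([0.08, 0.05, 0.03])
    kin = popstats.KinshipMatrix(list(pops), F)
    es = flk.eigensystem(kin)
    T = (u ** 2).sum(axis=1)
    table = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.repeat("1", n),
            "pos": np.arange(1, n + 1) * 100,
            "p0": 0.5,
            "T": T,
            "p_value": stats.chi2.sf(T, 2),
            "flagged": False,
        }
    )
    return flk.FlkResult(table, u, es, 2)


class TestAssignment:
    def test_dominant_eigenvector_assigns_population(self, rng):
        u = rng.normal(0, 0.5, size=(2000, 3))
        u[1000:1010, 0] = 8.0  # strong signal on the leading eigenvector
        res = _mock_flk_result(u)
        region = flk.SelectionRegion("1", 100_050, 101_050, 100_100, 1e-6)
        (out,) = flk.assign_populations([region], res)
        istar = int(np.argmax(out.measures))
        expect = res.eigen.populations[int(np.argmax(np.abs(res.eigen.Q[istar])))]
        assert out.assigned_population == expect
        assert out.n_snps == 10
        assert out.measures[istar] >= 2 * np.partition(out.measures, -2)[-2]

    def test_tied_measures_leave_unassigned(self, rng):
        u = rng.normal(0, 0.5, size=(2000, 3))
        u[1000:1010, :] = 6.0  # equal excess on every eigenvector
        res = _mock_flk_result(u)
        region = flk.SelectionRegion("1", 100_050, 101_050, 100_100, 1e-6)
        (out,) = flk.assign_populations([region], res)
        assert out.assigned_population is None
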