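import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from droneselect import hetsnp_cnv as hc
from droneselect import synthetic_data as sd
from droneselect.io_formats import ALT, HET, Interval, REF, SampleTable
from conftest import make_gm


class TestSiteFilter:
    def test_low_dp_in_one_sample_drops_site(self):
        depth = np.array([[10, 10], [8, 9]])
        gm = make_gm(np.zeros((2, 2), dtype=np.int8), depth=depth)
        out = hc.site_filter(gm)
        assert out.sites["pos"].tolist() == [200]

    def test_non_autosome_dropped(self):
        gm = make_gm(np.zeros((2, 3), dtype=np.int8), chrom="Un17")
        assert hc.site_filter(gm).n_sites == 0

    def test_against_brute_force_oracle(self, rng):
        depth = rng.integers(0, 20, size=(6, 100))
        gm = make_gm(np.zeros((6, 100), dtype=np.int8), depth=depth)
        out = hc.site_filter(gm)
        expect = [j for j in range(100) if (depth[:, j] >= 9).all()]
        assert out.sites["pos"].tolist() == [(j + 1) * 100 for j in expect]


class TestNeighborFilter:
    def test_isolated_pair_removed(self):
        assert hc.neighbor_filter(np.array([10_000, 50_000])).tolist() == []

    def test_close_pair_retained(self):
        kept = hc.neighbor_filter(np.array([10_000, 11_000, 50_000]))
        assert kept.tolist() == [10_000, 11_000]

    @given(st.lists(st.integers(1, 100_000), min_size=0, max_size=40))
    @settings(deadline=None, max_examples=80, derandomize=True)
    def test_against_pairwise_oracle(self, raw):
        pos = np.unique(np.array(raw, dtype=int))
        kept = set(hc.neighbor_filter(pos).tolist())
        oracle = {
            int(p)
            for p in pos
            if any(q != p and abs(int(q) - int(p)) <= 2000 for q in pos)
        }
        assert kept == oracle


class TestCallClusters:
    def test_hand_traced_cluster(self):
        pos = np.array([10_000, 10_800, 11_500, 12_100])
        dp = np.array([25, 22, 30, 27])
        (cl,) = hc.call_clusters(pos, dp, "d1", "3", drone_mean_dp=7.0)
        assert (cl.start, cl.end, cl.n_het) == (10_000, 12_100, 4)
        assert cl.mean_dp == pytest.approx(26.0)

    def test_too_few_hets(self):
        assert (
            hc.call_clusters(
                np.array([10_000, 10_800]), np.array([30, 30]), "d", "1", 7.0
            )
            == []
        )

    def test_span_too_short(self):
        pos = np.array([10_000, 10_500, 11_000, 11_500])
        assert hc.call_clusters(pos, np.full(4, 30), "d", "1", 7.0) == []

    def test_depth_rule(self):
        pos = np.array([10_000, 11_000, 12_100])
        assert hc.call_clusters(pos, np.full(3, 20), "d", "1", 7.0) == []  # 20 < 21
        assert len(hc.call_clusters(pos, np.full(3, 21), "d", "1", 7.0)) == 1


class TestMerge:
    def _table(self):
        return SampleTable.from_records(
            ["d1", "d2", "d3"], ["RJ", "HN", "RJ"]
        )

    def _cl(self, drone, chrom, start, end):
        return hc.HetSnpCluster(drone, chrom, start, end, 3, 30.0, 7.0)

    def test_overlap_union(self):
        cls = [self._cl("d1", "1", 1000, 3000), self._cl("d2", "1", 2500, 4600)]
        (iv,) = hc.merge_across_drones(cls, self._table())
        assert (iv.start, iv.end, iv.total_carriers) == (1000, 4600, 2)
        assert iv.carriers == {"RJ": 1, "HN": 1}

    def test_disjoint_stay_separate(self):
        cls = [self._cl("d1", "1", 1000, 3001), self._cl("d2", "1", 5000, 8000)]
        ivs = hc.merge_across_drones(cls, self._table())
        assert len(ivs) == 2

    def test_order_independence(self, rng):
        cls = [
            self._cl(f"d{1 + i % 3}", "1", int(s), int(s) + int(rng.integers(2001, 6000)))
            for i, s in enumerate(rng.integers(1, 50_000, size=15))
        ]
        ivs1 = hc.merge_across_drones(cls, self._table())
        perm = [cls[i] for i in rng.permutation(len(cls))]
        ivs2 = hc.merge_across_drones(perm, self._table())
        key = lambda ivs: [(i.chrom, i.start, i.end, i.total_carriers) for i in ivs]
        assert key(ivs1) == key(ivs2)

    def test_against_sweep_line_oracle(self, rng):
        cls = [
            self._cl("d1", "1", int(s), int(s) + 2500)
            for s in rng.integers(1, 30_000, size=12)
        ]
        ivs = hc.merge_across_drones(cls, self._table())
        # oracle: mark covered positions, read off maximal covered runs
        cover = np.zeros(40_000, dtype=bool)
        for c in cls:
            cover[c.start: c.end + 1] = True
        runs = []
        inrun = False
        for i in range(1, 40_000):
            if cover[i] and not inrun:
                s = i
                inrun = True
            elif not cover[i] and inrun:
                runs.append((s, i - 1))
                inrun = False
        assert [(iv.start, iv.end) for iv in ivs] == runs


class TestBiasTest:
    def test_paper_concordant_counts(self):
        chi2, p = hc.population_bias_test(
            {"RJ": 23, "HN": 9}, {"RJ": 30, "HN": 30}
        )
        assert chi2 == pytest.approx(13.125, abs=1e-9)
        assert p == pytest.approx(2.9e-4, abs=1e-5)

    def test_equal_fractions_null(self):
        chi2, p = hc.population_bias_test({"A": 10, "B": 10}, {"A": 20, "B": 20})
        assert chi2 == 0 and p == 1

    def test_textbook_formula_oracle(self, rng):
        for _ in range(30):
            nA, nB = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            a = int(rng.integers(1, nA))
            b = int(rng.integers(1, nB))
            chi2, p = hc.population_bias_test({"A": a, "B": b}, {"A": nA, "B": nB})
            n = nA + nB
            expect = (
                n * (a * (nB - b) - (nA - a) * b) ** 2
                / ((a + b) * (n - a - b) * nA * nB)
            )
            assert chi2 == pytest.approx(expect, rel=1e-9)
            assert p == pytest.approx(stats.chi2.sf(expect, 1), rel=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hc.population_bias_test({"A": 1}, {"A": 10, "B": 0})


class TestAnnotate:
    def _iv(self, start, end):
        return hc.ClusterInterval("1", start, end)

    def test_gene_margin_boundaries(self):
        genes = [Interval("1", 3500, 5000, "near"), Interval("1", 4101, 5000, "far")]
        iv = self._iv(1000, 2000)
        hc.annotate([iv], genes=[genes[0]], gene_margin=2000)
        assert iv.nearby_genes == ["near"]  # distance 1500
        iv2 = self._iv(1000, 2000)
        hc.annotate([iv2], genes=[genes[1]], gene_margin=2000)
        assert iv2.nearby_genes == []  # distance 2101

    def test_recombination_overlap_flag(self):
        iv = self._iv(1000, 2000)
        hc.annotate([iv], recomb_intervals=[Interval("1", 2000, 2400)])
        assert iv.overlaps_recombination
        iv2 = self._iv(1000, 2000)
        hc.annotate([iv2], recomb_intervals=[Interval("1", 2001, 2400)])
        assert not iv2.overlaps_recombination

    def test_against_quadratic_oracle(self, rng):
        genes = [
            Interval("1", int(s), int(s) + int(rng.integers(100, 2000)), f"g{i}")
            for i, s in enumerate(rng.integers(1, 50_000, size=25))
        ]
        ivs = [
            self._iv(int(s), int(s) + 1500) for s in rng.integers(1, 50_000, size=10)
        ]
        hc.annotate(ivs, genes=genes, gene_margin=2000)
        for iv in ivs:
            expect = sorted(
                g.name
                for g in genes
                if g.start <= iv.end + 2000 and iv.start - 2000 <= g.end
            )
            assert iv.nearby_genes == expect


class TestPipelineProperties:
    def test_emitted_clusters_resatisfy_predicates(self):
        model = sd.DriftModel(nsites=2500, seed=21)
        freqs, _ = sd.simulate_frequencies(model)
        gm = sd.simulate_haplotypes(freqs, 20, seed=22, pop_labels=["HN", "RJ", "SL"])
        spec = sd.CnvSpec(
            "1", 100_000, 110_000, carrier_fraction={"RJ": 0.6}, min_realized_hets=3
        )
        gm, _ = sd.inject_cnv(gm, spec, seed=23)
        clusters = hc.detect_clusters(gm)
        assert clusters, "expected clusters on CNV-injected data"
        called = gm.calls != -1
        for cl in clusters:
            i = gm.samples.sample_ids.index(cl.drone_id)
            # independent re-check of the three printed predicates
            assert cl.n_het >= 3
            assert cl.end - cl.start >= 2000
            baseline = gm.depth[i][called[i]].mean()
            assert cl.mean_dp >= 3 * baseline - 1e-9
            assert cl.drone_mean_dp == pytest.approx(baseline)
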