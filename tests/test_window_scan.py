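"""Window tiling, counting, z-scoring, merging, and the estimator API."""

import math
import warnings

import numpy as np
import pytest
from sklearn.base import clone

from ecrscan import (
    DegenerateNullWarning,
    GenomeLayout,
    ScanParams,
    Window,
    WindowClusterScanner,
    WindowScanResult,
    call_clusters,
    count_in_windows,
    make_windows,
    scan,
    score_windows,
    write_clusters,
)
from conftest import make_point_sites, random_point_sites


def brute_force_counts(windows, sites):
    """Independent oracle: exhaustive per-window scan over every site point."""
    return [
        sum(1 for s in sites if s.chrom == c and start <= s.point < end)
        for c, start, end in windows
    ]


class TestMakeWindows:
    def test_regular_tiling_counts_and_bounds(self):
        g = GenomeLayout([("chr1", 5_000_000)])
        w = make_windows(g, ScanParams())
        assert len(w) == 61
        assert w[0] == ("chr1", 0, 2_000_000)
        assert w[-1] == ("chr1", 3_000_000, 5_000_000)
        assert all(e - s == 2_000_000 for _, s, e in w)

    def test_short_chromosome_single_window(self):
        g = GenomeLayout([("chr1", 1_000_000)])
        assert make_windows(g, ScanParams()) == [("chr1", 0, 1_000_000)]

    def test_final_window_right_anchored(self):
        # L=2,025,000: regular starts {0}; 25,000 inserted so the tail is
        # covered by a full-length window rather than a truncated one.
        g = GenomeLayout([("chr1", 2_025_000)])
        w = make_windows(g, ScanParams())
        assert [s for _, s, _ in w] == [0, 25_000]
        assert all(e - s == 2_000_000 for _, s, e in w)

    @pytest.mark.parametrize("length", [999_983, 3_141_593, 20_000_000])
    def test_tiling_rule_invariants(self, length, toy_params):
        g = GenomeLayout([("chrA", length)])
        ws = make_windows(g, toy_params)
        for _, s, e in ws:
            assert 0 <= s < e <= length
            assert e - s == min(toy_params.window_size, length)
        if length > toy_params.window_size:
            assert ws[-1][2] == length  # tail always covered


class TestCounting:
    def test_half_open_boundaries(self, small_genome):
        ss = make_point_sites(small_genome, [("chr1", 150), ("chr1", 1_999_999), ("chr1", 2_000_000)])
        wins = count_in_windows([("chr1", 0, 2_000_000)], ss)
        assert wins[0].count == 2  # 2,000,000 excluded (half-open)

    def test_point_in_overlapping_windows_counts_in_each(self, small_genome):
        ss = make_point_sites(small_genome, [("chr1", 1_000_000)])
        wins = count_in_windows(
            [("chr1", 0, 2_000_000), ("chr1", 500_000, 2_500_000)], ss
        )
        assert [w.count for w in wins] == [1, 1]

    def test_matches_brute_force_on_random_instances(self, toy_params):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = GenomeLayout(
                [("chr1", int(rng.integers(2_000_000, 12_000_000))),
                 ("chr2", int(rng.integers(500_000, 8_000_000)))]
            )
            ss = random_point_sites(rng, g, int(rng.integers(1, 300)))
            wins = make_windows(g, toy_params)
            got = [w.count for w in count_in_windows(wins, ss)]
            assert got == brute_force_counts(wins, ss)


class TestScoring:
    @staticmethod
    def _result(counts, params=None, chrom="chr1"):
        params = params or ScanParams()
        wins = [Window(chrom, i * 10, i * 10 + 10, count=c) for i, c in enumerate(counts)]
        return WindowScanResult(params=params, windows=wins)

    def test_z_and_p_against_frozen_values(self):
        # counts [2,2,2,2,12]: mu=4, sample sd=sqrt(20); hand-checked tail
        r = score_windows(self._result([2, 2, 2, 2, 12]))
        assert r.null_mean["genome"] == pytest.approx(4.0)
        assert r.null_sd["genome"] == pytest.approx(math.sqrt(20), rel=1e-12)
        assert r.windows[-1].z == pytest.approx(1.7889, abs=1e-4)
        assert r.windows[-1].p == pytest.approx(0.0368, abs=1e-4)
        assert r.windows[-1].p < 0.05

    def test_one_sided_depleted_windows_never_significant(self):
        r = score_windows(self._result([2, 2, 2, 2, 12]))
        for w in r.windows[:4]:
            assert w.z < 0 and w.p > 0.5

    def test_population_sd_option(self):
        r = score_windows(self._result([2, 2, 2, 2, 12], ScanParams(sd_mode="population")))
        assert r.null_sd["genome"] == pytest.approx(4.0)  # sqrt(80/5)

    def test_degenerate_null_sets_all_p_to_one(self):
        with pytest.warns(DegenerateNullWarning):
            r = score_windows(self._result([3, 3, 3, 3]))
        assert all(w.p == 1.0 for w in r.windows)
        assert all(math.isnan(w.z) for w in r.windows)

    def test_fewer_than_two_windows_is_an_error(self):
        with pytest.raises(ValueError, match="need >=2"):
            score_windows(self._result([5]))

    def test_p_monotone_nonincreasing_in_z(self):
        r = score_windows(self._result(list(range(20))))
        zs = sorted(r.windows, key=lambda w: w.z)
        ps = [w.p for w in zs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_per_chromosome_scope_estimates_separate_nulls(self):
        wins = [Window("chr1", i, i + 1, count=c) for i, c in enumerate([1, 1, 1, 9])]
        wins += [Window("chr2", i, i + 1, count=c) for i, c in enumerate([5, 5, 5, 5])]
        with pytest.warns(DegenerateNullWarning):  # chr2 is flat
            r = score_windows(
                WindowScanResult(ScanParams(null_scope="per_chromosome"), wins)
            )
        assert set(r.null_mean) == {"chr1", "chr2"}
        assert r.null_mean["chr1"] == pytest.approx(3.0)
        assert all(w.p == 1.0 for w in r.windows if w.chrom == "chr2")


class TestClusterCalling:
    @staticmethod
    def _scored(sig_spec, genome, params):
        """Windows with p forced significant (0.001) or not (0.9)."""
        wins = [Window(c, s, e, count=0, z=0.0, p=0.001 if sig else 0.9)
                for (c, s, e), sig in sig_spec]
        return WindowScanResult(params=params, windows=wins)

    def test_no_significant_windows_empty_set(self, small_genome):
        params = ScanParams()
        ss = make_point_sites(small_genome, [("chr1", 100)])
        r = self._scored([(("chr1", 0, 2_000_000), False)], small_genome, params)
        assert len(call_clusters(r, ss)) == 0

    def test_overlapping_windows_merge(self, small_genome):
        params = ScanParams()
        ss = make_point_sites(small_genome, [("chr1", 500_000), ("chr1", 4_000_000)])
        r = self._scored(
            [(("chr1", 100_000, 2_100_000), True), (("chr1", 150_000, 2_150_000), True)],
            small_genome, params,
        )
        cs = call_clusters(r, ss)
        assert len(cs) == 1
        c = cs.clusters[0]
        assert (c.start, c.end, c.n_windows_merged) == (100_000, 2_150_000, 2)
        assert c.member_site_ids == ["S_1"] and c.n_sites == 1

    def test_gap_rule_merges_within_threshold_only(self):
        genome = GenomeLayout([("chr1", 10_000_000)])
        ss = make_point_sites(genome, [("chr1", 1)])
        spec = [(("chr1", 0, 2_000_000), True), (("chr1", 2_050_000, 4_050_000), True)]
        cs = call_clusters(self._scored(spec, genome, ScanParams(merge_gap=50_000)), ss)
        assert len(cs) == 1 and (cs.clusters[0].start, cs.clusters[0].end) == (0, 4_050_000)
        cs = call_clusters(self._scored(spec, genome, ScanParams(merge_gap=0)), ss)
        assert len(cs) == 2

    def test_cluster_p_is_min_window_p_and_ids_follow_genome_order(self):
        genome = GenomeLayout([("chrA", 10_000_000), ("chrB", 10_000_000)])
        ss = make_point_sites(genome, [("chrA", 1), ("chrB", 1)])
        wins = [
            Window("chrB", 0, 2_000_000, 0, 3.0, 0.002),
            Window("chrA", 0, 2_000_000, 0, 2.0, 0.01),
            Window("chrA", 50_000, 2_050_000, 0, 2.5, 0.005),
        ]
        cs = call_clusters(WindowScanResult(ScanParams(), wins), ss)
        assert [c.cluster_id for c in cs] == ["S_c1", "S_c2"]
        assert cs.clusters[0].chrom == "chrA"
        assert cs.clusters[0].p_value == pytest.approx(0.005)

    def test_bh_correction_is_stricter_than_raw(self):
        genome = GenomeLayout([("chr1", 100_000_000)])
        rng = np.random.default_rng(5)
        ss = random_point_sites(rng, genome, 400)
        _, raw = scan(ss, params=ScanParams(alpha=0.05))
        _, bh = scan(ss, params=ScanParams(alpha=0.05, mt_correction="bh"))
        assert len(bh) <= len(raw)


class TestScanEndToEnd:
    def test_empty_siteset_yields_empty_clusterset(self, small_genome):
        ss = make_point_sites(small_genome, [])
        with pytest.warns(DegenerateNullWarning):
            result, clusters = scan(ss)
        assert len(clusters) == 0
        assert all(w.count == 0 for w in result.windows)

    def test_single_dense_region_captures_all_points(self):
        genome = GenomeLayout([("chr1", 50_000_000)])
        rng = np.random.default_rng(7)
        pts = [("chr1", int(p)) for p in rng.integers(20_000_000, 22_000_000, 40)]
        ss = make_point_sites(genome, pts)
        _, clusters = scan(ss)
        assert len(clusters) == 1
        c = clusters.clusters[0]
        assert c.n_sites == 40
        assert c.start <= 20_000_000 and c.end >= 22_000_000

    def test_scan_is_deterministic(self, tmp_path):
        genome = GenomeLayout([("chr1", 30_000_000)])
        rng = np.random.default_rng(11)
        ss = random_point_sites(rng, genome, 200)
        outs = []
        for name in ("a.bed", "b.bed"):
            _, clusters = scan(ss)
            write_clusters(clusters, tmp_path / name)
            outs.append((tmp_path / name).read_bytes())
        assert outs[0] == outs[1]

    def test_clusters_disjoint_and_spans_at_least_window_size(self):
        genome = GenomeLayout([("chr1", 80_000_000)])
        rng = np.random.default_rng(13)
        ss = random_point_sites(rng, genome, 500)
        _, clusters = scan(ss)
        prev_end = {}
        for c in clusters:
            assert c.end - c.start >= min(2_000_000, genome.length_of(c.chrom))
            assert c.start >= prev_end.get(c.chrom, -1)
            prev_end[c.chrom] = c.end
            assert c.n_windows_merged >= 1

    def test_adding_site_inside_cluster_keeps_it_at_fixed_null(self):
        """At fixed mu/sigma, extra points inside a cluster only raise counts,
        so every previously significant window stays significant."""
        genome = GenomeLayout([("chr1", 50_000_000)])
        rng = np.random.default_rng(17)
        pts = [("chr1", int(p)) for p in rng.integers(10_000_000, 11_500_000, 30)]
        pts += [("chr1", int(p)) for p in rng.integers(0, 50_000_000, 200)]
        ss = make_point_sites(genome, pts)
        result, clusters = scan(ss)
        assert len(clusters) >= 1
        target = clusters.clusters[0]
        mu, sd = result.null_mean["genome"], result.null_sd["genome"]
        new_pt = (target.start + target.end) // 2

        ss2 = make_point_sites(genome, pts + [(("chr1"), new_pt)])
        wins2 = count_in_windows([(w.chrom, w.start, w.end) for w in result.windows], ss2)
        for w_old, w_new in zip(result.windows, wins2):
            assert w_new.count >= w_old.count
            if w_old.p < 0.05:  # re-score at the original null
                from scipy.stats import norm
                assert norm.sf((w_new.count - mu) / sd) < 0.05


class TestEstimatorAPI:
    def test_get_set_params_and_clone(self):
        est = WindowClusterScanner(alpha=0.01, step=25_000)
        assert est.get_params()["alpha"] == 0.01
        est2 = clone(est).set_params(alpha=0.2)
        assert est2.alpha == 0.2 and est.alpha == 0.01

    def test_fit_exposes_underscored_state_and_labels(self):
        genome = GenomeLayout([("chr1", 50_000_000)])
        rng = np.random.default_rng(23)
        pts = [("chr1", int(p)) for p in rng.integers(5_000_000, 6_500_000, 40)]
        pts += [("chr1", int(p)) for p in rng.integers(0, 50_000_000, 100)]
        ss = make_point_sites(genome, pts)
        est = WindowClusterScanner().fit(ss)
        assert est.n_clusters_ == len(est.clusters_)
        assert est.labels_.shape == (len(ss),)
        in_cluster = {sid for c in est.clusters_ for sid in c.member_site_ids}
        for site, lab in zip(ss, est.labels_):
            assert (lab >= 0) == (site.site_id in in_cluster)

    def test_fit_rejects_non_siteset(self):
        with pytest.raises(TypeError, match="SiteSet"):
            WindowClusterScanner().fit(np.zeros((3, 2)))
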