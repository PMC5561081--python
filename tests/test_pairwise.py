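import math

import numpy as np
import pytest
from scipy import stats

from comodnet.gem import GEM
from comodnet.pairwise import (
    OutlierRule,
    PairwiseConfig,
    assemble_pair,
    cluster_and_correlate,
    count_pairs,
    flag_outliers_pre,
    iter_pair_results,
    min_cluster_size_power,
    pair_from_index,
    read_pair_results,
    write_pair_results,
)


def _mp_normal_quantile(p: str) -> float:
    """Arbitrary-precision standard-normal quantile via mpmath."""
    from mpmath import erfinv, mp, mpf, sqrt

    mp.dps = 50
    return float(sqrt(2) * erfinv(2 * mpf(p) - 1))


class TestPowerAnalysis:
    def test_default_parameters_give_thirty(self):
        assert min_cluster_size_power(0.05, 0.2, 0.5) == 30

    def test_matches_arbitrary_precision_oracle(self):
        z = _mp_normal_quantile("0.975") + _mp_normal_quantile("0.8")
        expected = math.ceil((z / math.atanh(0.9)) ** 2 + 3)
        assert min_cluster_size_power(0.05, 0.2, 0.9) == expected

    def test_limit_large_effect_size_approaches_four(self):
        assert min_cluster_size_power(0.05, 0.2, 1 - 1e-12) == 4

    @pytest.mark.parametrize("bad", [(0, 0.2, 0.5), (0.05, 1.0, 0.5),
                                     (0.05, 0.2, 0.0), (0.05, 0.2, 1.0)])
    def test_out_of_range_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            min_cluster_size_power(*bad)


class TestCountPairs:
    @pytest.mark.parametrize("n,expected", [(2, 1), (1000, 499500),
                                            (76300, 2910806850), (1, 0), (0, 0)])
    def test_closed_form(self, n, expected):
        assert count_pairs(n) == expected

    def test_pair_from_index_enumerates_upper_triangle(self):
        n = 7
        seen = [pair_from_index(k, n) for k in range(count_pairs(n))]
        expected = [(i, j) for i in range(n) for j in range(i + 1, n)]
        assert seen == expected


class TestAssemblePair:
    def test_no_missing_gives_full_template(self, tiny_gem):
        pts, template, idx = assemble_pair(tiny_gem, "T0", "T1")
        assert len(template) == tiny_gem.n_samples
        assert template == "0" * tiny_gem.n_samples
        assert pts.shape == (tiny_gem.n_samples, 2)

    def test_missing_samples_marked_nine(self):
        vals = np.arange(14.0).reshape(2, 7)
        vals[0, 2] = np.nan
        vals[0, 5] = np.nan
        gem = GEM(["A", "B"], [f"S{j}" for j in range(7)], vals)
        pts, template, idx = assemble_pair(gem, "A", "B")
        assert template == "0090090"
        assert pts.shape == (5, 2)
        assert list(idx) == [0, 1, 3, 4, 6]

    def test_same_gene_rejected(self, tiny_gem):
        with pytest.raises(ValueError):
            assemble_pair(tiny_gem, "T0", "T0")


class TestOutlierFlags:
    def test_identical_points_have_no_outliers(self):
        pts = np.zeros((10, 2))
        assert not flag_outliers_pre(pts).any()

    def test_extreme_point_flagged_against_quartile_oracle(self):
        pts = np.array([[0.0, 0.0]] * 19 + [[100.0, 0.0]])
        flags = flag_outliers_pre(pts)
        # oracle: quartiles of the 20-vector x-coordinates
        x = pts[:, 0]
        q1, q3 = np.percentile(x, [25, 75])
        hi = q3 + 1.5 * (q3 - q1)
        assert list(flags) == list(x > hi)
        assert flags[19] and flags.sum() == 1

    def test_rule_none_flags_nothing(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 2)) * 100
        assert not flag_outliers_pre(pts, OutlierRule.NONE).any()


def _spearman_rank_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Average-rank Spearman via explicit ranking + Pearson on ranks."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def _string_for(result, k):
    return result.clusters[k].sample_string


@pytest.fixture(scope="module")
def planted_modes_result():
    """50 samples correlated at ~0.95 around (2,2); 50 uncorrelated
    around (10,10)."""
    rng = np.random.default_rng(21)
    z = rng.standard_normal(50)
    r = 0.95
    a1 = 2 + math.sqrt(r) * z + math.sqrt(1 - r) * rng.standard_normal(50)
    b1 = 2 + math.sqrt(r) * z + math.sqrt(1 - r) * rng.standard_normal(50)
    a2 = 10 + rng.standard_normal(50)
    b2 = 10 + rng.standard_normal(50)
    vals = np.vstack([np.concatenate([a1, a2]), np.concatenate([b1, b2])])
    gem = GEM(["A", "B"], [f"S{j}" for j in range(100)], vals)
    cfg = PairwiseConfig(seed=5)
    return gem, cfg, cluster_and_correlate(gem, "A", "B", cfg)


class TestClusterAndCorrelate:
    def test_perfect_monotone_non_gmm(self):
        x = np.linspace(0.0, 4.0, 40)
        gem = GEM(["A", "B"], [f"S{j}" for j in range(40)],
                  np.vstack([x, 2 * x + 1]))
        cfg = PairwiseConfig(use_gmm=False, outlier_rule="none", seed=0)
        res = cluster_and_correlate(gem, "A", "B", cfg)
        assert len(res.clusters) == 1
        assert res.clusters[0].rho == pytest.approx(1.0)
        assert res.clusters[0].sample_string == "1" * 40

    def test_cluster_of_29_skipped_below_min_size(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(2, 8, size=(2, 29))
        gem = GEM(["A", "B"], [f"S{j}" for j in range(29)], vals)
        cfg = PairwiseConfig(use_gmm=False, outlier_rule="none")
        res = cluster_and_correlate(gem, "A", "B", cfg)
        cl = res.clusters[0]
        assert cl.rho is None
        assert cl.reason == "below min_cluster_size"

    def test_low_expression_range_skipped(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(5.0, 5.05, size=40)   # spans 0.05 log2 units
        b = rng.uniform(2.0, 8.0, size=40)
        gem = GEM(["A", "B"], [f"S{j}" for j in range(40)], np.vstack([a, b]))
        cfg = PairwiseConfig(use_gmm=False, outlier_rule="none")
        res = cluster_and_correlate(gem, "A", "B", cfg)
        assert res.clusters[0].reason == "below range"

    def test_insufficient_data(self):
        vals = np.array([[1.0, np.nan, 3.0], [np.nan, 2.0, np.nan]])
        gem = GEM(["A", "B"], ["S1", "S2", "S3"], vals)
        cfg = PairwiseConfig(use_gmm=False)
        res = cluster_and_correlate(gem, "A", "B", cfg)
        assert res.clusters == []
        assert res.reason == "insufficient data"

    def test_non_gmm_equals_plain_correlation(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, size=(2, 60))
        gem = GEM(["A", "B"], [f"S{j}" for j in range(60)], vals)
        cfg = PairwiseConfig(use_gmm=False, outlier_rule="none")
        res = cluster_and_correlate(gem, "A", "B", cfg)
        expected = stats.spearmanr(vals[0], vals[1]).statistic
        assert res.clusters[0].rho == pytest.approx(expected, abs=1e-15)

    def test_two_planted_modes_found_and_correlated(self, planted_modes_result):
        gem, cfg, res = planted_modes_result
        assert len(res.clusters) == 2
        rhos = sorted(abs(c.rho) for c in res.clusters)
        assert rhos[0] <= 0.3
        assert rhos[1] >= 0.8

    def test_per_cluster_rho_matches_rank_oracle(self, planted_modes_result):
        gem, cfg, res = planted_modes_result
        a = gem.values[0]
        b = gem.values[1]
        for cl in res.clusters:
            members = [k for k, d in enumerate(cl.sample_string) if d == "1"]
            oracle = _spearman_rank_oracle(a[members], b[members])
            assert cl.rho == pytest.approx(oracle, abs=1e-12)

    def test_digit_partition_invariants(self, planted_modes_result):
        gem, cfg, res = planted_modes_result
        strings = [c.sample_string for c in res.clusters]
        M = gem.n_samples
        assert all(len(s) == M for s in strings)
        assert all(set(s) <= set("01689") for s in strings)
        for pos in range(M):
            digs = [s[pos] for s in strings]
            # 9/6 shared across cluster strings of the pair
            if "9" in digs:
                assert set(digs) == {"9"}
            if "6" in digs:
                assert set(digs) == {"6"}
            # digit 1 in at most one cluster string
            assert digs.count("1") <= 1
        # '1'+'8' digits across clusters partition the observed samples
        n_observed = sum(1 for d in strings[0] if d not in "96")
        n_in_clusters = sum(s.count("1") + s.count("8") for s in strings)
        assert n_in_clusters == n_observed
        for cl in res.clusters:
            assert cl.size == cl.sample_string.count("1")

    def test_symmetric_in_gene_order(self, planted_modes_result):
        gem, cfg, res = planted_modes_result
        res_rev = cluster_and_correlate(gem, "B", "A", cfg)
        rhos = sorted(c.rho for c in res.clusters)
        rhos_rev = sorted(c.rho for c in res_rev.clusters)
        assert rhos == pytest.approx(rhos_rev, abs=1e-12)


class TestChunking:
    def test_chunked_windows_merge_to_full_run(self, small_synth):
        cfg, gem, truth, ann = small_synth
        sub = GEM(
            gem.transcript_ids[:8],
            gem.sample_ids,
            gem.values[:8],
        )
        pcfg = PairwiseConfig(seed=3)
        full = list(iter_pair_results(sub, pcfg))
        total = count_pairs(8)
        split = list(iter_pair_results(sub, pcfg, 0, 10)) + list(
            iter_pair_results(sub, pcfg, 10, total)
        )
        assert len(full) == len(split) == total
        for a, b in zip(full, split):
            assert (a.gene_a, a.gene_b) == (b.gene_a, b.gene_b)
            assert [c.rho for c in a.clusters] == [c.rho for c in b.clusters]
            assert [c.sample_string for c in a.clusters] == [
                c.sample_string for c in b.clusters
            ]

    def test_results_round_trip_through_tsv(self, tmp_path, small_synth):
        cfg, gem, truth, ann = small_synth
        sub = GEM(gem.transcript_ids[:5], gem.sample_ids, gem.values[:5])
        pcfg = PairwiseConfig(seed=3)
        results = list(iter_pair_results(sub, pcfg))
        p = tmp_path / "chunk.tsv"
        write_pair_results(results, p)
        back = read_pair_results(p)
        orig = {
            (r.gene_a, r.gene_b): r for r in results if r.clusters
        }
        assert {(r.gene_a, r.gene_b) for r in back} == set(orig)
        for r in back:
            o = orig[(r.gene_a, r.gene_b)]
            for cb, co in zip(r.clusters, o.clusters):
                assert cb.sample_string == co.sample_string
                assert cb.reason == co.reason
                if co.rho is None:
                    assert cb.rho is None
                else:
                    assert cb.rho == pytest.approx(co.rho, rel=1e-9)
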