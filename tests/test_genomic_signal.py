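"""Quantification, windows, profiles, methylation, clustering."""

import numpy as np
import pandas as pd
import pytest

import archdelta as ad
import archdelta.genomic_signal as gs


def _track(layout, chrom_vals, bin_size=100, units="count"):
    tr = ad.SignalTrack.zeros(layout, bin_size, units)
    for chrom, vals in chrom_vals.items():
        tr.values[chrom][: len(vals)] = vals
    return tr


class TestRpkm:
    @pytest.mark.parametrize("count,total,expected", [
        (10, 1e6, 100.0), (0, 1e6, 0.0), (10, 2e6, 50.0)])
    def test_formula(self, layout, count, total, expected):
        tr = _track(layout, {"chr1": [count]})
        out = gs.counts_to_rpkm(tr, total)
        assert out.values["chr1"][0] == pytest.approx(expected)
        assert out.units == "rpkm"

    def test_linear_in_counts_inverse_in_total(self, layout):
        rng = np.random.default_rng(0)
        vals = rng.poisson(5, 100).astype(float)
        a = gs.counts_to_rpkm(_track(layout, {"chr1": vals}), 1e6)
        b = gs.counts_to_rpkm(_track(layout, {"chr1": 3 * vals}), 1e6)
        c = gs.counts_to_rpkm(_track(layout, {"chr1": vals}), 2e6)
        assert np.allclose(b.values["chr1"], 3 * a.values["chr1"])
        assert np.allclose(c.values["chr1"], a.values["chr1"] / 2)

    def test_zero_total_errors(self, layout):
        with pytest.raises(ValueError):
            gs.counts_to_rpkm(_track(layout, {"chr1": [1]}), 0)


class TestInputSubtract:
    def test_difference_and_negatives_retained(self, layout):
        sig = _track(layout, {"chr1": [100.0, 0.0]}, units="rpkm")
        ctl = _track(layout, {"chr1": [40.0, 5.0]}, units="rpkm")
        out = gs.input_subtract(sig, ctl)
        assert out.values["chr1"][0] == 60.0
        assert out.values["chr1"][1] == -5.0  # never clipped

    def test_self_subtraction_is_zero(self, layout):
        sig = _track(layout, {"chr1": np.arange(10.0)}, units="rpkm")
        out = gs.input_subtract(sig, sig)
        assert not out.values["chr1"].any()

    def test_bin_mismatch_errors(self, layout):
        with pytest.raises(ValueError):
            gs.input_subtract(_track(layout, {}, 100), _track(layout, {}, 200))


class TestAggregate:
    def test_constant_mean_identity(self, layout):
        tr = _track(layout, {"chr1": np.full(100, 3.25)})
        out = gs.aggregate_to_windows(tr, 5000, "mean")
        assert np.allclose(out.values["chr1"][:2], 3.25)

    def test_sum_of_ones(self, layout):
        tr = _track(layout, {"chr1": np.ones(50)})
        out = gs.aggregate_to_windows(tr, 5000, "sum")
        assert out.values["chr1"][0] == 50.0

    def test_matches_naive_loop(self, layout):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 5, layout.n_bins("chr1", 100))
        tr = _track(layout, {"chr1": vals})
        out = gs.aggregate_to_windows(tr, 1000, "mean")
        naive = [vals[i * 10:(i + 1) * 10].mean()
                 for i in range(len(out.values["chr1"]))]
        assert np.allclose(out.values["chr1"], naive)

    def test_non_multiple_errors(self, layout):
        with pytest.raises(ValueError):
            gs.aggregate_to_windows(_track(layout, {}), 250)


class TestCooccupancy:
    def _fs(self, *coords):
        return ad.FeatureSet([ad.Interval(c, s, e) for c, s, e in coords])

    def test_cross_sample_union_counts(self, layout):
        # mark A hit from sample 1, mark B hit from sample 3 -> included
        a = [self._fs(("chr1", 1000, 1200)), self._fs()]
        b = [self._fs(), self._fs(), self._fs(("chr1", 4000, 4100))]
        table = gs.cooccupancy_windows(a, b, layout, 5000)
        assert len(table) == 1 and table["start"].iloc[0] == 0

    def test_single_mark_window_excluded(self, layout):
        a = [self._fs(("chr1", 1000, 1200))]
        b = [self._fs(("chr1", 80_000, 80_500))]
        table = gs.cooccupancy_windows(a, b, layout, 5000)
        assert len(table) == 0

    def test_empty_mark_gives_empty_table(self, layout):
        a = [self._fs(("chr1", 0, 100))]
        b = [self._fs()]
        assert len(gs.cooccupancy_windows(a, b, layout, 5000)) == 0

    def test_monotone_in_peaks(self, layout):
        a = [self._fs(("chr1", 1000, 1200))]
        b = [self._fs(("chr1", 2000, 2200))]
        base = gs.cooccupancy_windows(a, b, layout, 5000)
        more = gs.cooccupancy_windows(
            a + [self._fs(("chr2", 0, 100))],
            b + [self._fs(("chr2", 50, 150))], layout, 5000)
        base_keys = set(zip(base["chrom"], base["start"]))
        assert base_keys <= set(zip(more["chrom"], more["start"]))

    def test_no_sample_lists_errors(self, layout):
        with pytest.raises(ValueError):
            gs.cooccupancy_windows([], [self._fs()], layout, 5000)


class TestExclusivity:
    def test_exact_anticorrelation(self):
        t = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [4, 3, 2, 1.0]})
        assert gs.exclusivity_summary(t, "a", "b")["pearson_r"] == pytest.approx(-1)

    def test_identical_columns(self):
        x = np.arange(100.0)
        t = pd.DataFrame({"a": x, "b": x})
        s = gs.exclusivity_summary(t, "a", "b", 0.9)
        assert s["pearson_r"] == pytest.approx(1)
        assert s["double_high_fraction"] == pytest.approx(0.1)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(size=6), rng.uniform(size=6)
        s = gs.exclusivity_summary(pd.DataFrame({"a": a, "b": b}), "a", "b", 0.5)
        r = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        frac = np.mean((a > np.quantile(a, .5)) & (b > np.quantile(b, .5)))
        assert s["pearson_r"] == pytest.approx(r)
        assert s["double_high_fraction"] == pytest.approx(frac)

    def test_constant_column_warns_nan(self):
        t = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3.0]})
        with pytest.warns(UserWarning):
            s = gs.exclusivity_summary(t, "a", "b")
        assert np.isnan(s["pearson_r"])


class TestProfile:
    def test_delta_track_peaks_at_zero_offset(self, layout):
        tr = ad.SignalTrack.zeros(layout, 100)
        tr.values["chr1"][50] = 9.0
        anchors = ad.FeatureSet([ad.Interval("chr1", 5000, 5100)])
        _, curve, offsets = gs.profile_around(tr, anchors, 1000)
        assert curve[np.where(offsets == 0)[0][0]] == 9.0
        assert curve.sum() == 9.0

    def test_constant_track_flat(self, layout):
        tr = _track(layout, {"chr1": np.full(10_000, 2.0)})
        anchors = ad.FeatureSet([ad.Interval("chr1", 500_000, 500_100)])
        _, curve, _ = gs.profile_around(tr, anchors, 1000)
        assert np.allclose(curve, 2.0)

    def test_columnwise_means_match_manual(self, layout):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, 200)
        tr = _track(layout, {"chr1": vals})
        anchors = ad.FeatureSet([ad.Interval("chr1", 5000, 5100),
                                 ad.Interval("chr1", 10_000, 10_100)])
        mat, curve, _ = gs.profile_around(tr, anchors, 500)
        mids = [50, 100]
        manual = np.mean([vals[m - 5: m + 6] for m in mids], axis=0)
        assert np.allclose(curve, manual)

    def test_edge_anchor_padded_not_crashed(self, layout):
        tr = _track(layout, {"chr1": np.ones(100)})
        anchors = ad.FeatureSet([ad.Interval("chr1", 0, 100)])
        mat, curve, _ = gs.profile_around(tr, anchors, 1000)
        assert np.isnan(mat[0, 0]) and curve[-1] == 1.0


class TestMethylation:
    def test_pooled_ratio(self, layout):
        calls = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 60],
                              "coverage": [6, 6], "methylated": [3, 6]})
        tr = gs.methylation_windows(calls, layout)
        assert tr.values["chr1"][0] == pytest.approx(9 / 12)

    def test_low_coverage_masked(self, layout):
        calls = pd.DataFrame({"chrom": ["chr1"], "pos": [10],
                              "coverage": [4], "methylated": [2]})
        tr = gs.methylation_windows(calls, layout, min_reads=5)
        assert np.isnan(tr.values["chr1"][0])

    def test_fully_methylated(self, layout):
        calls = pd.DataFrame({"chrom": ["chr1"], "pos": [10],
                              "coverage": [8], "methylated": [8]})
        assert gs.methylation_windows(calls, layout).values["chr1"][0] == 1.0

    def test_impossible_calls_rejected(self, layout):
        calls = pd.DataFrame({"chrom": ["chr1"], "pos": [10],
                              "coverage": [3], "methylated": [5]})
        with pytest.raises(ValueError):
            gs.methylation_windows(calls, layout)


class TestClustering:
    def test_k1_single_label(self):
        labels, _ = gs.cluster_rows(np.random.default_rng(0).normal(size=(20, 3)), 1)
        assert set(labels) == {0}

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, size=(30, 4))
        b = rng.normal(5, 0.1, size=(30, 4))
        labels, order = gs.cluster_rows(np.vstack([a, b]), 2, seed=0)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]
        assert np.array_equal(np.sort(labels[order]), labels[order])

    def test_seed_determinism(self):
        m = np.random.default_rng(5).normal(size=(40, 5))
        l1, _ = gs.cluster_rows(m, 4, seed=11)
        l2, _ = gs.cluster_rows(m, 4, seed=11)
        assert np.array_equal(l1, l2)

    def test_k_exceeds_rows_errors(self):
        with pytest.raises(ValueError):
            gs.cluster_rows(np.zeros((3, 2)), 5)
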