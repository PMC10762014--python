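"""Loop merging, counting, scaling, differential tests, classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import archdelta as ad
from archdelta import InteractionRecord, LoopRecord


def P(chrom, i, j, res=25_000):
    return ad.make_pair(chrom, i * res, (i + 1) * res, j * res, (j + 1) * res)


class TestMergeLoops:
    def test_exact_anchor_union(self):
        l1, l2, l3 = P("chr1", 0, 10), P("chr1", 5, 20), P("chr1", 7, 30)
        merged = ad.merge_loops({"WT": [l1, l2], "KO": [l1, l3]})
        assert len(merged) == 3
        prov = {r.pair.key(): r.provenance for r in merged}
        assert prov[l1.key()] == {"WT", "KO"}
        assert prov[l2.key()] == {"WT"}

    def test_idempotent(self):
        s = [P("chr1", 0, 10), P("chr1", 5, 20)]
        assert len(ad.merge_loops({"a": s, "b": s})) == len(s)

    def test_empty_identity(self):
        s = [P("chr1", 0, 10)]
        merged = ad.merge_loops({"a": [], "b": s})
        assert [r.pair.key() for r in merged] == [p.key() for p in s]

    def test_associative(self):
        a = [P("chr1", 0, 10)]
        b = [P("chr1", 0, 10), P("chr1", 3, 12)]
        c = [P("chr1", 3, 12), P("chr1", 4, 40)]
        ab_c = ad.merge_loops({"ab": [r.pair for r in ad.merge_loops({"a": a, "b": b})],
                               "c": c})
        a_bc = ad.merge_loops({"a": a,
                               "bc": [r.pair for r in ad.merge_loops({"b": b, "c": c})]})
        assert {r.pair.key() for r in ab_c} == {r.pair.key() for r in a_bc}
        assert len(ab_c) <= len(a) + len(b) + len(c)


class TestLoopCounts:
    def _map(self, dense):
        return ad.contact_map_from_dense({"chr1": dense}, 25_000)

    def test_single_cell(self):
        m = np.zeros((40, 40))
        m[3, 17] = m[17, 3] = 10
        loops = [LoopRecord(pair=P("chr1", 3, 17))]
        ad.loop_counts(self._map(m), loops, "WT")
        assert loops[0].counts["WT"] == 10

    def test_empty_region_zero(self):
        loops = [LoopRecord(pair=P("chr1", 2, 9))]
        ad.loop_counts(self._map(np.zeros((20, 20))), loops, "WT")
        assert loops[0].counts["WT"] == 0

    def test_rectangle_sum_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        upper = np.triu(rng.poisson(3, (50, 50)).astype(float))
        m = upper + np.triu(upper, 1).T
        pair = ad.make_pair("chr1", 5 * 25_000, 8 * 25_000,
                            20 * 25_000, 22 * 25_000)
        loops = [LoopRecord(pair=pair)]
        ad.loop_counts(self._map(m), loops, "s")
        brute = sum(m[i, j] for i in range(5, 8) for j in range(20, 22))
        assert loops[0].counts["s"] == pytest.approx(brute)

    def test_anchor_outside_map_errors(self):
        loops = [LoopRecord(pair=P("chr1", 2, 30))]
        with pytest.raises(ValueError):
            ad.loop_counts(self._map(np.zeros((20, 20))), loops, "s")


class TestScaleToSmallest:
    def test_documented_factors(self):
        scaled, factors = ad.scale_to_smallest(
            {"a": np.array([10.0]), "b": np.array([10.0])},
            {"a": 100.0, "b": 50.0})
        assert factors == {"a": 0.5, "b": 1.0}
        assert scaled["a"][0] == 5.0 and scaled["b"][0] == 10.0

    def test_equal_totals_identity(self):
        scaled, factors = ad.scale_to_smallest(
            {"a": np.array([3.0, 4.0]), "b": np.array([5.0, 1.0])},
            {"a": 10.0, "b": 10.0})
        assert all(f == 1.0 for f in factors.values())

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=20),
           st.floats(1, 1e6), st.floats(1, 1e6))
    def test_proportions_and_totals_conserved(self, counts, ta, tb):
        counts = np.asarray(counts, dtype=float)
        scaled, factors = ad.scale_to_smallest(
            {"a": counts, "b": counts * 2}, {"a": ta, "b": tb})
        assert ta * factors["a"] == pytest.approx(tb * factors["b"])
        nz = counts > 0
        if nz.sum() >= 2:
            ratio = scaled["a"][nz] / counts[nz]
            assert np.allclose(ratio, ratio[0])

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            ad.scale_to_smallest({"a": np.array([1.0])}, {"a": 0.0})


class TestDifferentialClassification:
    def test_threshold_rules(self):
        ref = np.array([30.0, 30, 30] + [30.0] * 30)
        obs = np.array([120.0, 9, 33] + [30.0] * 30)
        df = ad.classify_differential(ref, obs)
        assert list(df["class"][:3]) == ["increased", "decreased", "unchanged"]

    def test_label_symmetry_under_sample_swap(self):
        rng = np.random.default_rng(1)
        ref = rng.poisson(30, 100).astype(float)
        obs = ref.copy()
        obs[:10] *= 4
        obs[10:20] = np.maximum(obs[10:20] / 4, 0)
        fwd = ad.classify_differential(ref, obs)["class"]
        rev = ad.classify_differential(obs, ref)["class"]
        swap = {"increased": "decreased", "decreased": "increased"}
        assert list(rev) == [swap.get(c, c) for c in fwd]

    def test_interactions_share_core_with_loops(self):
        rng = np.random.default_rng(2)
        ref = rng.poisson(25, 60).astype(float)
        obs = rng.poisson(25, 60).astype(float)
        obs[:5] *= 5
        recs = [InteractionRecord(pair=P("chr1", i, i + 10),
                                  q_by_sample={"WT": 0.01, "KO": 0.01},
                                  counts={"WT": r, "KO": o})
                for i, (r, o) in enumerate(zip(ref, obs))]
        loops = [LoopRecord(pair=r.pair, counts=dict(r.counts)) for r in recs]
        df_i = ad.differential_interactions(recs, "WT", "KO",
                                            {"WT": 1000.0, "KO": 1000.0})
        df_l = ad.differential_loops(loops, "WT", "KO",
                                     {"WT": 1000.0, "KO": 1000.0})
        assert list(df_i["class"]) == list(df_l["class"])
        assert np.allclose(df_i["q"], df_l["q"])


class TestMultiResMerge:
    def _rec(self, pair, q, counts=None):
        return InteractionRecord(pair=pair, q_by_sample=q, counts=counts or {})

    def test_fully_nested_keeps_highest_resolution(self):
        coarse = ad.make_pair("chr1", 0, 25_000, 100_000, 125_000)
        fine = ad.make_pair("chr1", 10_000, 15_000, 110_000, 115_000)
        out = ad.merge_interactions_multires([
            self._rec(coarse, {"WT": 0.01}), self._rec(fine, {"WT": 0.02})])
        assert [r.pair.key() for r in out] == [fine.key()]

    def test_partial_overlap_keeps_both(self):
        coarse = ad.make_pair("chr1", 0, 25_000, 100_000, 125_000)
        fine = ad.make_pair("chr1", 20_000, 25_000, 120_000, 130_000)
        out = ad.merge_interactions_multires([
            self._rec(coarse, {"WT": 0.01}), self._rec(fine, {"WT": 0.02})])
        assert len(out) == 2

    def test_q_filter_any_sample(self):
        p1 = ad.make_pair("chr1", 0, 25_000, 100_000, 125_000)
        p2 = ad.make_pair("chr1", 0, 25_000, 200_000, 225_000)
        out = ad.merge_interactions_multires([
            self._rec(p1, {"WT": 0.5, "KO": 0.05}),   # kept: any sample
            self._rec(p2, {"WT": 0.5, "KO": 0.2})])   # dropped
        assert [r.pair.key() for r in out] == [p1.key()]


class TestAnchorBinding:
    def _loops(self):
        return [LoopRecord(pair=P("chr1", 4, 20)),
                LoopRecord(pair=P("chr1", 40, 60))]

    def test_precedence_increased_over_unchanged(self):
        inc = ad.FeatureSet([ad.Interval("chr1", 100_000, 100_200, "i")])
        others = ad.FeatureSet([ad.Interval("chr1", 100_300, 100_400, f"u{k}")
                                for k in range(3)])
        df = ad.classify_anchor_binding(self._loops(), inc,
                                        ad.FeatureSet(inc.intervals + others.intervals))
        assert df["anchor_binding"].iloc[0] == "increased"

    def test_unchanged_and_none(self):
        inc = ad.FeatureSet([])
        allp = ad.FeatureSet([ad.Interval("chr1", 1_000_100, 1_000_200, "u")])
        df = ad.classify_anchor_binding(self._loops(), inc, allp)
        assert list(df["anchor_binding"]) == ["none", "unchanged"]


class TestFeaturesInLoops:
    def _classified_loops(self):
        loops = [LoopRecord(pair=P("chr1", 4, 20)),
                 LoopRecord(pair=P("chr1", 40, 60)),
                 LoopRecord(pair=P("chr1", 100, 140))]
        loops[0].cls = "increased"
        loops[1].cls = "decreased"
        return loops

    def test_membership_and_outside(self):
        feats = ad.FeatureSet([
            ad.Interval("chr1", 150_000, 155_000, "inside_inc"),
            ad.Interval("chr1", 4_000_000, 4_005_000, "outside"),
        ])
        mem, dist = ad.features_in_loops(feats, self._classified_loops())
        by = dict(zip(mem["feature"], mem["classes"]))
        assert by["inside_inc"] == "increased"
        assert by["outside"] == "outside"
        obs = dist[dist["set"] == "observed"].set_index("class")["count"]
        assert obs["increased"] == 1 and obs["outside"] == 1

    def test_feature_spanning_two_classes_counted_once_each(self):
        feats = ad.FeatureSet([ad.Interval("chr1", 490_000, 1_010_000, "wide")])
        _, dist = ad.features_in_loops(feats, self._classified_loops())
        obs = dist[dist["set"] == "observed"].set_index("class")["count"]
        assert obs["increased"] == 1 and obs["decreased"] == 1

    def test_random_control_tabulated(self):
        feats = ad.FeatureSet([ad.Interval("chr1", 150_000, 155_000, "g0")])
        universe = ad.FeatureSet(
            feats.intervals +
            [ad.Interval("chr1", i * 10_000, i * 10_000 + 1000, f"g{i+1}")
             for i in range(20)])
        mem, dist = ad.features_in_loops(feats, self._classified_loops(),
                                         universe=universe, random_n=5, seed=1)
        assert (dist[dist["set"] == "random"]["count"].sum()) >= 5
        assert set(mem["set"]) == {"observed", "random"}
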