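"""Differential chromatin loops and significant interactions.

Loops called per sample are merged on exact anchor coordinates, counted
from the contact maps, scaled to the smallest library (every sample's
counts multiplied by min(totals)/total_s so scaled totals agree), and
tested per loop with the two-sided Poisson pairwise test; BH runs across
the loop family.  Increased/decreased calls require q < 0.1 and fold
change > 2 (resp. < 1/2).  Significant interactions at 25/10/5 kb are
filtered to q < 0.1 in any sample, deduplicated across resolutions
(fully nested records keep only the highest resolution), and tested the
same way in their own BH family.  Anchor-peak and feature-in-loop
classification back the loop-centric summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .differential_binding import (bh_adjust, fold_change, poisson_pairwise_test,
                                   sample_matched_random)
from .io_formats import AnchorPair, ContactMap, FeatureSet

logger = logging.getLogger("archdelta")

LOOP_Q = 0.1
LOOP_FC = 2.0


@dataclass
class LoopRecord:
    pair: AnchorPair
    provenance: set = field(default_factory=set)
    counts: dict = field(default_factory=dict)         # sample -> raw count
    scaled: dict = field(default_factory=dict)         # sample -> scaled count
    p: float | None = None
    q: float | None = None
    fc: float | None = None
    cls: str = "unchanged"


def merge_loops(sets: dict[str, list[AnchorPair]]) -> list[LoopRecord]:
    """Union loop lists on exact anchor coordinates.

    Loops from different samples with exactly the same anchors collapse to
    one definition; provenance records which samples called each loop.
    Idempotent and associative; output in first-seen order.
    """
    merged: dict[tuple, LoopRecord] = {}
    for sample, pairs in sets.items():
        for pair in pairs:
            key = pair.key()
            if key not in merged:
                merged[key] = LoopRecord(pair=pair)
            merged[key].provenance.add(sample)
    out = list(merged.values())
    logger.info("merge_loops: %d inputs -> %d merged",
                sum(len(v) for v in sets.values()), len(out))
    return out


def loop_counts(cmap: ContactMap, loops: list[LoopRecord], sample: str) -> None:
    """Raw contact count per loop: sum of map cells in anchor1 x anchor2."""
    bs = cmap.bin_size
    dense_cache: dict[str, np.ndarray] = {}
    for rec in loops:
        p = rec.pair
        if p.anchor1.width % bs or p.anchor2.width % bs:
            raise ValueError("map bin size must divide anchor resolution")
        if p.chrom not in cmap.matrices:
            raise ValueError(f"anchor chromosome {p.chrom} absent from map")
        if p.chrom not in dense_cache:
            dense_cache[p.chrom] = cmap.dense(p.chrom)
        m = dense_cache[p.chrom]
        n = m.shape[0]
        b1 = slice(p.anchor1.start // bs, math.ceil(p.anchor1.end / bs))
        b2 = slice(p.anchor2.start // bs, math.ceil(p.anchor2.end / bs))
        if b1.stop > n or b2.stop > n:
            raise ValueError(f"anchor outside contact map on {p.chrom}")
        rec.counts[sample] = float(m[b1, b2].sum())


def scale_to_smallest(counts: dict[str, np.ndarray],
                      totals: dict[str, float]):
    """Scale each sample's counts down to the smallest library.

    factor_s = min(totals)/total_s; scaled totals all equal min(totals)
    and within-sample proportions are preserved exactly.  Returns
    ``(scaled counts, factors)``.
    """
    if any(t <= 0 for t in totals.values()):
        raise ValueError("library totals must be positive")
    smallest = min(totals.values())
    factors = {s: smallest / t for s, t in totals.items()}
    scaled = {s: np.asarray(c, dtype=float) * factors[s] for s, c in counts.items()}
    return scaled, factors


def classify_differential(
    count_ref: np.ndarray,
    count_obs: np.ndarray,
    q_threshold: float = LOOP_Q,
    fc_threshold: float = LOOP_FC,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Shared statistical core for differential loops and interactions.

    Two-sided Poisson pairwise test on (scaled) counts with equal
    effective totals, BH within the family; increased: q < 0.1 and
    FC > 2; decreased: q < 0.1 and FC < 1/2.  Swapping the two samples
    maps increased to decreased exactly.
    """
    count_ref = np.asarray(count_ref, dtype=float)
    count_obs = np.asarray(count_obs, dtype=float)
    if count_ref.shape != count_obs.shape:
        raise ValueError("count vectors differ in length")
    p = np.array([
        poisson_pairwise_test(r, o, 1.0, 1.0, "two_sided", pseudocount)
        for r, o in zip(count_ref, count_obs)
    ])
    q = bh_adjust(p)
    fc = np.array([fold_change(r, o, 1.0, 1.0, pseudocount)
                   for r, o in zip(count_ref, count_obs)])
    cls = np.where((q < q_threshold) & (fc > fc_threshold), "increased",
                   np.where((q < q_threshold) & (fc < 1.0 / fc_threshold),
                            "decreased", "unchanged"))
    return pd.DataFrame({"count_ref": count_ref, "count_obs": count_obs,
                         "p": p, "q": q, "fc": fc, "class": cls})


def differential_loops(
    loops: list[LoopRecord],
    ref_sample: str,
    obs_sample: str,
    totals: dict[str, float],
    q_threshold: float = LOOP_Q,
    fc_threshold: float = LOOP_FC,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential test over merged loops (obs vs ref).

    Raw per-loop counts are scaled to the smallest library total, then
    classified with :func:`classify_differential`.  Loop records are
    annotated in place; the returned frame carries coordinates.
    """
    for rec in loops:
        if ref_sample not in rec.counts or obs_sample not in rec.counts:
            raise ValueError("loop record missing counts for a sample")
    raw = {s: np.array([rec.counts[s] for rec in loops])
           for s in (ref_sample, obs_sample)}
    scaled, factors = scale_to_smallest(raw, {s: totals[s] for s in raw})
    stats_df = classify_differential(scaled[ref_sample], scaled[obs_sample],
                                     q_threshold, fc_threshold, pseudocount)
    for rec, (_, row) in zip(loops, stats_df.iterrows()):
        rec.scaled = {ref_sample: row["count_ref"], obs_sample: row["count_obs"]}
        rec.p, rec.q, rec.fc = row["p"], row["q"], row["fc"]
        rec.cls = row["class"]
    coords = pd.DataFrame({
        "chrom": [r.pair.chrom for r in loops],
        "start1": [r.pair.anchor1.start for r in loops],
        "end1": [r.pair.anchor1.end for r in loops],
        "start2": [r.pair.anchor2.start for r in loops],
        "end2": [r.pair.anchor2.end for r in loops],
    })
    df = pd.concat([coords, stats_df], axis=1)
    logger.info("differential_loops: %d loops, %d increased, %d decreased "
                "(factors %s)", len(df), int((df["class"] == "increased").sum()),
                int((df["class"] == "decreased").sum()),
                {s: round(f, 4) for s, f in factors.items()})
    return df


@dataclass
class InteractionRecord:
    pair: AnchorPair
    q_by_sample: dict
    counts: dict = field(default_factory=dict)


def merge_interactions_multires(
    calls: list[InteractionRecord],
    q_threshold: float = LOOP_Q,
) -> list[InteractionRecord]:
    """Multi-resolution merge of significant interactions.

    Keeps records with q < 0.1 in at least one sample, then removes any
    lower-resolution record whose both anchors fully contain the anchors
    of a retained higher-resolution record (partial overlaps keep both).
    Output sorted by coordinate.
    """
    kept = [r for r in calls if any(q < q_threshold for q in r.q_by_sample.values())]
    by_chrom: dict[str, list[InteractionRecord]] = {}
    for r in kept:
        by_chrom.setdefault(r.pair.chrom, []).append(r)
    out = []
    for chrom, recs in by_chrom.items():
        drop = set()
        for i, low in enumerate(recs):
            for high in recs:
                if high.pair.resolution >= low.pair.resolution:
                    continue
                h1, h2 = high.pair.anchor1, high.pair.anchor2
                l1, l2 = low.pair.anchor1, low.pair.anchor2
                if (l1.start <= h1.start and h1.end <= l1.end
                        and l2.start <= h2.start and h2.end <= l2.end):
                    drop.add(i)
                    break
        out.extend(r for i, r in enumerate(recs) if i not in drop)
    out.sort(key=lambda r: r.pair.key())
    logger.info("merge_interactions_multires: %d calls -> %d significant -> %d merged",
                len(calls), len(kept), len(out))
    return out


def differential_interactions(
    interactions: list[InteractionRecord],
    ref_sample: str,
    obs_sample: str,
    totals: dict[str, float],
    q_threshold: float = LOOP_Q,
    fc_threshold: float = LOOP_FC,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential test over merged significant interactions.

    Same scaling and statistical core as :func:`differential_loops`; the
    interaction family is BH-adjusted separately from loops.
    """
    raw = {s: np.array([r.counts[s] for r in interactions])
           for s in (ref_sample, obs_sample)}
    scaled, _ = scale_to_smallest(raw, {s: totals[s] for s in raw})
    stats_df = classify_differential(scaled[ref_sample], scaled[obs_sample],
                                     q_threshold, fc_threshold, pseudocount)
    coords = pd.DataFrame({
        "chrom": [r.pair.chrom for r in interactions],
        "start1": [r.pair.anchor1.start for r in interactions],
        "end1": [r.pair.anchor1.end for r in interactions],
        "start2": [r.pair.anchor2.start for r in interactions],
        "end2": [r.pair.anchor2.end for r in interactions],
        "resolution": [r.pair.resolution for r in interactions],
    })
    return pd.concat([coords, stats_df], axis=1)


def _tree(features: FeatureSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in features:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def classify_anchor_binding(
    loops: list[LoopRecord],
    increased_peaks: FeatureSet,
    all_peaks: FeatureSet,
) -> pd.DataFrame:
    """CTCF-binding class of each loop's anchors.

    "increased" if any increased peak overlaps either anchor (precedence
    over everything), else "unchanged" if any other peak overlaps either
    anchor, else "none".
    """
    inc = _tree(increased_peaks)
    all_t = _tree(all_peaks)
    rows = []
    for rec in loops:
        p = rec.pair
        anchors = (p.anchor1, p.anchor2)

        def hits(trees):
            return any(trees.get(p.chrom) and trees[p.chrom].overlap(a.start, a.end)
                       for a in anchors)

        if hits(inc):
            cls = "increased"
        elif hits(all_t):
            cls = "unchanged"
        else:
            cls = "none"
        rows.append({"chrom": p.chrom, "start1": p.anchor1.start,
                     "start2": p.anchor2.start, "loop_class": rec.cls,
                     "anchor_binding": cls})
    return pd.DataFrame(rows)


def features_in_loops(
    features: FeatureSet,
    loops: list[LoopRecord],
    universe: FeatureSet | None = None,
    random_n: int | None = None,
    seed: int = 0,
):
    """Which loop classes each feature falls into, vs a random control.

    A feature "falls into" a loop iff it overlaps (>= 1 bp) the loop span
    [anchor1.start, anchor2.end].  A feature overlapping loops of several
    classes is counted once per class; features overlapping no span count
    as "outside".  When ``universe`` and ``random_n`` are given, a
    number-matched random feature set (drawn from universe minus
    features) is tabulated the same way.

    Returns ``(membership DataFrame, distribution DataFrame)``.
    """
    span_trees: dict[str, IntervalTree] = {}
    for rec in loops:
        s, e = rec.pair.span
        span_trees.setdefault(rec.pair.chrom, IntervalTree()).addi(s, e, rec)

    def tabulate(fs: FeatureSet, label: str):
        classes = ["increased", "decreased", "unchanged", "outside"]
        counts = dict.fromkeys(classes, 0)
        membership = []
        for iv in fs:
            hit_classes = {h.data.cls for h in
                           span_trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)}
            if not hit_classes:
                hit_classes = {"outside"}
            for c in hit_classes:
                counts[c] += 1
            membership.append({"feature": iv.name, "set": label,
                               "classes": ",".join(sorted(hit_classes))})
        dist = pd.DataFrame({"set": label, "class": classes,
                             "count": [counts[c] for c in classes]})
        return membership, dist

    mem, dist = tabulate(features, "observed")
    dists = [dist]
    if universe is not None and random_n is not None:
        control = sample_matched_random(universe, features, random_n, seed)
        mem_r, dist_r = tabulate(control, "random")
        mem += mem_r
        dists.append(dist_r)
    return pd.DataFrame(mem), pd.concat(dists, ignore_index=True)
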