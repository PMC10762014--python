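"""Differential statistics for paired-condition count data.

The core test is a Poisson pairwise comparison: the observed-condition
count is tested against an expected rate derived from the reference count
scaled by the library-size ratio,

    lambda = (count_ref + alpha) * total_obs / total_ref,

with a pseudocount alpha (default 1) guarding zero references.  A
one-tailed Fisher's exact test on the 2x2 count/library table is provided
as the alternative formulation for increased-peak calling; both are
exposed and the result table records which was used.  Multiple testing is
corrected per family with Benjamini-Hochberg.

Thresholds (defaults): increased-peak tiers q < 5e-4 / 1e-5 / 1e-7
(nested low/medium/high); dysregulated genes q < 0.001 and fold change
> 2; dysregulated individual repeats q < 0.01 and fold change > 2 (the
symmetric rule FC < 1/2 defines "down").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import FeatureSet

logger = logging.getLogger("archdelta")

PEAK_TIERS: dict[str, float] = {"low": 5e-4, "medium": 1e-5, "high": 1e-7}
GENE_Q = 1e-3
REPEAT_Q = 1e-2
FC_THRESHOLD = 2.0


@dataclass(frozen=True)
class CountPair:
    """Per-unit counts in two conditions with their library totals."""

    unit_id: str
    count_ref: float
    count_obs: float
    total_ref: float
    total_obs: float

    def __post_init__(self) -> None:
        if self.count_ref < 0 or self.count_obs < 0:
            raise ValueError("negative count")
        if self.total_ref <= 0 or self.total_obs <= 0:
            raise ValueError("library totals must be positive")


def poisson_pairwise_test(
    count_ref: float,
    count_obs: float,
    total_ref: float = 1.0,
    total_obs: float = 1.0,
    direction: str = "two_sided",
    pseudocount: float = 1.0,
) -> float:
    """Poisson p-value for a pairwise count comparison.

    lambda = (count_ref + pseudocount) * total_obs / total_ref.  The
    observed count is rounded to the nearest integer (scaled counts are
    real-valued).  ``increase``: P(X >= obs | lambda); ``decrease``:
    P(X <= obs | lambda); ``two_sided``: 2 * min(tails, 0.5), capped at 1.
    Scaling both totals by the same factor leaves p unchanged.
    """
    if count_ref < 0 or count_obs < 0:
        raise ValueError("negative count")
    if total_ref <= 0 or total_obs <= 0:
        raise ValueError("library totals must be positive")
    lam = (count_ref + pseudocount) * (total_obs / total_ref)
    obs = int(round(count_obs))
    # floor keeps p strictly positive when the tail underflows
    p_inc = max(float(stats.poisson.sf(obs - 1, lam)), 1e-300)
    p_dec = max(float(stats.poisson.cdf(obs, lam)), 1e-300)
    if direction == "increase":
        return min(p_inc, 1.0)
    if direction == "decrease":
        return min(p_dec, 1.0)
    if direction == "two_sided":
        return min(1.0, 2.0 * min(p_inc, p_dec, 0.5))
    raise ValueError(f"unknown direction {direction!r}")


def fisher_increase_test(count_ref: int, count_obs: int,
                         total_ref: int, total_obs: int) -> float:
    """One-tailed Fisher's exact test for enrichment in the observed sample.

    2x2 table: [[count_obs, total_obs - count_obs],
                [count_ref, total_ref - count_ref]].
    """
    cells = [count_obs, total_obs - count_obs, count_ref, total_ref - count_ref]
    if any(c < 0 for c in cells):
        raise ValueError("counts exceed totals or are negative")
    table = [[cells[0], cells[1]], [cells[2], cells[3]]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(count_ref: float, count_obs: float,
                total_ref: float, total_obs: float,
                pseudocount: float = 1.0) -> float:
    """Library-normalized pseudocounted fold change obs/ref."""
    return ((count_obs + pseudocount) / total_obs) / ((count_ref + pseudocount) / total_ref)


def call_increased_peaks(
    pairs: list[CountPair],
    method: str = "fisher",
    tiers: dict[str, float] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Increased-peak calling with nested significance tiers.

    One-tailed (increase) test per peak — Fisher's exact on the count/
    library table or the Poisson pairwise test — then BH across all peaks.
    A peak belongs to every tier whose q threshold it passes, so tier sets
    are nested (high within medium within low).
    """
    if not pairs:
        raise ValueError("empty peak list")
    if tiers is None:
        tiers = dict(PEAK_TIERS)
    order = sorted(tiers.items(), key=lambda kv: -kv[1])  # loosest first
    if method == "fisher":
        p = [fisher_increase_test(int(cp.count_ref), int(cp.count_obs),
                                  int(cp.total_ref), int(cp.total_obs))
             for cp in pairs]
    elif method == "poisson":
        p = [poisson_pairwise_test(cp.count_ref, cp.count_obs, cp.total_ref,
                                   cp.total_obs, "increase", pseudocount)
             for cp in pairs]
    else:
        raise ValueError(f"unknown method {method!r}")
    q = bh_adjust(p)
    rows = []
    for cp, pi, qi in zip(pairs, p, q):
        fc = fold_change(cp.count_ref, cp.count_obs, cp.total_ref, cp.total_obs,
                         pseudocount)
        tier_set = [name for name, thr in order if qi < thr]
        rows.append({
            "unit_id": cp.unit_id, "count_ref": cp.count_ref,
            "count_obs": cp.count_obs, "p": pi, "q": qi, "fc": fc,
            "tiers": ",".join(tier_set),
            "class": "increased" if tier_set else "unchanged",
            "method": method,
        })
    df = pd.DataFrame(rows)
    logger.info("call_increased_peaks(%s): %d peaks, %d increased",
                method, len(df), int((df["class"] == "increased").sum()))
    return df


def call_dysregulated(
    pairs: list[CountPair],
    feature_kind: str,
    pseudocount: float = 1.0,
    fc_threshold: float = FC_THRESHOLD,
) -> pd.DataFrame:
    """Classify genes or individual repeats as up / down / unchanged.

    Two-sided Poisson pairwise test, BH within the family.  ``up``:
    q < q_kind and FC > 2; ``down``: q < q_kind and FC < 1/2; otherwise
    unchanged.  q_kind is 0.001 for genes and 0.01 for repeats.
    """
    if feature_kind == "gene":
        q_thr = GENE_Q
    elif feature_kind == "repeat":
        q_thr = REPEAT_Q
    else:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    if not pairs:
        raise ValueError("empty feature list")
    p = [poisson_pairwise_test(cp.count_ref, cp.count_obs, cp.total_ref,
                               cp.total_obs, "two_sided", pseudocount)
         for cp in pairs]
    q = bh_adjust(p)
    rows = []
    for cp, pi, qi in zip(pairs, p, q):
        fc = fold_change(cp.count_ref, cp.count_obs, cp.total_ref, cp.total_obs,
                         pseudocount)
        if qi < q_thr and fc > fc_threshold:
            cls = "up"
        elif qi < q_thr and fc < 1.0 / fc_threshold:
            cls = "down"
        else:
            cls = "unchanged"
        rows.append({"unit_id": cp.unit_id, "count_ref": cp.count_ref,
                     "count_obs": cp.count_obs, "p": pi, "q": qi, "fc": fc,
                     "class": cls, "kind": feature_kind})
    df = pd.DataFrame(rows)
    logger.info("call_dysregulated(%s): %d features, %d up, %d down",
                feature_kind, len(df), int((df["class"] == "up").sum()),
                int((df["class"] == "down").sum()))
    return df


def sample_matched_random(universe: FeatureSet, exclude: FeatureSet,
                          n: int, seed: int) -> FeatureSet:
    """Number-matched random control features.

    Uniform sample without replacement from ``universe`` minus ``exclude``
    (matched by coordinates), deterministic under ``seed``.
    """
    excluded = exclude.keys()
    eligible = [iv for iv in universe if iv.key() not in excluded]
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} eligible features for n={n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    logger.info("sample_matched_random: n=%d of %d eligible, seed=%d",
                n, len(eligible), seed)
    return FeatureSet([eligible[i] for i in sorted(idx)])
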