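"""Repeat-class composition, exact hypergeometric tests, and bootstrap
empirical p-values.

The hypergeometric two-sided p uses the minimum-likelihood convention:
the sum of probabilities of all outcomes no more likely than the observed
one.  Bootstrap p-values use the add-one empirical formula
p = (1 + #{simulated at least as extreme}) / (1 + n_sim), which is exact
and conservative; the simulated vector is retained so a density of the
null can be plotted as a diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import FeatureSet

logger = logging.getLogger("archdelta")


def repeat_composition(peaks: FeatureSet, repeats: FeatureSet) -> pd.DataFrame:
    """Per-class composition of a peak set against a classed annotation.

    Each peak is assigned the class of its largest-overlap repeat
    (ties broken by overlap length, then annotation start), or
    "unannotated" when no repeat overlaps it.  Proportions sum to 1.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in repeats:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    assigned = []
    for peak in peaks:
        best = None  # (overlap, -start, class)
        for hit in trees.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end):
            rep = hit.data
            ov = min(peak.end, rep.end) - max(peak.start, rep.start)
            key = (ov, -rep.start)
            if best is None or key > best[0]:
                best = (key, rep.cls or "unclassed")
        assigned.append(best[1] if best else "unannotated")
    counts = pd.Series(assigned, dtype=object).value_counts()
    df = pd.DataFrame({"cls": counts.index, "count": counts.to_numpy()})
    df["proportion"] = df["count"] / max(len(peaks), 1)
    return df.reset_index(drop=True)


def hypergeom_test(k: int, n: int, K: int, N: int, tail: str = "two_sided") -> float:
    """Exact hypergeometric tail p-value.

    k successes among n draws from a universe of N containing K successes.
    ``greater``/``less`` are exact tail sums; ``two_sided`` sums every
    outcome whose probability does not exceed that of k (minimum-
    likelihood method).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    lo, hi = max(0, n - (N - K)), min(n, K)
    if not (lo <= k <= hi):
        raise ValueError(f"k={k} outside support [{lo}, {hi}]")
    dist = stats.hypergeom(N, K, n)
    if tail == "greater":
        return float(min(1.0, dist.sf(k - 1)))
    if tail == "less":
        return float(min(1.0, dist.cdf(k)))
    if tail == "two_sided":
        support = np.arange(lo, hi + 1)
        pmf = dist.pmf(support)
        p_obs = dist.pmf(k)
        return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class BootstrapResult:
    observed: float
    simulated: np.ndarray
    p: float
    direction: str
    seed: int
    n_sim: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_sim = len(self.simulated)


def bootstrap_enrichment(
    observed: float,
    sampler: Callable[[np.random.Generator], float],
    n_sim: int = 10_000,
    direction: str = "greater",
    seed: int = 0,
) -> BootstrapResult:
    """Empirical p-value from a seeded null sampler.

    ``sampler(rng)`` draws one statistic from the null.  For ``greater``
    p = (1 + #{sim >= observed}) / (1 + n_sim); ``less`` mirrors;
    ``two_sided`` doubles the smaller tail, capped at 1.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    sims = np.asarray([sampler(rng) for _ in range(n_sim)], dtype=float)
    p_greater = (1 + int(np.sum(sims >= observed))) / (1 + n_sim)
    p_less = (1 + int(np.sum(sims <= observed))) / (1 + n_sim)
    if direction == "greater":
        p = p_greater
    elif direction == "less":
        p = p_less
    elif direction == "two_sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    logger.info("bootstrap_enrichment: observed=%g p=%g (n_sim=%d, %s)",
                observed, p, n_sim, direction)
    return BootstrapResult(observed=float(observed), simulated=sims, p=float(p),
                           direction=direction, seed=seed)
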