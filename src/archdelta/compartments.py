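"""A/B compartment assignment and compartment switching.

Compartments are called per chromosome from the Pearson-correlation
matrix of the distance-normalized (observed/expected) contact map at
25 kb: the first three eigenvectors (largest |eigenvalue|) are computed,
the one whose entries best correlate with accessibility (ATAC signal on
the same grid) is reported as the compartmentalization score, and its
sign is oriented per chromosome so that positive correlates with ATAC.
Positive scores are A, negative are B; |score| <= epsilon (default 0)
is left unclassified.  Switch classes between two conditions follow
directly from the label pair, and feature/switch overlap is tested with
a two-tailed hypergeometric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import hypergeom_test
from .io_formats import ContactMap, SignalTrack

logger = logging.getLogger("archdelta")

MIN_USABLE_BINS = 10


def observed_expected(cmap: ContactMap) -> dict[str, np.ndarray]:
    """Distance-normalized matrix per chromosome.

    expected(d) is the mean over all matrix entries at genomic distance d
    on that chromosome (diagonal included, no smoothing); O/E is
    observed/expected with cells of zero expectation masked as NaN.
    Empty chromosomes are skipped with a warning.
    """
    out = {}
    for chrom in cmap.matrices:
        m = cmap.dense(chrom)
        n = m.shape[0]
        if n == 0 or m.sum() == 0:
            warnings.warn(f"chromosome {chrom} has no contacts; skipped", stacklevel=2)
            continue
        exp_by_d = np.array([m.diagonal(d).mean() for d in range(n)])
        d_idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        expected = exp_by_d[d_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(expected > 0, m / expected, np.nan)
        out[chrom] = oe
    return out


def correlation_eigenvectors(oe: np.ndarray):
    """First three eigenvectors of the O/E Pearson-correlation matrix.

    All-NaN rows (bins with no usable contacts) are dropped, the
    correlation matrix is computed on the remaining rows (isolated masked
    cells fall back to the neutral value 1 before correlation), and the
    three unit-norm eigenvectors of largest |eigenvalue| are re-embedded
    with NaN at masked bins.

    Returns ``(eigvecs (n, 3), eigvals (3,))``.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    good = ~np.all(np.isnan(oe), axis=1)
    if good.sum() < MIN_USABLE_BINS:
        raise ValueError(f"only {int(good.sum())} usable bins (<{MIN_USABLE_BINS})")
    sub = oe[np.ix_(good, good)]
    sub = np.where(np.isnan(sub), 1.0, sub)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(corr, nan=0.0)
    eigvals, eigvecs = np.linalg.eigh(corr)
    top = np.argsort(-np.abs(eigvals))[:3]
    vals = eigvals[top]
    vecs = np.full((n, 3), np.nan)
    vecs[good] = eigvecs[:, top]
    return vecs, vals


@dataclass
class CompartmentProfile:
    """Oriented compartmentalization scores and A/B labels per chromosome."""

    bin_size: int
    table: pd.DataFrame  # chrom, bin, score, label
    chosen_index: dict[str, int]  # 1-based eigenvector index per chromosome
    atac_r: dict[str, float]

    def labels(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "label"].to_numpy()

    def scores(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "score"].to_numpy(float)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def assign_compartments(
    eigs: dict[str, tuple[np.ndarray, np.ndarray]],
    atac: SignalTrack,
    epsilon: float = 0.0,
) -> CompartmentProfile:
    """Choose and orient the compartment eigenvector per chromosome.

    ``eigs`` maps chromosome -> (eigenvectors (n, 3), eigenvalues).  For
    each chromosome the eigenvector with the largest |Pearson r| against
    the ATAC track (ties: lowest index) is chosen and sign-flipped if
    r < 0, so A compartments (positive score) correlate with open
    chromatin.  A chromosome with constant ATAC is left unclassified.
    """
    rows = []
    chosen: dict[str, int] = {}
    atac_r: dict[str, float] = {}
    for chrom, (vecs, _vals) in eigs.items():
        a = atac.values[chrom][: vecs.shape[0]]
        rs = np.array([_pearson(vecs[:, j], a) for j in range(vecs.shape[1])])
        if np.all(np.isnan(rs)):
            warnings.warn(f"ATAC constant on {chrom}; compartments unclassified",
                          stacklevel=2)
            for b in range(vecs.shape[0]):
                rows.append({"chrom": chrom, "bin": b, "score": np.nan,
                             "label": "unclassified"})
            chosen[chrom] = 0
            atac_r[chrom] = np.nan
            continue
        j = int(np.nanargmax(np.abs(rs)))
        score = vecs[:, j].copy()
        r = rs[j]
        if r < 0:
            score = -score
            r = -r
        chosen[chrom] = j + 1
        atac_r[chrom] = float(r)
        for b, s in enumerate(score):
            if np.isnan(s) or abs(s) <= epsilon:
                label = "unclassified"
            else:
                label = "A" if s > 0 else "B"
            rows.append({"chrom": chrom, "bin": b, "score": s, "label": label})
    table = pd.DataFrame(rows, columns=["chrom", "bin", "score", "label"])
    logger.info("assign_compartments: %d bins, chosen eigenvectors %s (r=%s)",
                len(table), chosen, {c: round(v, 3) for c, v in atac_r.items()
                                     if np.isfinite(v)})
    return CompartmentProfile(bin_size=atac.bin_size, table=table,
                              chosen_index=chosen, atac_r=atac_r)


_SWITCH = {("A", "B"): "A->B", ("B", "A"): "B->A",
           ("A", "A"): "unchanged", ("B", "B"): "unchanged"}


def classify_switching(wt: CompartmentProfile, ko: CompartmentProfile) -> pd.DataFrame:
    """Per-bin switch classes between two conditions.

    Classes follow from the label pair alone; any unclassified member
    makes the bin unclassified.  Swapping the conditions maps A->B to
    B->A exactly.  The returned frame carries
    ``attrs["switching_fraction"]`` — switching bins over classified bins.
    """
    wt_t, ko_t = wt.table, ko.table
    if len(wt_t) != len(ko_t) or not (wt_t["chrom"].to_numpy() == ko_t["chrom"].to_numpy()).all():
        raise ValueError("condition profiles are on different grids")
    classes = [
        _SWITCH.get((a, b), "unclassified")
        for a, b in zip(wt_t["label"], ko_t["label"])
    ]
    df = pd.DataFrame({
        "chrom": wt_t["chrom"], "bin": wt_t["bin"],
        "wt_score": wt_t["score"].to_numpy(float),
        "ko_score": ko_t["score"].to_numpy(float),
        "class": classes,
    })
    classified = df["class"] != "unclassified"
    switching = df["class"].isin(["A->B", "B->A"])
    frac = float(switching.sum() / max(int(classified.sum()), 1))
    df.attrs["switching_fraction"] = frac
    logger.info("classify_switching: %.2f%% of %d classified bins switch",
                100 * frac, int(classified.sum()))
    return df


def switch_enrichment(switch_bins: set, feature_bins: set, universe: set):
    """Two-tailed hypergeometric enrichment of features in switching bins.

    Overlap k of feature and switch bins tested against
    hypergeom(N=|universe|, K=|switch|, n=|feature|); fold enrichment is
    (k/n)/(K/N).  Returns ``(p, fold, k)``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (switch_bins <= universe and feature_bins <= universe):
        raise ValueError("switch and feature bins must lie within the universe")
    N, K, n = len(universe), len(switch_bins), len(feature_bins)
    k = len(switch_bins & feature_bins)
    p = hypergeom_test(k, n, K, N, tail="two_sided")
    fold = (k / n) / (K / N) if n > 0 and K > 0 else np.nan
    return p, fold, k
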