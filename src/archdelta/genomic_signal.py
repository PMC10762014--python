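"""Binned 1-D signal quantification and summaries.

ChIP-type signal is quantified in 100 bp bins as input-subtracted RPKM,
aggregated to 5 kb windows for co-occupancy analysis, and summarized as
aggregation profiles around anchor midpoints.  CpG methylation is pooled
into 100 bp windows with a minimum-coverage filter.  Row clustering wraps
seeded k-means for signal heatmaps.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import FeatureSet, GenomeLayout, SignalTrack

logger = logging.getLogger("archdelta")


def counts_to_rpkm(track: SignalTrack, library_total: float | None = None) -> SignalTrack:
    """Reads per kilobase per million mapped reads, per bin.

    value = count / (bin_kb * library_total / 1e6).  Linear in counts,
    inverse-linear in the library total.
    """
    if track.units != "count":
        raise ValueError(f"expected raw counts, got units={track.units!r}")
    total = library_total if library_total is not None else track.library_total
    if total is None:
        total = track.total()
    if total <= 0:
        raise ValueError("library total must be positive")
    denom = (track.bin_size / 1000.0) * (total / 1e6)
    values = {c: v / denom for c, v in track.values.items()}
    out = track.copy_with(values, "rpkm")
    out.library_total = total
    return out


def input_subtract(signal: SignalTrack, control: SignalTrack) -> SignalTrack:
    """Input-subtracted signal (elementwise); negative values are retained."""
    if signal.bin_size != control.bin_size:
        raise ValueError("bin size mismatch between signal and input")
    values = {}
    for chrom, v in signal.values.items():
        u = control.values[chrom]
        if v.shape != u.shape:
            raise ValueError(f"array length mismatch on {chrom}")
        values[chrom] = v - u
    return signal.copy_with(values, f"input_{signal.units}")


def aggregate_to_windows(track: SignalTrack, window_size: int, mode: str = "mean") -> SignalTrack:
    """Re-bin a track to coarser windows by mean (default) or sum.

    ``window_size`` must be a multiple of the bin size; a trailing partial
    window uses only the bins it has.
    """
    if window_size % track.bin_size != 0:
        raise ValueError(f"window {window_size} not a multiple of bin {track.bin_size}")
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown mode {mode!r}")
    step = window_size // track.bin_size
    values = {}
    for chrom, arr in track.values.items():
        n_win = math.ceil(len(arr) / step)
        out = np.empty(n_win)
        for w in range(n_win):
            seg = arr[w * step:(w + 1) * step]
            out[w] = np.nansum(seg) if mode == "sum" else np.nanmean(seg)
        values[chrom] = out
    out_track = SignalTrack(bin_size=window_size, values=values, units=track.units,
                            library_total=track.library_total)
    return out_track


def _windows_hit(peak_sets: Sequence[FeatureSet], layout: GenomeLayout,
                 window_size: int) -> dict[str, np.ndarray]:
    """Boolean per-window flags: window overlaps >=1 peak in >=1 sample."""
    hit = {c: np.zeros(layout.n_bins(c, window_size), dtype=bool)
           for c in layout.chromosomes}
    for fs in peak_sets:
        for iv in fs:
            first = iv.start // window_size
            last = (iv.end - 1) // window_size
            hit[iv.chrom][first:last + 1] = True
    return hit


def cooccupancy_windows(
    peaks_a: Sequence[FeatureSet],
    peaks_b: Sequence[FeatureSet],
    layout: GenomeLayout,
    window_size: int = 5_000,
    signals: dict[str, SignalTrack] | None = None,
) -> pd.DataFrame:
    """Fixed windows carrying both marks.

    Returns exactly the windows that overlap (>=1 bp) at least one mark-A
    peak from any sample AND at least one mark-B peak from any sample.
    Adding peaks can only add windows, never remove them.  Columns: window
    coordinates, per-mark flags, and the mean of each supplied signal track
    over the window.
    """
    if not peaks_a or not peaks_b:
        raise ValueError("each mark needs at least one peak set")
    hit_a = _windows_hit(peaks_a, layout, window_size)
    hit_b = _windows_hit(peaks_b, layout, window_size)
    rows = []
    sig_win = {}
    for name, tr in (signals or {}).items():
        if window_size % tr.bin_size != 0:
            raise ValueError(f"signal {name!r} bin size incompatible with window")
        sig_win[name] = aggregate_to_windows(tr, window_size, "mean")
    for chrom in layout.chromosomes:
        both = hit_a[chrom] & hit_b[chrom]
        for w in np.flatnonzero(both):
            row = {"chrom": chrom, "start": int(w) * window_size,
                   "end": (int(w) + 1) * window_size,
                   "has_mark_a": True, "has_mark_b": True}
            for name, tr in sig_win.items():
                row[name] = tr.values[chrom][w]
            rows.append(row)
    logger.info("cooccupancy_windows: %d windows", len(rows))
    cols = ["chrom", "start", "end", "has_mark_a", "has_mark_b", *sig_win]
    return pd.DataFrame(rows, columns=cols)


def exclusivity_summary(table: pd.DataFrame, col_a: str, col_b: str,
                        high_quantile: float = 0.9) -> dict:
    """Scatter summaries of mutual exclusivity between two signal columns.

    Reports the Pearson correlation of the two columns and the fraction of
    windows jointly above each column's ``high_quantile`` quantile (the
    "double-high fraction").  Mutually exclusive marks give a negative r
    and a double-high fraction below the independence expectation.
    """
    a = table[col_a].to_numpy(float)
    b = table[col_b].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant signal column: correlation undefined", stacklevel=2)
        r = np.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    qa = np.quantile(a, high_quantile)
    qb = np.quantile(b, high_quantile)
    double_high = float(np.mean((a > qa) & (b > qb)))
    return {"pearson_r": r, "double_high_fraction": double_high,
            "high_quantile": high_quantile, "n_windows": len(table)}


def profile_around(track: SignalTrack, anchors: FeatureSet, flank: int):
    """Aggregation profile of a track around anchor midpoints.

    One row per anchor over offsets [-flank, +flank] in track bins; the
    mean curve is the columnwise mean.  Positions beyond chromosome edges
    are NaN-padded and excluded from the mean positionwise.

    Returns ``(matrix, mean_curve, offsets_bp)``.
    """
    if flank % track.bin_size != 0:
        raise ValueError("flank must be a multiple of the bin size")
    k = flank // track.bin_size
    width = 2 * k + 1
    mat = np.full((len(anchors), width), np.nan)
    for r, iv in enumerate(anchors):
        arr = track.values[iv.chrom]
        mid = iv.midpoint // track.bin_size
        lo, hi = mid - k, mid + k + 1
        src_lo, src_hi = max(lo, 0), min(hi, len(arr))
        mat[r, src_lo - lo: src_hi - lo] = arr[src_lo:src_hi]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_curve = np.nanmean(mat, axis=0)
    offsets = (np.arange(width) - k) * track.bin_size
    return mat, mean_curve, offsets


def methylation_windows(
    cpg_calls: pd.DataFrame,
    layout: GenomeLayout,
    window_size: int = 100,
    min_reads: int = 5,
) -> SignalTrack:
    """Pooled CpG methylation ratio per window.

    ``cpg_calls`` columns: chrom, pos, coverage, methylated.  Per window
    the ratio is sum(methylated)/sum(coverage); windows whose pooled
    coverage is below ``min_reads`` aligned reads are masked (NaN).
    """
    if (cpg_calls["methylated"] > cpg_calls["coverage"]).any():
        raise ValueError("methylated count exceeds coverage at some site")
    cov = SignalTrack.zeros(layout, window_size)
    meth = SignalTrack.zeros(layout, window_size)
    for row in cpg_calls.itertuples(index=False):
        b = int(row.pos) // window_size
        cov.values[row.chrom][b] += row.coverage
        meth.values[row.chrom][b] += row.methylated
    values = {}
    for chrom in layout.chromosomes:
        c, m = cov.values[chrom], meth.values[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(c >= min_reads, m / np.where(c > 0, c, 1), np.nan)
        values[chrom] = ratio
    return SignalTrack(bin_size=window_size, values=values, units="ratio")


def feature_counts(track: SignalTrack, features: FeatureSet) -> np.ndarray:
    """Total track signal over each feature (sum of overlapped bins)."""
    bs = track.bin_size
    out = np.empty(len(features))
    for i, iv in enumerate(features):
        arr = track.values[iv.chrom]
        out[i] = arr[iv.start // bs: math.ceil(iv.end / bs)].sum()
    return out


def cluster_rows(matrix: np.ndarray, k: int, seed: int = 0):
    """Seeded k-means over signal rows; returns (labels, row_order).

    k-means++ initialization, squared-Euclidean, 100 iterations max; the
    same seed always yields the same labels.  Rows are returned grouped by
    cluster (stable within clusters).
    """
    from sklearn.cluster import KMeans

    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("clustering input must be finite")
    if k < 1 or k > matrix.shape[0]:
        raise ValueError(f"k={k} invalid for {matrix.shape[0]} rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=100,
                random_state=seed)
    labels = km.fit_predict(matrix)
    order = np.argsort(labels, kind="stable")
    return labels, order
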