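"""Matrix balancing, directionality index, and TAD boundaries.

Contact matrices are balanced with the Knight-Ruiz algorithm (inner-outer
Newton iteration with conjugate-gradient inner solves) so that unmasked
row sums agree; bins with zero marginal are masked beforehand.  The
directionality index (DI) per bin contrasts upstream (A) against
downstream (B) contact sums within a window:

    E = (A + B) / 2
    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)

which is 0 when A = B and scales linearly with counts.  Boundaries are
called by a thresholded sign-transition scan over the DI profile — a
deterministic simplified substitute for HMM-based domain callers, not
equivalent to them — and boundary sets from multiple samples can be
merged with a positional tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ContactMap, contact_map_from_dense

logger = logging.getLogger("archdelta")

DI_WINDOW = 2_000_000      # +/- window for up/downstream sums, bp
KR_TOL = 1e-6
KR_MAX_ITER = 3_000
BOUNDARY_THRESHOLD_SD = 0.4  # x std of nonzero DI per chromosome


class BalanceError(RuntimeError):
    """Knight-Ruiz iteration failed to converge."""


def _kr_vector(A: np.ndarray, tol: float, max_outer: int) -> np.ndarray:
    """Knight-Ruiz balancing vector x with diag(x) A diag(x) row sums 1."""
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise BalanceError(
                f"KR did not converge in {max_outer} outer iterations "
                f"(residual {np.sqrt(rout):.3g})"
            )
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        rho_km2 = rho_km1
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                gamma = np.min((delta - y[neg]) / ap[neg])
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                big = ynew > Delta
                gamma = np.min((Delta - y[big]) / ap[big])
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 10 * n:
                raise BalanceError("KR inner iteration stalled")
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o ** 2 > 0.1:
            eta = max(eta, g * eta_o ** 2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, stop_tol))
    return x


def kr_balance_dense(m: np.ndarray, tol: float = KR_TOL,
                     max_iter: int = KR_MAX_ITER):
    """Balance one symmetric non-negative matrix.

    Rows with zero marginal are masked (left zero, scaling NaN); the
    balanced unmasked rows sum to 1 within ``tol``.  Returns
    ``(balanced, scaling)``.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if (m < 0).any():
        raise ValueError("matrix must be non-negative")
    marg = m.sum(axis=1)
    good = marg > 0
    scaling = np.full(m.shape[0], np.nan)
    balanced = np.zeros_like(m)
    if good.sum() == 0:
        return balanced, scaling
    sub = m[np.ix_(good, good)]
    # pre-scale for conditioning; folded back into the vector
    s = sub.sum(axis=1).mean()
    x = _kr_vector(sub / s, tol, max_iter)
    x = x / np.sqrt(s)
    scaling[good] = x
    balanced[np.ix_(good, good)] = sub * np.outer(x, x)
    return balanced, scaling


def kr_balance(cmap: ContactMap, tol: float = KR_TOL,
               max_iter: int = KR_MAX_ITER):
    """Knight-Ruiz balance every chromosome of a contact map.

    Returns ``(balanced ContactMap, scaling vectors per chromosome)``.
    """
    dense = {}
    scalings = {}
    for chrom in cmap.matrices:
        balanced, scaling = kr_balance_dense(cmap.dense(chrom), tol, max_iter)
        dense[chrom] = balanced
        scalings[chrom] = scaling
        logger.info("kr_balance: %s converged (%d/%d bins unmasked)",
                    chrom, int(np.isfinite(scaling).sum()), len(scaling))
    return contact_map_from_dense(dense, cmap.bin_size), scalings


@dataclass
class DIProfile:
    bin_size: int
    window: int
    table: pd.DataFrame  # chrom, bin, up_sum, down_sum, di

    def di(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "di"].to_numpy(float)


def directionality_index_dense(m: np.ndarray, window_bins: int) -> pd.DataFrame:
    """DI profile for one symmetric dense matrix (window in bins)."""
    n = m.shape[0]
    cs = np.concatenate([np.zeros((n, 1)), np.cumsum(m, axis=1)], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - window_bins, 0)
    hi = np.minimum(idx + window_bins, n - 1)
    up = cs[idx, idx] - cs[idx, lo]            # sum over [i-w, i-1]
    down = cs[idx, hi + 1] - cs[idx, idx + 1]  # sum over [i+1, i+w]
    tot = up + down
    with np.errstate(divide="ignore", invalid="ignore"):
        di = np.where(tot > 0, np.sign(down - up) * (down - up) ** 2 / tot, 0.0)
    return pd.DataFrame({"bin": idx, "up_sum": up, "down_sum": down, "di": di})


def directionality_index(cmap: ContactMap, window: int = DI_WINDOW) -> DIProfile:
    """DI profile of a (balanced) contact map.

    ``window`` is the +/- genomic span in bp and must be a multiple of the
    bin size and at least one bin.
    """
    if window < cmap.bin_size or window % cmap.bin_size != 0:
        raise ValueError("window must be a positive multiple of the bin size")
    w = window // cmap.bin_size
    frames = []
    for chrom in cmap.matrices:
        df = directionality_index_dense(cmap.dense(chrom), w)
        df.insert(0, "chrom", chrom)
        frames.append(df)
    return DIProfile(bin_size=cmap.bin_size, window=window,
                     table=pd.concat(frames, ignore_index=True))


@dataclass
class BoundarySet:
    sample_id: str
    positions: dict[str, np.ndarray]  # strictly increasing bin indices

    def size(self) -> int:
        return int(sum(len(v) for v in self.positions.values()))


def _sign_runs(di: np.ndarray, max_gap: int = 1):
    """Runs of constant DI sign, spanning zero gaps of <= max_gap bins.

    Yields (sign, start, extremum) where extremum is max |DI| in the run.
    """
    runs = []
    cur_sign = 0
    start = 0
    ext = 0.0
    gap = 0
    for i, v in enumerate(di):
        s = int(np.sign(v))
        if s == 0:
            gap += 1
            if cur_sign != 0 and gap > max_gap:
                runs.append((cur_sign, start, ext))
                cur_sign = 0
            continue
        if s == cur_sign:
            gap = 0
            ext = max(ext, abs(v))
        else:
            if cur_sign != 0:
                runs.append((cur_sign, start, ext))
            cur_sign, start, ext, gap = s, i, abs(v), 0
    if cur_sign != 0:
        runs.append((cur_sign, start, ext))
    return runs


def call_boundaries(di_profile: DIProfile, magnitude_threshold: float | None = None,
                    sample_id: str = "sample") -> BoundarySet:
    """Boundary at each strong downstream-bias onset.

    A boundary is placed at the first bin of a positive DI run whose
    preceding negative run reached ``-threshold`` and which itself reaches
    ``+threshold``; runs may bridge zero-DI gaps of one bin.  The default
    threshold is 0.4 x the standard deviation of the nonzero DI values of
    the chromosome.
    """
    positions = {}
    for chrom, sub in di_profile.table.groupby("chrom", sort=False):
        di = sub["di"].to_numpy(float)
        nz = di[di != 0]
        if magnitude_threshold is None:
            thr = BOUNDARY_THRESHOLD_SD * float(np.std(nz)) if len(nz) else np.inf
        else:
            thr = magnitude_threshold
        runs = _sign_runs(di)
        bnds = []
        for prev, cur in zip(runs, runs[1:]):
            if prev[0] == -1 and cur[0] == +1 and prev[2] >= thr and cur[2] >= thr:
                bnds.append(cur[1])
        positions[chrom] = np.asarray(bnds, dtype=int)
        logger.info("call_boundaries: %s -> %d boundaries (threshold %.3g)",
                    chrom, len(bnds), thr)
    return BoundarySet(sample_id=sample_id, positions=positions)


def merge_boundaries(sets: list[BoundarySet], tolerance_bins: int = 1):
    """Merge boundary sets with a positional tolerance.

    Boundaries within ``tolerance_bins`` across sets are unified at the
    floor midpoint of their cluster.  The conservation table reports, for
    each ordered sample pair, the fraction of the first sample's
    boundaries matched within tolerance in the second.

    Returns ``(merged BoundarySet, conservation DataFrame)``.
    """
    chroms = sorted({c for bs in sets for c in bs.positions})
    merged = {}
    for chrom in chroms:
        allpos = np.sort(np.concatenate(
            [bs.positions.get(chrom, np.empty(0, int)) for bs in sets]))
        out = []
        i = 0
        while i < len(allpos):
            j = i
            while j + 1 < len(allpos) and allpos[j + 1] - allpos[j] <= tolerance_bins:
                j += 1
            out.append((int(allpos[i]) + int(allpos[j])) // 2)
            i = j + 1
        merged[chrom] = np.unique(np.asarray(out, dtype=int))
    rows = []
    for a in sets:
        for b in sets:
            if a.sample_id == b.sample_id:
                continue
            n_total = a.size()
            n_hit = 0
            for chrom, pos in a.positions.items():
                other = b.positions.get(chrom, np.empty(0, int))
                for p in pos:
                    if len(other) and np.min(np.abs(other - p)) <= tolerance_bins:
                        n_hit += 1
            rows.append({"sample": a.sample_id, "versus": b.sample_id,
                         "n": n_total,
                         "conserved_fraction": n_hit / n_total if n_total else np.nan})
    return (BoundarySet(sample_id="merged", positions=merged),
            pd.DataFrame(rows, columns=["sample", "versus", "n", "conserved_fraction"]))
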