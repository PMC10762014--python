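"""Genomic file formats and core containers.

All coordinates follow the BED convention: 0-based, half-open.  Contact
matrices are stored upper-triangular per chromosome and indexed from 0 as
``floor(start / bin_size)``.  Strand is ignored throughout — no operation
in this pipeline is stranded.

On-disk dialects:

* intervals — BED / BED-like TSV (3-6+ columns)
* anchor pairs — BEDPE
* tracks — bedGraph, grid-aligned (or exactly rebinnable)
* contacts — plain-text COO triples ``chrom  bin_i  bin_j  count``
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("archdelta")

# Bin sizes used by the pipeline stages, in bp: 1-D quantification,
# co-occupancy windows, compartments/domains, and the two finer
# interaction resolutions.
QUANT_BIN = 100
WINDOW_BIN = 5_000
HIC_BIN = 25_000
INTERACTION_BINS = (25_000, 10_000, 5_000)


class FormatError(ValueError):
    """Malformed record in a genomic text file."""


class LayoutError(ValueError):
    """Record inconsistent with the genome layout."""


# ---------------------------------------------------------------------------
# Genome layout and intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths; the coordinate frame for everything."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise LayoutError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.lengths[chrom] / bin_size)

    def check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.lengths:
            raise LayoutError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise LayoutError(
                f"interval {chrom}:{start}-{end} outside chromosome of "
                f"length {self.lengths[chrom]}"
            )


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    cls: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class FeatureSet:
    """Ordered collection of named intervals (peaks, genes, repeats...)."""

    intervals: list[Interval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def keys(self) -> set[tuple[str, int, int]]:
        return {iv.key() for iv in self.intervals}


@dataclass(frozen=True)
class AnchorPair:
    """Intra-chromosomal anchor pair (loop or significant interaction).

    Anchors are genome-ordered: ``anchor1`` precedes ``anchor2``.  Anchor
    width equals the calling resolution.
    """

    anchor1: Interval
    anchor2: Interval
    resolution: int

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop/interaction anchors must share a chromosome")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def span(self) -> tuple[int, int]:
        return (self.anchor1.start, self.anchor2.end)

    def key(self) -> tuple[str, int, int, int, int]:
        return (self.chrom, self.anchor1.start, self.anchor1.end,
                self.anchor2.start, self.anchor2.end)


def make_pair(chrom: str, s1: int, e1: int, s2: int, e2: int,
              resolution: int | None = None) -> AnchorPair:
    """Build a genome-ordered AnchorPair, inferring resolution from width."""
    if (s1, e1) > (s2, e2):
        s1, e1, s2, e2 = s2, e2, s1, e1
    if resolution is None:
        resolution = e1 - s1
    return AnchorPair(Interval(chrom, s1, e1), Interval(chrom, s2, e2), resolution)


# ---------------------------------------------------------------------------
# Tracks and contact maps
# ---------------------------------------------------------------------------

@dataclass
class SignalTrack:
    """Dense per-chromosome binned values.

    ``units`` is one of {"count", "rpkm", "input_rpkm", "rpm", "normalized",
    "ratio"}.  Raw counts are non-negative; input-subtracted values may be
    negative and are never clipped.  ``library_total`` is required to
    convert counts to RPKM/RPM.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    units: str = "count"
    library_total: float | None = None

    @classmethod
    def zeros(cls, layout: GenomeLayout, bin_size: int, units: str = "count") -> "SignalTrack":
        vals = {c: np.zeros(layout.n_bins(c, bin_size)) for c in layout.chromosomes}
        return cls(bin_size=bin_size, values=vals, units=units)

    def total(self) -> float:
        return float(sum(np.nansum(v) for v in self.values.values()))

    def copy_with(self, values: dict[str, np.ndarray], units: str) -> "SignalTrack":
        return SignalTrack(bin_size=self.bin_size, values=values, units=units,
                           library_total=self.library_total)


@dataclass
class ContactMap:
    """Per-chromosome sparse upper-triangular binned contact counts."""

    bin_size: int
    matrices: dict[str, sp.csr_matrix]

    @property
    def total(self) -> float:
        """Sum of all contacts, diagonal counted once."""
        return float(sum(m.sum() for m in self.matrices.values()))

    def dense(self, chrom: str, symmetric: bool = True) -> np.ndarray:
        """Dense matrix for one chromosome; symmetrized by default."""
        upper = self.matrices[chrom].toarray()
        if not symmetric:
            return upper
        full = upper + upper.T
        np.fill_diagonal(full, np.diag(upper))
        return full

    def n_bins(self, chrom: str) -> int:
        return self.matrices[chrom].shape[0]


def contact_map_from_dense(dense: dict[str, np.ndarray], bin_size: int) -> ContactMap:
    """Store symmetric dense per-chromosome matrices upper-triangular."""
    mats = {}
    for chrom, m in dense.items():
        mats[chrom] = sp.csr_matrix(np.triu(m))
    return ContactMap(bin_size=bin_size, matrices=mats)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_intervals(path: str | Path, layout: GenomeLayout) -> FeatureSet:
    """Read a BED / BED-like file (3-6+ tab-separated columns).

    Input order is preserved; rows without a name column get stable
    identifiers ``feat_<i>``.  Malformed lines raise :class:`FormatError`
    naming the line; intervals outside the layout raise :class:`LayoutError`.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            layout.check(chrom, start, end)
            name = f[3] if len(f) > 3 and f[3] not in ("", ".") else f"feat_{len(intervals)}"
            score = None
            if len(f) > 4 and f[4] not in ("", "."):
                score = float(f[4])
            cls = f[5] if len(f) > 5 and f[5] not in ("", ".") else None
            intervals.append(Interval(chrom, start, end, name, score, cls))
    logger.info("read_intervals: %s -> %d records", path, len(intervals))
    return FeatureSet(intervals)


def write_intervals(features: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in features:
            score = "." if iv.score is None else repr(iv.score)
            cls = iv.cls if iv.cls is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{cls}\n")


def read_pairs(path: str | Path, layout: GenomeLayout) -> list[AnchorPair]:
    """Read BEDPE anchor pairs.

    Anchors are canonicalized so ``anchor1`` precedes ``anchor2``;
    resolution is inferred from anchor width.  Inter-chromosomal records
    are rejected with a warning (the analyses here are intra-chromosomal).
    Duplicates are retained — merging is a separate operation.
    """
    pairs: list[AnchorPair] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            try:
                c1, s1, e1 = f[0], int(f[1]), int(f[2])
                c2, s2, e2 = f[3], int(f[4]), int(f[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if c1 != c2:
                warnings.warn(
                    f"{path}:{lineno}: inter-chromosomal pair {c1}/{c2} rejected",
                    stacklevel=2,
                )
                n_rejected += 1
                continue
            layout.check(c1, s1, e1)
            layout.check(c2, s2, e2)
            pairs.append(make_pair(c1, s1, e1, s2, e2))
    logger.info("read_pairs: %s -> %d pairs, %d rejected", path, len(pairs), n_rejected)
    return pairs


def write_pairs(pairs: Sequence[AnchorPair], path: str | Path,
                extra: "dict[str, Sequence] | None" = None) -> None:
    """Write BEDPE; optional extra columns (counts, p, q, FC, class...)."""
    cols = list(extra or {})
    with open(path, "w") as fh:
        if cols:
            fh.write("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\t" + "\t".join(cols) + "\n")
        for i, p in enumerate(pairs):
            row = [p.chrom, p.anchor1.start, p.anchor1.end,
                   p.chrom, p.anchor2.start, p.anchor2.end]
            row += [extra[c][i] for c in cols]
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_track(path: str | Path, layout: GenomeLayout, bin_size: int) -> SignalTrack:
    """Read a bedGraph into a dense track at ``bin_size``.

    Records must align to the bin grid or be exactly rebinnable: a record
    of width w with ``bin_size % w == 0`` contributes ``value * w/bin_size``
    to its bin (so the bin value is the mean over its sub-bins, absent
    sub-bins counting as 0); a record of width w with ``w % bin_size == 0``
    broadcasts its value to every covered bin.  Missing bins are 0.
    """
    track = SignalTrack.zeros(layout, bin_size)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            layout.check(chrom, start, end)
            w = end - start
            arr = track.values[chrom]
            if w == bin_size and start % bin_size == 0:
                arr[start // bin_size] += value
            elif bin_size % w == 0 and start % w == 0:
                # sub-bin record: fractional contribution to the enclosing bin
                arr[start // bin_size] += value * w / bin_size
            elif w % bin_size == 0 and start % bin_size == 0:
                arr[start // bin_size: end // bin_size] += value
            else:
                raise FormatError(
                    f"{path}:{lineno}: record {chrom}:{start}-{end} not alignable "
                    f"to {bin_size} bp grid"
                )
    track.units = "count"
    return track


def write_track(track: SignalTrack, path: str | Path, skip_zero: bool = True) -> None:
    with open(path, "w") as fh:
        bs = track.bin_size
        for chrom, arr in track.values.items():
            for i, v in enumerate(arr):
                if skip_zero and (v == 0 or np.isnan(v)):
                    continue
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v:g}\n")


def read_contacts(path: str | Path, layout: GenomeLayout, bin_size: int) -> ContactMap:
    """Read COO triples ``chrom  bin_i  bin_j  count`` into a ContactMap.

    Entries are accumulated (duplicate triples sum); pairs are stored upper
    triangular regardless of input order.  Negative counts and bin indices
    outside the chromosome raise errors.
    """
    rows: dict[str, list[tuple[int, int, float]]] = {c: [] for c in layout.chromosomes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 COO columns")
            chrom, i, j, count = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in layout.lengths:
                raise LayoutError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            n = layout.n_bins(chrom, bin_size)
            if not (0 <= i < n and 0 <= j < n):
                raise LayoutError(f"{path}:{lineno}: bin index out of range for {chrom}")
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            if i > j:
                i, j = j, i
            rows[chrom].append((i, j, count))
    mats = {}
    for chrom in layout.chromosomes:
        n = layout.n_bins(chrom, bin_size)
        if rows[chrom]:
            i, j, v = map(np.asarray, zip(*rows[chrom]))
            mats[chrom] = sp.coo_matrix((v.astype(float), (i, j)), shape=(n, n)).tocsr()
        else:
            mats[chrom] = sp.csr_matrix((n, n))
    cmap = ContactMap(bin_size=bin_size, matrices=mats)
    logger.info("read_contacts: %s -> total %g contacts", path, cmap.total)
    return cmap


def write_contacts(cmap: ContactMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, mat in cmap.matrices.items():
            coo = mat.tocoo()
            order = np.lexsort((coo.col, coo.row))
            for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                fh.write(f"{chrom}\t{i}\t{j}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "bins": {"quant": QUANT_BIN, "window": WINDOW_BIN, "hic": HIC_BIN},
    "thresholds": {
        "peak_tiers": {"low": 5e-4, "medium": 1e-5, "high": 1e-7},
        "gene_q": 1e-3,
        "repeat_q": 1e-2,
        "loop_q": 0.1,
        "interaction_q": 0.1,
        "fold_change": 2.0,
    },
    "pseudocount": 1.0,
    "peak_test": "fisher",       # fisher | poisson for increased-peak calling
    "high_quantile": 0.9,
    "epsilon": 0.0,              # unclassified compartment band
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    """DEFAULT_CONFIG overlaid with a YAML file (sections merged shallowly)."""
    import copy

    import yaml

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg
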