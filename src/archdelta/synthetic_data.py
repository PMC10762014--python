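"""Paired-condition synthetic data with machine-readable planted truth.

The generator emulates the statistical structure the analysis assumes:

* ChIP tracks — per-bin Poisson counts over a flat background, with peaks
  adding rate.  In the KO condition, planted "gained" architectural-
  protein (CTCF-like) peaks multiply their rate by the effect ratio while
  the co-located repressive mark (H3K9me3-like) rate is divided by it,
  producing the anticorrelated gain/loss coupling; the input track is
  pure background.
* Expression — Poisson counts per gene/repeat around lognormal base
  rates; planted dysregulated features scale their rate by the fold
  change in KO.
* Contact maps — expected cell rate depth * (d+1)^-alpha times a
  compartment checkerboard factor (same-label boost / cross-label damp),
  a within-TAD boost, and focal loop spikes; Poisson-sampled.  The KO map
  flips compartment labels inside planted switch blocks and scales
  planted loop spikes by the change ratio.

Planted perturbations are kept disjoint (loop anchors avoid switch
blocks) so each recovery test has unambiguous truth.  Everything is
deterministic under (config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (ContactMap, FeatureSet, GenomeLayout, Interval,
                         contact_map_from_dense, make_pair)
from .loops_interactions import InteractionRecord

logger = logging.getLogger("archdelta")

# rng stream codes so stages and conditions draw independent noise
_CODE = {"genome": 1, "tracks": 2, "contacts": 3, "expression": 4,
         "interactions": 5}
_COND = {"WT": 0, "KO": 1}


def _rng(seed: int, stage: str, condition: str = "WT") -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _CODE[stage], _COND[condition]]))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions.

    Rates are per 100 bp bin; depth is the expected contact count of a
    distance-0 cell before structural factors.
    """

    # genome
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 50_000_000, "chr2": 50_000_000})
    quant_bin: int = 100
    window_bin: int = 5_000
    hic_bin: int = 25_000
    # ChIP peaks and tracks
    n_ctcf_peaks: int = 5_000
    n_gained_peaks: int = 200
    gain_ratio: float = 4.0
    coupling: float = 1.0          # scales the reciprocal H3K9me3 loss
    ctcf_peak_width: int = 500
    k9_peak_width: int = 2_000
    n_k9_peaks: int = 3_000
    cooccupied_fraction: float = 0.3  # stable CTCF peaks inside a K9 peak
    background_rate: float = 0.2
    ctcf_peak_rate: float = 10.0
    k9_peak_rate: float = 5.0
    atac_peak_rate: float = 5.0
    atac_open_factor: float = 2.0   # background multiplier in A bins
    atac_closed_factor: float = 0.5
    # expression
    n_genes: int = 2_000
    n_repeats: int = 3_000
    repeat_class_proportions: dict[str, float] = field(default_factory=lambda: {
        "SINE_B2": 0.4, "SINE_Alu": 0.15, "SINE_B4": 0.1,
        "ERVL-MaLR": 0.15, "LINE_L1": 0.2})
    n_up_genes: int = 100
    n_down_genes: int = 50
    n_up_repeats: int = 150
    n_down_repeats: int = 75
    expression_fc: float = 4.0
    gene_base_rate: float = 100.0
    repeat_base_rate: float = 50.0
    rate_sigma: float = 0.5        # lognormal spread of base rates
    # contact maps
    decay_alpha: float = 1.0
    depth: float = 100.0
    comp_block_bins: int = 25
    comp_same_factor: float = 1.6
    comp_cross_factor: float = 0.6
    n_switch_blocks: int = 20
    switch_block_bins: int = 10
    n_tad_boundaries: int = 20
    tad_factor: float = 2.5
    n_loops: int = 500
    loop_factor: float = 15.0
    n_loop_gain: int = 50
    n_loop_loss: int = 0
    loop_change_ratio: float = 3.0
    loop_min_dist_bins: int = 10
    loop_max_dist_bins: int = 100
    # robustness knob only; 0 keeps the Poisson-test assumption exact
    overdispersion: float = 0.0

    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.chrom_lengths))


def null_config(**overrides) -> SimulationConfig:
    """All planted effects set to 1 (no real signal changes)."""
    cfg = SimulationConfig(gain_ratio=1.0, expression_fc=1.0,
                           loop_change_ratio=1.0, n_switch_blocks=0)
    return replace(cfg, **overrides)


def tad_only_config(**overrides) -> SimulationConfig:
    """Block-TAD maps: compartment contrast and loops disabled."""
    cfg = SimulationConfig(comp_same_factor=1.0, comp_cross_factor=1.0,
                           n_loops=0, n_loop_gain=0, n_switch_blocks=0)
    return replace(cfg, **overrides)


@dataclass
class SyntheticTruth:
    """Planted ground truth — the oracle for every recovery test."""

    config: SimulationConfig
    layout: GenomeLayout
    genes: FeatureSet
    repeats: FeatureSet
    ctcf_peaks: FeatureSet
    k9_peaks: FeatureSet
    gained_peaks: pd.DataFrame       # name, chrom, start, end, ratio
    cooccupied_stable: set           # CTCF peak names sitting in a K9 peak
    ctcf_site_factor: dict           # peak name -> occupancy factor (latent)
    k9_site_factor: dict
    dysregulated: pd.DataFrame       # feature, kind, direction, fc
    comp_labels_wt: dict             # chrom -> +1 (A) / -1 (B) per hic bin
    switch_blocks: pd.DataFrame      # chrom, bin_start, bin_end, direction
    tad_boundaries: dict             # chrom -> bin indices
    loops: list                      # AnchorPair, names loop_<i>
    loop_names: list
    loop_changes: pd.DataFrame       # loop, ratio
    gene_rates: np.ndarray
    repeat_rates: np.ndarray

    def comp_labels_ko(self) -> dict:
        labels = {c: v.copy() for c, v in self.comp_labels_wt.items()}
        for row in self.switch_blocks.itertuples(index=False):
            labels[row.chrom][row.bin_start:row.bin_end] *= -1
        return labels

    def labels_for(self, condition: str) -> dict:
        return self.comp_labels_wt if condition == "WT" else self.comp_labels_ko()


# ---------------------------------------------------------------------------
# genome / annotation / truth
# ---------------------------------------------------------------------------

def _class_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder rounding so class counts sum exactly to n."""
    raw = {c: p * n for c, p in proportions.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _spread(total: int, weights: list[int]) -> list[int]:
    """Split `total` across chromosomes proportionally to length."""
    w = np.asarray(weights, dtype=float)
    alloc = np.floor(total * w / w.sum()).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(total * w / w.sum() - alloc))
    for i in order[:rem]:
        alloc[i] += 1
    return alloc.tolist()


def simulate_genome(config: SimulationConfig, seed: int) -> SyntheticTruth:
    """Lay out the genome and plant every truth record.

    Genes are non-overlapping; repeat classes follow the configured
    mixture exactly; planted peak gains, dysregulated features, switch
    blocks, TAD boundaries and loop changes are all chosen here so the
    per-condition samplers only add noise.  Deterministic under seed.
    """
    rng = _rng(seed, "genome")
    layout = config.layout()
    chroms = layout.chromosomes
    lens = [layout.lengths[c] for c in chroms]

    # genes: grid placement guarantees non-overlap
    genes = []
    for chrom, n_g in zip(chroms, _spread(config.n_genes, lens)):
        spacing = layout.lengths[chrom] // max(n_g, 1)
        if spacing < 500:
            raise ValueError("gene packing infeasible for this genome size")
        for i in range(n_g):
            start = i * spacing + int(rng.integers(0, spacing // 4))
            length = int(rng.integers(2_000, min(10_000, spacing // 2)))
            genes.append(Interval(chrom, start, start + length,
                                  f"gene_{len(genes)}", cls="gene"))
    genes_fs = FeatureSet(genes)

    # repeats: random positions, exact class mixture
    counts = _class_counts(config.repeat_class_proportions, config.n_repeats)
    classes = np.array([c for c, k in counts.items() for _ in range(k)])
    rng.shuffle(classes)
    repeats = []
    for chrom, n_r in zip(chroms, _spread(config.n_repeats, lens)):
        starts = rng.integers(0, layout.lengths[chrom] - 400, size=n_r)
        widths = rng.integers(150, 300, size=n_r)
        for s, w in zip(np.sort(starts), widths):
            repeats.append(Interval(chrom, int(s), int(s + w),
                                    f"repeat_{len(repeats)}",
                                    cls=str(classes[len(repeats)])))
    repeats_fs = FeatureSet(repeats)

    # CTCF peaks on a jittered grid; a subset is planted to gain in KO
    ctcf = []
    for chrom, n_p in zip(chroms, _spread(config.n_ctcf_peaks, lens)):
        spacing = layout.lengths[chrom] // max(n_p, 1)
        for i in range(n_p):
            centre = i * spacing + spacing // 2 + int(
                rng.integers(-spacing // 4, spacing // 4))
            s = max(centre - config.ctcf_peak_width // 2, 0)
            ctcf.append(Interval(chrom, s, s + config.ctcf_peak_width,
                                 f"peak_{len(ctcf)}"))
    ctcf_fs = FeatureSet(ctcf)
    gained_idx = rng.choice(len(ctcf), size=config.n_gained_peaks, replace=False)
    gained_idx = np.sort(gained_idx)
    gained = pd.DataFrame({
        "name": [ctcf[i].name for i in gained_idx],
        "chrom": [ctcf[i].chrom for i in gained_idx],
        "start": [ctcf[i].start for i in gained_idx],
        "end": [ctcf[i].end for i in gained_idx],
        "ratio": config.gain_ratio,
    })

    # H3K9me3 peaks: on every gained CTCF site (the coupling substrate),
    # on a stable co-occupied subset, and free-standing elsewhere
    gained_set = set(gained_idx.tolist())
    non_gained = [i for i in range(len(ctcf)) if i not in gained_set]
    n_stable = min(int(round(config.cooccupied_fraction * len(non_gained))),
                   max(config.n_k9_peaks - len(gained_set), 0))
    stable_idx = rng.choice(len(non_gained), size=n_stable, replace=False)
    stable = {non_gained[i] for i in stable_idx}
    # latent exclusivity at stable co-occupied sites: K9 rate scales with
    # 2t and the architectural-protein rate with 2(1-t), mixed by the
    # coupling strength (coupling 0 = independent occupancy)
    c = config.coupling
    t_latent: dict[str, float] = {}
    ctcf_site_factor: dict[str, float] = {}
    k9_site_factor: dict[str, float] = {}
    for i in sorted(stable):
        t = float(rng.uniform())
        u = float(rng.uniform())
        t_latent[ctcf[i].name] = t
        ctcf_site_factor[ctcf[i].name] = 2.0 * (c * (1.0 - t) + (1.0 - c) * u)
    k9 = []

    def k9_at(centre: int, chrom: str) -> Interval:
        s = max(centre - config.k9_peak_width // 2, 0)
        e = min(s + config.k9_peak_width, layout.lengths[chrom])
        return Interval(chrom, s, e, f"k9_{len(k9)}")

    for i in sorted(gained_set | stable):
        peak = k9_at(ctcf[i].midpoint, ctcf[i].chrom)
        if i in stable:
            k9_site_factor[peak.name] = 2.0 * t_latent[ctcf[i].name]
        k9.append(peak)
    n_free = max(config.n_k9_peaks - len(k9), 0)
    for chrom, n_f in zip(chroms, _spread(n_free, lens)):
        for s in np.sort(rng.integers(0, layout.lengths[chrom] - config.k9_peak_width,
                                      size=n_f)):
            k9.append(k9_at(int(s) + config.k9_peak_width // 2, chrom))
    k9_fs = FeatureSet(k9)

    # dysregulated features
    dys_rows = []
    for kind, feats, n_up, n_down in (
            ("gene", genes_fs, config.n_up_genes, config.n_down_genes),
            ("repeat", repeats_fs, config.n_up_repeats, config.n_down_repeats)):
        pick = rng.choice(len(feats), size=n_up + n_down, replace=False)
        for j, i in enumerate(np.sort(pick)):
            direction = "up" if j < n_up else "down"
            fc = config.expression_fc if direction == "up" else 1 / config.expression_fc
            dys_rows.append({"feature": feats[int(i)].name, "kind": kind,
                             "direction": direction, "fc": fc})
    dysregulated = pd.DataFrame(
        dys_rows, columns=["feature", "kind", "direction", "fc"])

    # compartment checkerboard and planted switch blocks
    comp_labels = {}
    for chrom in chroms:
        n = layout.n_bins(chrom, config.hic_bin)
        block_id = np.arange(n) // config.comp_block_bins
        comp_labels[chrom] = np.where(block_id % 2 == 0, 1, -1)
    switch_rows = []
    if config.n_switch_blocks:
        per_chrom = _spread(config.n_switch_blocks,
                            [layout.n_bins(c, config.hic_bin) for c in chroms])
        for chrom, n_s in zip(chroms, per_chrom):
            n = layout.n_bins(chrom, config.hic_bin)
            n_blocks = n // config.comp_block_bins
            chosen = rng.choice(n_blocks - 1, size=n_s, replace=False)
            for b in np.sort(chosen):
                start = int(b) * config.comp_block_bins
                end = start + config.switch_block_bins
                wt = comp_labels[chrom][start]
                switch_rows.append({
                    "chrom": chrom, "bin_start": start, "bin_end": end,
                    "direction": "A->B" if wt == 1 else "B->A"})
    switch_blocks = pd.DataFrame(
        switch_rows, columns=["chrom", "bin_start", "bin_end", "direction"])

    # TAD boundaries, roughly evenly spaced with jitter
    tad_boundaries = {}
    per_chrom = _spread(config.n_tad_boundaries, lens)
    for chrom, n_b in zip(chroms, per_chrom):
        n = layout.n_bins(chrom, config.hic_bin)
        spacing = n // (n_b + 1)
        pos = []
        for i in range(n_b):
            jitter = int(rng.integers(-spacing // 4, spacing // 4 + 1))
            pos.append((i + 1) * spacing + jitter)
        tad_boundaries[chrom] = np.array(sorted(pos), dtype=int)

    # loops: anchors avoid switch blocks so planted effects stay disjoint
    forbidden = {c: np.zeros(layout.n_bins(c, config.hic_bin), dtype=bool)
                 for c in chroms}
    for row in switch_rows:
        forbidden[row["chrom"]][row["bin_start"]:row["bin_end"]] = True
    loops, loop_names = [], []
    per_chrom = _spread(config.n_loops, lens)
    seen = set()
    for chrom, n_l in zip(chroms, per_chrom):
        n = layout.n_bins(chrom, config.hic_bin)
        made = 0
        while made < n_l:
            i = int(rng.integers(0, n - config.loop_max_dist_bins - 1))
            d = int(rng.integers(config.loop_min_dist_bins,
                                 config.loop_max_dist_bins + 1))
            j = i + d
            if forbidden[chrom][i] or forbidden[chrom][j] or (chrom, i, j) in seen:
                continue
            seen.add((chrom, i, j))
            bs = config.hic_bin
            loops.append(make_pair(chrom, i * bs, (i + 1) * bs,
                                   j * bs, (j + 1) * bs))
            loop_names.append(f"loop_{len(loop_names)}")
            made += 1
    n_changed = config.n_loop_gain + config.n_loop_loss
    change_rows = []
    if n_changed:
        pick = rng.choice(len(loops), size=n_changed, replace=False)
        for j, i in enumerate(np.sort(pick)):
            ratio = (config.loop_change_ratio if j < config.n_loop_gain
                     else 1 / config.loop_change_ratio)
            change_rows.append({"loop": loop_names[int(i)], "ratio": ratio})
    loop_changes = pd.DataFrame(change_rows, columns=["loop", "ratio"])

    # expression base rates (shared by both conditions)
    gene_rates = config.gene_base_rate * rng.lognormal(
        0, config.rate_sigma, size=len(genes_fs))
    repeat_rates = config.repeat_base_rate * rng.lognormal(
        0, config.rate_sigma, size=len(repeats_fs))

    logger.info("simulate_genome: %d genes, %d repeats, %d CTCF peaks "
                "(%d gained), %d K9 peaks, %d loops (%d changed)",
                len(genes_fs), len(repeats_fs), len(ctcf_fs), len(gained),
                len(k9_fs), len(loops), len(loop_changes))
    return SyntheticTruth(
        config=config, layout=layout, genes=genes_fs, repeats=repeats_fs,
        ctcf_peaks=ctcf_fs, k9_peaks=k9_fs, gained_peaks=gained,
        cooccupied_stable={ctcf[i].name for i in stable},
        ctcf_site_factor=ctcf_site_factor, k9_site_factor=k9_site_factor,
        dysregulated=dysregulated, comp_labels_wt=comp_labels,
        switch_blocks=switch_blocks, tad_boundaries=tad_boundaries,
        loops=loops, loop_names=loop_names, loop_changes=loop_changes,
        gene_rates=gene_rates, repeat_rates=repeat_rates)


# ---------------------------------------------------------------------------
# per-condition samplers
# ---------------------------------------------------------------------------

def _sample_counts(rng: np.random.Generator, rate: np.ndarray,
                   overdispersion: float) -> np.ndarray:
    if overdispersion <= 0:
        return rng.poisson(rate).astype(float)
    # gamma-Poisson mixture for robustness experiments only
    shape = 1.0 / overdispersion
    return rng.poisson(rng.gamma(shape, rate / shape)).astype(float)


def simulate_tracks(truth: SyntheticTruth, condition: str, seed: int):
    """ChIP/input/ATAC count tracks and peak lists for one condition.

    Returns ``(tracks, peaks)`` where tracks maps
    {"ctcf", "h3k9me3", "atac", "input"} to raw-count SignalTracks and
    peaks maps {"ctcf", "h3k9me3"} to FeatureSets (peak definitions are
    shared between conditions, as after cross-sample merging).
    """
    cfg = truth.config
    rng = _rng(seed, "tracks", condition)
    layout = truth.layout
    bs = cfg.quant_bin
    gained = set(truth.gained_peaks["name"])
    labels = truth.labels_for(condition)

    rates = {name: {c: np.full(layout.n_bins(c, bs), cfg.background_rate)
                    for c in layout.chromosomes}
             for name in ("ctcf", "h3k9me3", "atac", "input")}

    # ATAC background follows compartment openness
    ratio_bins = cfg.hic_bin // bs
    for chrom in layout.chromosomes:
        factor = np.where(labels[chrom] == 1, cfg.atac_open_factor,
                          cfg.atac_closed_factor)
        per_bin = np.repeat(factor, ratio_bins)[: layout.n_bins(chrom, bs)]
        if len(per_bin) < layout.n_bins(chrom, bs):
            per_bin = np.pad(per_bin, (0, layout.n_bins(chrom, bs) - len(per_bin)),
                             constant_values=1.0)
        rates["atac"][chrom] *= per_bin

    for iv in truth.ctcf_peaks:
        r = cfg.ctcf_peak_rate * truth.ctcf_site_factor.get(iv.name, 1.0)
        if condition == "KO" and iv.name in gained:
            r *= cfg.gain_ratio
        sl = slice(iv.start // bs, math.ceil(iv.end / bs))
        rates["ctcf"][iv.chrom][sl] += r
        rates["atac"][iv.chrom][sl] += cfg.atac_peak_rate

    gained_lookup = {(row.chrom, row.start, row.end)
                     for row in truth.gained_peaks.itertuples(index=False)}
    gained_mid = {}
    for row in truth.gained_peaks.itertuples(index=False):
        gained_mid.setdefault(row.chrom, []).append((row.start + row.end) // 2)
    for iv in truth.k9_peaks:
        r = cfg.k9_peak_rate * truth.k9_site_factor.get(iv.name, 1.0)
        if condition == "KO":
            mids = gained_mid.get(iv.chrom, ())
            if any(iv.start <= m < iv.end for m in mids):
                r *= cfg.gain_ratio ** (-cfg.coupling)
        sl = slice(iv.start // bs, math.ceil(iv.end / bs))
        rates["h3k9me3"][iv.chrom][sl] += r

    from .io_formats import SignalTrack
    tracks = {}
    for name, per_chrom in rates.items():
        values = {c: _sample_counts(rng, r, cfg.overdispersion)
                  for c, r in per_chrom.items()}
        tr = SignalTrack(bin_size=bs, values=values, units="count")
        tr.library_total = tr.total()
        tracks[name] = tr
    peaks = {"ctcf": truth.ctcf_peaks, "h3k9me3": truth.k9_peaks}
    logger.info("simulate_tracks(%s): totals %s", condition,
                {k: int(t.library_total) for k, t in tracks.items()})
    return tracks, peaks


def _loop_cells(truth: SyntheticTruth):
    cells = {}
    bs = truth.config.hic_bin
    changed = dict(zip(truth.loop_changes["loop"], truth.loop_changes["ratio"]))
    for pair, name in zip(truth.loops, truth.loop_names):
        i = pair.anchor1.start // bs
        j = pair.anchor2.start // bs
        cells.setdefault(pair.chrom, []).append((i, j, changed.get(name, 1.0)))
    return cells


def contact_rate_matrix(truth: SyntheticTruth, condition: str,
                        chrom: str) -> np.ndarray:
    """Expected (noise-free) contact rate matrix for one chromosome."""
    cfg = truth.config
    n = truth.layout.n_bins(chrom, cfg.hic_bin)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    rate = cfg.depth / (d + 1.0) ** cfg.decay_alpha
    labels = truth.labels_for(condition)[chrom]
    same = np.equal.outer(labels, labels)
    rate *= np.where(same, cfg.comp_same_factor, cfg.comp_cross_factor)
    bounds = truth.tad_boundaries.get(chrom, np.empty(0, int))
    domain = np.searchsorted(bounds, np.arange(n), side="right")
    rate *= np.where(np.equal.outer(domain, domain), cfg.tad_factor, 1.0)
    for i, j, ratio in _loop_cells(truth).get(chrom, ()):
        f = cfg.loop_factor * (ratio if condition == "KO" else 1.0)
        rate[i, j] *= f
        rate[j, i] *= f
    return rate


def simulate_contacts(truth: SyntheticTruth, condition: str, seed: int):
    """Poisson-sampled contact map plus the called-loop list.

    Upstream loop calling is out of scope, so the emitted "called" loops
    are the planted anchor pairs (identical across samples, as after
    exact-anchor merging).  Returns ``(ContactMap, called_loops)``.
    """
    cfg = truth.config
    rng = _rng(seed, "contacts", condition)
    dense = {}
    for chrom in truth.layout.chromosomes:
        rate = contact_rate_matrix(truth, condition, chrom)
        upper = np.triu(rate)
        counts = _sample_counts(rng, upper, cfg.overdispersion)
        dense[chrom] = counts + np.triu(counts, 1).T
    cmap = contact_map_from_dense(dense, cfg.hic_bin)
    logger.info("simulate_contacts(%s): total %g contacts", condition, cmap.total)
    return cmap, list(truth.loops)


def emit_interaction_calls(truth: SyntheticTruth, seed: int,
                           maps: dict[str, ContactMap]) -> list[InteractionRecord]:
    """Significance-called interaction records at three resolutions.

    Upstream interaction significance is a declared input here: 25 kb
    records cover the planted loop cells with per-sample q drawn below
    the retention threshold, and a subset also appears as fully nested
    5 kb records (exercising the highest-resolution rule); background
    pairs get q above threshold.  Counts for the 25 kb records are read
    from the supplied per-sample maps.
    """
    cfg = truth.config
    rng = _rng(seed, "interactions")
    bs = cfg.hic_bin
    records = []
    for pair in truth.loops:
        q = {s: float(rng.uniform(0.0, 0.09)) for s in maps}
        rec = InteractionRecord(pair=pair, q_by_sample=q)
        for s, cmap in maps.items():
            m = cmap.matrices[pair.chrom]
            i = pair.anchor1.start // bs
            j = pair.anchor2.start // bs
            rec.counts[s] = float(m[i, j])
        records.append(rec)
        if rng.uniform() < 0.2:  # nested finer-resolution duplicate
            fine = 5_000
            off = int(rng.integers(0, bs // fine)) * fine
            nested = make_pair(pair.chrom,
                               pair.anchor1.start + off, pair.anchor1.start + off + fine,
                               pair.anchor2.start + off, pair.anchor2.start + off + fine)
            records.append(InteractionRecord(
                pair=nested, q_by_sample=dict(q),
                counts={s: rec.counts[s] for s in maps}))
    # background pairs that fail the q filter
    n = truth.layout.n_bins(truth.layout.chromosomes[0], bs)
    for _ in range(max(len(truth.loops) // 10, 1)):
        i = int(rng.integers(0, n - 20))
        j = i + int(rng.integers(5, 20))
        chrom = truth.layout.chromosomes[0]
        records.append(InteractionRecord(
            pair=make_pair(chrom, i * bs, (i + 1) * bs, j * bs, (j + 1) * bs),
            q_by_sample={s: float(rng.uniform(0.2, 1.0)) for s in maps},
            counts={s: float(maps[s].matrices[chrom][i, j]) for s in maps}))
    return records


def simulate_expression(truth: SyntheticTruth, condition: str, seed: int):
    """Gene/repeat count tables for one condition.

    Returns a DataFrame (feature, kind, count) plus the library total;
    planted features scale their base rate by the fold change in KO.
    """
    cfg = truth.config
    rng = _rng(seed, "expression", condition)
    fc = dict(zip(truth.dysregulated["feature"], truth.dysregulated["fc"]))
    rows = []
    for feats, rates, kind in ((truth.genes, truth.gene_rates, "gene"),
                               (truth.repeats, truth.repeat_rates, "repeat")):
        r = rates.copy()
        if condition == "KO":
            for i, iv in enumerate(feats):
                if iv.name in fc:
                    r[i] *= fc[iv.name]
        counts = _sample_counts(rng, r, cfg.overdispersion)
        for iv, c in zip(feats, counts):
            rows.append({"feature": iv.name, "kind": kind, "count": float(c)})
    df = pd.DataFrame(rows)
    total = float(df["count"].sum())
    logger.info("simulate_expression(%s): total %g", condition, total)
    return df, total


# ---------------------------------------------------------------------------
# truth report
# ---------------------------------------------------------------------------

def truth_report(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Lossless tabular dump of the planted truth."""
    tad = pd.DataFrame(
        [{"chrom": c, "bin": int(b)} for c, pos in truth.tad_boundaries.items()
         for b in pos])
    loops = pd.DataFrame({
        "loop": truth.loop_names,
        "chrom": [p.chrom for p in truth.loops],
        "start1": [p.anchor1.start for p in truth.loops],
        "end1": [p.anchor1.end for p in truth.loops],
        "start2": [p.anchor2.start for p in truth.loops],
        "end2": [p.anchor2.end for p in truth.loops],
    })
    return {
        "gained_peaks": truth.gained_peaks.copy(),
        "dysregulated": truth.dysregulated.copy(),
        "switch_blocks": truth.switch_blocks.copy(),
        "tad_boundaries": tad,
        "loops": loops,
        "loop_changes": truth.loop_changes.copy(),
    }


def write_truth(truth: SyntheticTruth, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in truth_report(truth).items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
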