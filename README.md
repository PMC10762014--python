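# archdelta

Differential chromatin-architecture analysis for paired-condition
epigenomics experiments (e.g. wild-type vs knockout of a heterochromatin
writer).  The package provides, as a tested reusable library with a thin
CLI, the downstream statistics that such studies chain together:

* **Differential binding / expression** — Poisson pairwise test
  (λ = (n_ref + α)·T_obs/T_ref, exact tails) and one-tailed Fisher's
  exact test, Benjamini–Hochberg per family, nested significance tiers
  for increased peaks (q < 5·10⁻⁴ / 10⁻⁵ / 10⁻⁷), dysregulation rules
  (genes q < 0.001, repeats q < 0.01, |log₂FC| > 1), number-matched
  random controls.
* **A/B compartments** — per-chromosome eigendecomposition of the
  Pearson correlation of the observed/expected contact matrix at 25 kb;
  the first three eigenvectors, selection and sign-orientation by
  correlation with ATAC accessibility (A = positive score); switch
  classification between conditions and two-tailed hypergeometric switch
  enrichment.
* **Domains** — Knight–Ruiz matrix balancing; directionality index
  DI = sign(B−A)·((A−E)²+(B−E)²)/E over a ±2 Mb window; a deterministic
  sign-transition boundary caller; cross-sample boundary merging with a
  conservation table.
* **Loops / significant interactions** — exact-anchor loop merging,
  rectangle contact counting, scale-to-smallest library normalization,
  differential calls at q < 0.1 and FC > 2 (or < ½), multi-resolution
  interaction merging (fully nested records keep the highest
  resolution), anchor-binding and gene-in-loop classification.
* **Enrichment** — repeat-class composition by largest overlap, exact
  hypergeometric tests (minimum-likelihood two-sided), and 10,000-draw
  bootstrap empirical p-values.
* **Synthetic data** — a generator that plants gained peaks coupled to
  repressive-mark loss, dysregulated genes/repeats, compartment
  checkerboards with switch blocks, TAD blocks, and loop spikes — with
  machine-readable truth, so the whole pipeline is testable offline.

## Worked example

Simulate a small paired-condition dataset, quantify an architectural
protein's ChIP counts over its peaks, and call increased binding:

```python
import archdelta as ad
import archdelta.genomic_signal as gs

cfg = ad.SimulationConfig(chrom_lengths={"chr1": 10_000_000},
                          n_ctcf_peaks=500, n_gained_peaks=25, n_k9_peaks=300,
                          n_genes=200, n_repeats=400, n_up_genes=10, n_down_genes=5,
                          n_up_repeats=12, n_down_repeats=6,
                          n_switch_blocks=4, n_tad_boundaries=4,
                          n_loops=60, n_loop_gain=6)
truth = ad.simulate_genome(cfg, seed=0)
tracks_wt, peaks = ad.simulate_tracks(truth, "WT", seed=0)
tracks_ko, _ = ad.simulate_tracks(truth, "KO", seed=0)

wt, ko = tracks_wt["ctcf"], tracks_ko["ctcf"]
pairs = [ad.CountPair(p.name, r, o, wt.total(), ko.total())
         for p, r, o in zip(truth.ctcf_peaks,
                            gs.feature_counts(wt, truth.ctcf_peaks),
                            gs.feature_counts(ko, truth.ctcf_peaks))]
result = ad.call_increased_peaks(pairs, method="fisher")
print(result.loc[result["class"] == "increased",
                 ["unit_id", "count_ref", "count_obs", "q", "fc", "tiers"]].head(5))
```

```
    unit_id  count_ref  count_obs             q        fc            tiers
2    peak_2       63.0      262.0  1.144421e-24  3.738449  low,medium,high
9    peak_9       73.0      229.0  7.190460e-16  2.827560  low,medium,high
22  peak_22       53.0      252.0  1.318060e-26  4.262285  low,medium,high
72  peak_72       62.0      251.0  3.510892e-23  3.638947  low,medium,high
78  peak_78       54.0      245.0  6.124007e-25  4.069004  low,medium,high
```

Each row is a peak whose KO read count is significantly enriched over
the library-size-adjusted WT expectation; `q` is the BH-adjusted
one-tailed Fisher p, `fc` the pseudocounted library-normalized fold
change, and `tiers` the nested significance levels passed.  On this
dataset all 25 planted 4× gains are recovered and nothing else:

```
called 25 increased peaks; 25/25 planted gains recovered
```

The same flow works from the shell:

```bash
archdelta simulate --seed 0 --out data/
archdelta diff-peaks --data data/ --out peaks.tsv
archdelta compartments --data data/ --out switches.tsv
archdelta domains --data data/ --condition WT --out boundaries.tsv
archdelta loops --data data/ --out loops.tsv
```

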