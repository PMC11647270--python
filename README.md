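# spotsim

Simulation and benchmarking of differential gene expression analysis for
spot-based spatial transcriptomics (Visium-like) data.

## The problem

Spot-based spatial platforms capture transcripts from *mixtures* of cells:
each capture spot holds anywhere from a couple to hundreds of cells of
several types, transcripts diffuse ("leak") into neighboring spots, and
sequencing depth per spot is far shallower than in single-cell RNA-seq.
Most studies nevertheless call differentially expressed genes (DEGs)
between annotated tissue regions with tests designed for bulk or
single-cell data. Whether those calls can be trusted is impossible to
check on real tissue, because no spatial dataset comes with a known answer
key.

`spotsim` builds that answer key. It simulates two-condition single-cell
data with *injected, validated* DEGs, assembles the cells into spots on a
2D array, layers on the technology's artifacts, and scores any DEG calling
strategy against the known truth. Its headline analysis is **prior-based
gene selection**: using a gene–cell specificity score learned from
single-cell data to restrict testing (and the FDR correction) to genes
whose expression belongs predominantly to one cell type — the genes whose
between-condition signal survives cellular mixing.

## Model summary

- **Single cells.** Counts are negative binomial per (gene *g*, cell type
  *c*): mean μ_gc, variance μ + μ²/θ_g. Condition A uses reference means;
  in condition B a fraction `p_de` of genes per cell type is scaled by
  2^(±logFC). A four-criterion QC confirms the realized counts honor the
  requested ground truth before any tissue is built.
- **Tissue.** Spots grow by a random walk on a pseudo-hexagonal lattice
  (doubled-column Visium convention), are split into two contiguous,
  mutually exclusive condition regions, and receive Poisson-distributed
  cell loads per type under uniform/sparse and high/low-density states.
- **Artifacts.** Leakage: a Poisson share (`bleed_rate`) of each spot's
  transcripts is redistributed over a row-normalized Gaussian kernel
  (background included); the global transcript total is conserved exactly.
  Downsampling: each spot is thinned to a Normal-drawn target around
  `pct × total` (multinomial, or without replacement in `accurate` mode);
  the depth can be auto-selected by Kolmogorov–Smirnov matching against a
  reference's per-gene count distributions.
- **Specificity.** For gene *g*, `score[g, c] = x_gc / Σ_j x_gj` with *x*
  either the per-type mean expression (`mean`) or the per-type detection
  frequency (`frequency`); rows sum to 1. A gene is kept when its top
  score clears a threshold and is then attributed to that argmax type
  only; Benjamini–Hochberg runs with m = number of selected genes.
- **Evaluation.** Per (method, cell type): sensitivity TP/(TP+FN),
  specificity TN/(TN+FP), precision TP/(TP+FP), F1 = harmonic mean of
  precision and sensitivity, all against the injected ground truth.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

DEG recovery collapses when moving from single-cell space to realistic
spatial data (mixing + leakage + downsampling):

```python
import spotsim as s

prior = s.make_sc_prior(n_genes=400, n_cell_types=3, seed=11)
cfg = s.SimConfig(n_genes=400, n_cell_types=3, n_spots=250,
                  array_rows=40, array_cols=40, n_cells_per_type=1500)
table = s.run_experiment(prior, cfg, n_replicates=5, seed=1,
                         stages=("ST-M", "ST-LD", "SC"), methods=("ttest",))
print(table.groupby("stage")[["sensitivity", "specificity", "f1"]].mean().round(3))
```

```
       sensitivity  specificity     f1
stage
SC           0.938        0.999  0.962
ST-LD        0.018        0.998  0.032
ST-M         0.073        0.997  0.101
```

The same t-test that recovers almost every injected DEG on single cells
(F1 ≈ 0.96) drops to F1 ≈ 0.10 once cells are mixed into spots (ST-M) and
to ≈ 0.03 with leakage and downsampling added (ST-LD) — the false-positive
rate stays controlled (specificity ≈ 1), it is sensitivity that collapses.

Prior-based specificity selection recovers much of the loss in the
practical "regional" setting (two condition regions, no composition
knowledge), and does so because of *which* genes it keeps, not how many —
a size-matched random selection gains nothing:

```python
import pandas as pd

prior = s.make_sc_prior(800, 5, seed=11)
cfg = s.SimConfig(n_genes=800, n_cell_types=5, n_spots=200, array_rows=40,
                  array_cols=40, n_cells_per_type=1200,
                  uniformity_prob=1.0, density_high_prob=1.0, density_high_rate=6.0)
df = pd.concat([s.run_specificity_benchmark(prior, cfg, (0.25, 0.35, 0.45, 0.55), seed=i)
                for i in range(5)])
print(df.pivot_table(index="threshold", columns="selection", values="mean_f1").round(3))
```

```
selection  prior  random
threshold
0.25       0.226   0.199
0.35       0.467   0.195
0.45       0.606   0.166
0.55       0.637   0.171
```

Mean F1 rises with the specificity threshold for the prior-based
selection (0.23 → 0.64) while the matched random baseline stays flat
around 0.17–0.20: the trade-off is losing non-specific genes, which —
as the ST-LD numbers above show — could not be reliably tested anyway.

## Command line

Every stage is also a CLI subcommand operating on MTX directories:

```bash
spotsim --config params.json --outdir run build-tissue
spotsim --outdir run leak --bleed-rate 0.3
spotsim --outdir run downsample --pct 0.05 --accurate
spotsim --outdir run deg --method ttest --input-mode containing
spotsim --outdir run specificity --metric mean --threshold 0.3
spotsim --outdir run evaluate --baseline-stage ST-LD
```

`params.json` needs only the keys you want to override (`{"seed": 1}` is
valid); all other parameters take documented defaults, including the
seven standard candidate downsampling depths (10, 7, 5, 3, 2, 1, 0.5 %).

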