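# nerupture

Quantification pipeline for **nuclear-envelope (NE) rupture** live-cell
imaging. When a ~2-µm spot of the NE is ruptured (e.g. by 405-nm laser
microirradiation), nucleoplasmic proteins such as the diffusible pool of
lamin C rapidly accumulate at the rupture site, NLS-tagged reporters leak
into the cytoplasm until the envelope reseals, and factors like BAF and cGAS
are recruited. This package implements the image-quantification and
statistical workflow for such experiments — and, because raw microscope data
for this kind of study are rarely shareable, it ships a synthetic time-lapse
generator with exact ground truth so that every stage of the analysis is
verifiable end to end.

Intended users: cell biologists and image analysts quantifying NE rupture /
repair time lapses, and method developers who need a fully ground-truthed
test bed for intensity-kinetics pipelines.

## What it computes

**Compartment segmentation** (`nerupture.segment`). The nucleus is
recognized from the NLS-reporter channel (Gaussian smoothing, Otsu or fixed
threshold, hole filling, largest component). Compartments follow the
erosion convention used in CellProfiler-style NE measurements: with nucleus
mask *N* and disk structuring elements,

- NE ring: `N \ erode(N, r_ne)` with `r_ne = 3 px` (207 nm at 69 nm/px),
- nucleoplasm: `erode(N, r_np)` with `r_np = 10 px` (690 nm),
- the 3–10 px band in between is reported separately, never merged.

Circular ROIs are specified physically (center in µm, diameter in µm) and
rasterized by pixel-center inclusion.

**Kinetics** (`nerupture.kinetics`). Site traces are the per-frame max (or
mean) over the ROI after a σ = 2.0 px Gaussian filter. Normalizations:
initial-frame (`I(t)/I(0)`, so traces start at exactly 1) and per-cell peak
(max exactly 1, ties to the earliest frame). The C/N leakage ratio is
`(mean_cyto − bg) / (mean_nuc − bg)` per frame. FRAP traces use the
two-step (double) normalization

```
F(t) = [(B(t) − G(t)) / (R(t) − G(t))] / mean_pre[(B − G)/(R − G)]
```

(bleached *B*, nuclear reference *R*, background *G*, five pre-bleach
frames), which cancels acquisition photobleaching exactly. Model fits:
saturating accumulation `1 + A(1 − e^{−k_acc (t−t0)})` and FRAP recovery
`F_∞ − (F_∞ − F0) e^{−k_rec t}` with mobile fraction
`M = (F_∞ − F0)/(1 − F0)`, both by bounded multistart least squares.

**Statistics** (`nerupture.stats`). Mann–Whitney U (exact by enumeration at
small tie-free n, tie/continuity-corrected normal approximation otherwise);
Kruskal–Wallis with the Steel–Dwass all-pairs post-hoc (studentized-range
reference, seeded permutation mode as an internal oracle); two-sided
Smirnov–Grubbs far-outlier screening at P < 0.001, applied iteratively; and
a linear mixed model `value ~ group + time + group×time` with a random
intercept per subject cell (REML), testing the group-by-time interaction
with a Wald F.

**Synthetic generator** (`nerupture.simgen`). Renders two-channel stacks
(lamin-like probe with a bright NE rim plus nucleoplasmic pool; NLS-like
reporter) with: saturating site accumulation whose effective amplitude
scales with the nucleoplasmic pool fraction (zero if the pool was
photobleached before rupture), closed-form two-compartment reporter leakage
with resealing, FRAP bleach/recovery, per-frame acquisition bleaching, and
Poisson + Gaussian noise. Ground truth (noiseless compartment traces and
masks) is returned alongside every stack.

## Worked example

The packaged demo simulates two cohorts of five cells that differ only in
nucleoplasmic pool fraction (0.7 vs 0.05 — a lamin-C-like vs lamin-A-like
probe), segments each cell, measures site accumulation and C/N traces, and
compares the cohorts:

```
$ nerupture demo --out demo_out --seed 1
{
  "endpoint_mann_whitney": {
    "U": 25.0, "groups": ["large-pool", "small-pool"],
    "method": "mann-whitney-exact", "p": 0.007936507936507936
  },
  "enrichment_positive_fraction": {
    "large-pool": 1.0, "small-pool": 0.0
  },
  "mixed_model_interaction": {
    "F": 461.40667137080317, "df": [1, 186], "groups": [...],
    "method": "lmm-reml-wald-F", "p": 2.9137154117368094e-52
  }
}
```

Reading the output: every large-pool cell is scored enrichment-positive at
the rupture site (fold ≥ 1.5 over its own NE ring) and no small-pool cell
is; the 180-s endpoint intensities separate the cohorts (exact Mann–Whitney
p ≈ 0.008, the smallest attainable at n = 5 per group); and the mixed model
finds a decisive group-by-time interaction — the two probes accumulate at
different rates, which is the biological contrast the pipeline is built to
detect. `demo_out/` also contains the tidy `traces.csv`, per-cell
`cells.csv`, and a run manifest.

Other subcommands (`simulate`, `segment`, `kinetics`, `frap`, `stats`,
`run`) expose the stages individually; each takes `--config` (YAML/JSON),
`--out`, and `--seed`, and writes a manifest for reproducibility. The same
functionality is available as a library (`import nerupture`).

## Layout

```
src/nerupture/
  simgen.py    synthetic time-lapse generator with ground truth
  segment.py   nucleus / NE-ring / nucleoplasm / cytoplasm masks, ROIs
  kinetics.py  traces, normalizations, FRAP, model fits
  stats.py     rank tests, Grubbs screening, mixed model
  io.py        TIFF/CSV/JSON formats, configs, manifests
  cli.py       click CLI and pipeline orchestration
docs/methods.md   model and design notes
tests/            pytest suite (unit, property, end-to-end)
```
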