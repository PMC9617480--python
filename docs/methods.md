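# Methods and design notes

## The measurement problem

A focused laser pulse ruptures a ~2-µm spot of the nuclear envelope (NE).
Three quantities characterize the response in live-cell time lapses:

1. **Site accumulation** — how fast a fluorescent probe (e.g. a lamin
   isoform, BAF, or cGAS) concentrates at the rupture site, read as the
   ROI max intensity over time, normalized to the pre-rupture frame;
2. **Reporter leakage** — loss of compartmentalization, read as the
   cytoplasmic-to-nuclear (C/N) intensity ratio of an NLS-tagged reporter;
3. **Mobility** — the diffusible fraction of a probe, read by FRAP.

The package implements these measurements, the compartment definitions they
rely on, and the statistics used to compare conditions; a synthetic
generator supplies stacks with exact ground truth so every stage can be
validated without microscope data.

## Compartment definitions

The nucleus is segmented from the NLS-reporter channel: Gaussian smoothing
(σ = 1 px), a global threshold (Otsu by default; a fixed threshold is kept
for fully deterministic tests), hole filling, an area filter, then the
largest connected component. From the nucleus mask, with disk structuring
elements:

- **NE ring** = nucleus ∖ erode(nucleus, r_ne), r_ne = 3 px. At the default
  69 nm/px this is a 207-nm band — the resolution-limited rim where the
  lamina sits.
- **Nucleoplasm** = erode(nucleus, r_np), r_np = 10 px (690 nm), i.e. only
  pixels deeper than the rim's point-spread halo.
- The 3–10 px **intermediate band** belongs to neither compartment and is
  reported as its own mask; merging it silently into either compartment
  would bias both means.
- **Cytoplasm** = cell mask ∖ dilate(nucleus, r_ne) when a cell mask
  exists; otherwise a 10-px-wide band starting 3 px outside the nucleus.
  The band is a package convention — C/N measurements in the literature
  rarely state their cytoplasmic ROI — and is chosen wide enough to average
  shot noise but close enough to stay inside the cell.

A square structuring element (chessboard metric) is available purely as an
oracle cross-check; the disk matches the isotropic "depth from the rim"
semantics. Per-frame re-segmentation is the default (nuclei deform after
rupture); a frozen-mask mode is what the FRAP path effectively uses, since
its reference region must be stable.

## Kinetic measurements

ROI traces are computed per frame as the configured statistic (max by
default, mean optional) over the ROI after a 2-D Gaussian filter with
σ = 2.0 px and reflective borders. σ = 0 disables filtering. Two
normalizations are provided, both idempotent and invariant under global
intensity scaling:

- **initial**: divide by the first acquired frame (exactly one pre-rupture
  frame is assumed; the first normalized value is exactly 1);
- **peak**: divide by the per-cell maximum (ties resolve to the earliest
  frame, which keeps plateaued traces well-defined).

Background handling for the C/N ratio defaults to *none* (matching the
plain ratio-of-means definition); constant, ROI-based, and darkest-1%
modes exist for data with an appreciable offset.

### FRAP

With bleached-spot trace B, nuclear reference R, and background G, the
double-normalized trace is

    F(t) = [(B−G)/(R−G)] / mean_pre[(B−G)/(R−G)],

using the five pre-bleach frames. Any multiplicative factor shared by B and
R — acquisition photobleaching, laser drift — cancels exactly; the
pre-bleach mean is 1 by construction. Recovery is fit as
F(t) = F∞ − (F∞ − F0)e^(−k_rec t) (t from the bleach) by bounded least
squares (0 ≤ F0 ≤ F∞ ≤ 1.5, k ≥ 0) from three deterministic starts; the
mobile fraction is M = (F∞ − F0)/(1 − F0) and the half-time ln2/k_rec.
A flat post-bleach trace yields M = 0 with the rate flagged unidentifiable
rather than an arbitrary number.

A property worth knowing: measuring the spot through a σ = 2 filter mixes
unbleached signal into B, raising the apparent floor and plateau — but the
double-normalized **mobile fraction is invariant under such linear mixing**
(the mixing coefficient cancels in (F∞ − F0)/(1 − F0)). The tests verify
both the mixed (σ = 2, max) and unmixed (σ = 0, mean) routes.

### Accumulation fits and derived scores

Initial-normalized site traces are fit for t ≥ t0 to
1 + A(1 − e^(−k_acc(t−t0))). Degenerate (flat) traces resolve to the nested
A = 0 model with the rate flagged unidentifiable. Two scalar scores are
conventions of this package, stated as such:

- **onset time**: first time the trace reaches 1.2-fold sustained for two
  consecutive frames (none if never);
- **enrichment call**: site statistic divided by the same cell's NE-ring
  statistic, positive iff ≥ 1.5-fold (ties positive). The pipeline measures
  this fold unfiltered (σ = 0) and excludes the site plus an 8-px halo from
  the reference ring: a σ = 2 filter attenuates a 3-px-thin ring far more
  than the extended site plaque, which would inflate the fold for probes
  that do not accumulate at all.

## Statistics

- **Mann–Whitney U**, two-sided, midrank ties. Exact p by full enumeration
  of labelings when both n ≤ 8 and the pooled sample is tie-free; otherwise
  the normal approximation with tie and continuity corrections. The exact
  route is checked against an independent combinatorial enumeration.
- **Kruskal–Wallis** with tie correction, χ² reference on k−1 df.
- **Steel–Dwass** all-pairs comparison: each pair is ranked on its own, the
  standardized rank sum z is referred to the studentized range with k
  groups and infinite df (p = P(Q_{k,∞} ≥ √2|z|)). A seeded single-step
  max-|z| permutation mode serves as the internal oracle for the analytic
  route.
- **Smirnov–Grubbs**, two-sided, at the far-outlier level α = 0.001:
  G = max|x−mean|/sd against
  G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) t-quantile with
  n−2 df. Applied **iteratively** (re-tested after each removal) by
  default — a single-pass mode exists — and the result depends only on the
  multiset of values.
- **Linear mixed model** for longitudinal traces:
  value ~ group + time + group×time with a random intercept per subject
  cell, fit by REML. Time enters as a continuous covariate by default
  (traces are trace-shaped; a categorical-time mode exists for saturated
  designs). The interaction is tested with a Wald F on (q, n_obs − k_fixed)
  df, which reduces exactly to the OLS interaction F-test when the
  cell-level variance is zero. The optimizer's convergence flag alone is
  not treated as failure (it trips spuriously when a variance component
  sits at its boundary); only non-finite estimates or a collapsed scale
  trigger the documented OLS fallback, which is flagged in the result with
  the caveat that within-cell correlation is then ignored. Calibration is
  verified by simulation: the null rejection rate at α = 0.05 over 500
  runs falls inside the 95% binomial band.

The module exposes the Mann–Whitney endpoint comparison and the mixed model
side by side; reports always name the method used — there is no silent
selection.

## The synthetic generator

The generator emulates the experimental regimes, not the microscope optics.
Geometry: an elliptical nucleus (rim of `rim_width` = 3 px) inside an
elliptical cell on a 192×192 px field at 69 nm/px. Defaults for the
kinetics are chosen to be realistic for this assay class and are
illustrative, not fitted to any dataset:

| parameter | default | meaning |
|---|---|---|
| frame_interval | 10 s | rupture time-lapse sampling |
| rupture_frame | 1 | irradiation after the first acquired frame |
| amplitude A | 2.0 | saturating fold-increase at the site per unit pool |
| k_acc | 0.02 s⁻¹ | accumulation rate; puts the 1.2-fold onset in the tens of seconds |
| pool_fraction | 0.7 | lamin-C-like diffusible pool (0.05 mimics lamin A) |
| leak_conductance g | 0.01 s⁻¹ | reporter exchange while the rupture is open |
| reseal_time | 120 s | open window |
| V_n : V_c | 1 : 3 | compartment volumes |
| beta | 0 | acquisition bleaching per frame |
| FRAP | 5 pre-frames, 60 post, 500 ms, b = 0.3, M = 0.8, k_rec = 0.1 s⁻¹ | point-scan protocol |

Model choices (the experiments report curves, not models, so the simplest
forms with recoverable parameters are used):

- **Accumulation**: single-exponential saturation
  I_site(t) = baseline·[1 + A_eff(1 − e^(−k_acc(t−t0)))], with
  A_eff = A·pool_fraction, and A_eff = 0 if the nucleoplasmic pool was
  photobleached before rupture — encoding that only the diffusible pool
  feeds the site.
- **Leakage**: two-compartment well-mixed exchange
  dn/dt = −(g/V_n)(n−c), dc/dt = +(g/V_c)(n−c) with g(t) = g on
  [t0, t0+reseal] and 0 after, solved in closed form per piece (no ODE
  tolerance questions; total amount V_n·n + V_c·c is conserved to machine
  precision). The closed form is cross-checked against an independent
  numerical integration in the tests.
- **FRAP**: spot = I_pre·[b + M(1−b)(1 − e^(−k_rec(t−t_bleach)))], with the
  reference region untouched except by acquisition bleaching and noise.
- **Noise**: per-pixel Poisson on the (bleached) signal scaled by a photon
  gain, then additive Gaussian read noise — applied last, as a detector
  would see it. "SNR s" in the tests means photon_gain = s²/level at the
  stated signal level. Seeds are explicit fields; there is no global random
  state.

Ground truth records the noiseless, bleach-free per-frame value of every
compartment as rendered (signal plus the constant cellular background
offset), with the site ROI carved out of the ring/nucleoplasm/cytoplasm
truth masks so that rendered means equal truth values exactly.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: diffusion-limited transport (accumulation is
painted uniformly over the site ROI, not as a growing plaque), nuclear
deformation and drift, chromatin texture and nucleoli (the "mean intensity
excluding nucleoli" question does not arise), 3-D structure, detector
nonlinearity, and cell-to-cell variability beyond what the caller injects
via per-cell parameters. Conclusions about estimator correctness transfer;
conclusions about segmentation robustness on textured nuclei do not.

## Numerical and interface conventions

- Pixel indices are 0-based (row, column); physical coordinates in µm with
  the origin at the top-left pixel center. Frame f is at t = f·Δt, the
  first acquired frame at t = 0.
- Stacks are plain multi-page TIFF, frame-major T,C,Y,X pages, uint16 on
  disk; an axes declaration in the config replaces OME metadata.
- Traces travel as tidy CSV (cell_id, condition, channel, roi, frame,
  time_s, raw, normalized, normalization), sorted by (cell_id, frame);
  FRAP CSVs carry bleached/reference/background/normalized columns.
- Normalization denominators are guarded: a non-positive baseline, peak, or
  background-subtracted reference raises a typed error, never a silent
  division.
- Every CLI run emits one manifest (config hash, seed, version, paths,
  timestamp). All randomness descends from the run seed through
  `numpy.random.SeedSequence`; data outputs are byte-reproducible for a
  fixed (config, seed). The manifest timestamp is the only
  non-reproducible byte.
- Demo/test problem sizes (160×160 fields, 5–50 cells per study, 500-run
  calibration simulations) are chosen so the whole suite runs in about a
  minute on one CPU while keeping every statistical band comfortably
  resolvable.

## Known limitations

- The Steel–Dwass studentized-range reference is an asymptotic
  approximation; at very small groups (n < 5) the permutation mode is the
  safer route.
- The mixed model's Wald F uses residual-count df, not a Satterthwaite or
  Kenward–Roger correction; with very few cells it can be mildly liberal.
  The simulation-based calibration test bounds the practical effect at the
  study's design sizes.
- Mann–Whitney switches to the normal approximation whenever ties are
  present, even at small n; midrank exact enumeration is not implemented.
- The enrichment and onset thresholds (1.5-fold, 1.2-fold / 2 frames) are
  package conventions for scoring simulations, not measured constants.
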