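# Methods

## The measurement being emulated

A single pancreatic alpha cell expressing a glucagon–pHluorin biosensor is
imaged by TIRF microscopy while the perifusion buffer steps through a
protocol of glucose concentrations and drugs. Each granule fusion produces a
sudden flash — dark-to-bright within one frame — that decays over a few
hundred milliseconds as the fluorophore diffuses and re-acidifies. Secretion
is quantified as flashes per 100 µm² of footprint per minute. The scientific
questions the analysis answers are (a) at which glucose concentration
release switches from inhibited to stimulated, and (b) whether that switch
disappears when the glucose sensor (glucokinase) is knocked down.

## Dose–response model

Rates are in events / 100 µm² / min. The wildtype cell releases at `r_stim`
when the *effectively sensed* glucose lies in the stimulatory range
(default [1, 3] mM), at `r_inhib` above it, and again at `r_inhib` in
glucose-free buffer (`zero_glucose_suppressed`, default on): removing
glucose entirely collapses the ATP/ADP ratio, re-activates K_ATP channels
and shuts release down rather than stimulating it further.

Defaults `r_inhib = 1.0`, `r_stim = 2.0` encode the constrained *two-fold*
stimulation; absolute magnitudes are free parameters of the simulation (the
per-cell source rates of the original recordings are not published in a
machine-readable form), so only the ratio and orderings should be read as
biology. The knockdown genotype releases at the flat intermediate
`r_kd = 1.5` at every glucose concentration (`r_inhib < r_kd < r_stim`).

Treatments act through the effective sensed glucose:

| treatment | effect | rationale |
|---|---|---|
| 2-deoxy-glucose, 5-thio-glucose (10 mM) | any non-zero glucose sensed as stimulatory | glycolysis blocked downstream of transport; metabolic flux falls as in hypoglycaemia |
| glucokinase activator (0.1–10 µM) | sensed glucose = actual + 1 mM | activated glucokinase phosphorylates more at the same glucose; 3 mM then inhibits like 4 mM; concentration-independent over the tested range |
| mannoheptulose (10 mM) | none | requires GLUT2 for uptake, which rat alpha cells lack |
| arginine (10 mM) | `r_stim` regardless of glucose | direct depolarization, bypasses the metabolic sensor — also under knockdown |
| washout | excluded from analysis; rendered at `r_inhib` | transitional buffer state |

Under knockdown, all metabolism-routed treatments collapse to `r_kd`;
arginine still stimulates because it acts downstream of glucose sensing.
This is a deliberate modelling choice — the knockdown pharmacology was never
recorded, so these branches are untested extrapolations.

## Event sampling and rendering

Per protocol step, the event count is Poisson with mean
`rate × area/100 × duration/60`; onset times are uniform within the step,
positions uniform over mask pixels with sub-pixel jitter, amplitudes i.i.d.
**lognormal** with mean `amplitude_mean` and CV `amplitude_cv`. Lognormal
was chosen over normal because flash brightness is a product of granule
cargo and illumination factors and cannot be negative; it also has the
thinner left tail, which matters for detectability.

A flash contributes, from its onset frame `f0`, a 2-D Gaussian of sd
`psf_sigma_um` (default 0.4 µm ≈ 1.44 px) with peak
`amplitude × exp(−(f − f0)·Δt / τ)`, τ = 0.27 s (three frames). The rise is
instantaneous within one frame, matching the single-frame spike morphology
of real recordings. Flash kinetics are not published numerically; these
defaults make single events unambiguous at default noise while letting
border flashes bleed measurably into neighboring grid squares, which is what
exercises the spillover rule.

Camera model: constant background (default 50 counts) with linear bleaching
(1e-4 /s), optional Poisson shot noise on the total signal (on by default),
Gaussian read noise (default sd 20 counts; `amplitude_mean` defaults to 8×
this), clipped to the 16-bit range. Background and read noise were fixed so
that read noise dominates the per-square trace noise (shot noise on a
50-count background adds ~3% to the trace sd), giving a square-centered
mean-amplitude flash a trace SNR ≈ 10. Intensities stay floating-point
internally; quantization to 16-bit happens only at TIFF write, so noise-free
renders are analytically exact.

Determinism: all randomness flows through `numpy.random.SeedSequence`
spawning (one child per cell, split into event and noise streams), so a run
is bit-reproducible from (config, seed), independent of chunking or cell
count changes elsewhere.

## Event calling

* **Grid**: 10 × 10 px squares anchored at the top-left corner of the mask
  bounding box (the original analysis does not state alignment); partial
  edge squares are retained when they overlap the mask, and traces are
  per-square *means* so partial squares remain comparable.
* **Traces**: mean intensity of each square per frame.
* **Peaks**: a frame is a peak iff it is a local maximum, exceeds the
  rolling-median baseline (21 frames) by `k_sigma = 5` × robust noise sd
  (1.4826 × MAD of the baseline-subtracted trace), and lies ≥ 3 frames from
  a larger accepted peak. All four numbers are config-exposed
  (`DetectionParams`); the original FIJI criteria are unpublished.
* **Spillover**: a peak is discarded iff a neighboring square (8-connected)
  has a peak at the *same frame* with strictly greater amplitude;
  equal-amplitude ties keep the lower square index. By default comparisons
  run against the raw per-frame peak set, so a removed peak still suppresses
  its other neighbors (the rule is stated as a pairwise condition, not an
  iterative survivor rule); the survivor variant is available via
  `spillover_on_raw_peaks=False`.
* **Normalization**: `rate = n / (area/100) / minutes`, with cell area =
  mask pixel count × pixel size².

### Detection operating point

With the default flash/noise parameters, a mean-amplitude flash centered in
a square peaks at ≈ 10 trace-sigmas, but a flash on a square border splits
its Gaussian mass between squares and sits near 5 sigmas — the calling
threshold. Integrating the detection probability over uniform flash
positions and the lognormal amplitude distribution predicts recall ≈ 0.8;
the measured benchmark (20 seeded movies, greedy matching to ground truth
within the square-or-neighbor, ±2 frames gate) gives recall ≈ 0.80,
precision ≈ 0.97, pooled F1 ≈ 0.88. The residual false positives are
±1-frame duplicate calls in neighboring squares, which the same-frame
spillover rule deliberately does not remove. Border flashes are therefore
the known weak spot of the grid method at this SNR; because thinning is
amplitude-driven and identical across conditions, per-condition *rate
ratios* (the scientific readout) are unbiased by it.

## Threshold analysis

Per-cell rates at each treatment-free glucose level (the cell is the
statistical unit) enter a one-way **repeated-measures** ANOVA (cell as
block; a plain one-way variant is available — the sequential ramp design
records every cell at every level, which is a repeated-measures design).
Scheffé comparisons against the reference level (the highest tested, 11 mM)
then classify each level: significantly *above* the reference ⇒
stimulatory. The reported threshold is the bracketing pair (highest
stimulatory, lowest non-stimulatory level above it) — never an interpolated
concentration, since only tested levels carry evidence. `regulated` is the
omnibus ANOVA decision; by Scheffé coherence no level can be classified
stimulatory when the omnibus test is non-significant.

At the default rates (2 vs 1 events/100 µm²/min, ~217 µm² cell, 3-min
steps, n = 8 cells) the per-level Scheffé power is moderate (~0.5–0.7), so
the exact membership of the stimulatory set fluctuates across seeds; the
modal outcome across seeds is {3, 2, 1} mM with the threshold bracketed in
(3, 4). The fold change (mean rate over 1–3 mM ÷ mean over 4–11 mM)
recovers ≈ 2.0 per run.

## Statistics implementation

All tests are implemented from their sums-of-squares formulas (p-values via
`scipy.stats` distributions) and cross-checked in the test suite against
scipy, statsmodels and pingouin, plus explicit brute-force decompositions:

* pooled-variance Student's t (df = n₁+n₂−2; Welch variant by flag);
  zero-variance inputs degenerate to p = 1 (equal means) or p = 0, flagged;
* one-way fixed-effects ANOVA (any group with n < 2 is rejected);
* repeated-measures one-way ANOVA, SS_error = SS_total − SS_subjects −
  SS_conditions, df = (k−1)(n−1), with a numerical floor at zero for the
  tiny negative residuals the decomposition can produce in degenerate data;
* balanced two-way fixed-effects ANOVA with interaction (the balanced-only
  restriction is enforced by requiring a full a × b × r array; unbalanced
  tables are rejected with a message);
* Scheffé pairwise post-hoc: statistic
  (mᵢ−mⱼ)²/(MS_within(1/nᵢ+1/nⱼ)), critical value (k−1)·F_crit,
  p = upper F tail at statistic/(k−1). Pairwise contrasts only; general
  contrasts would be a straightforward extension of the same inequality.
  No multiplicity correction is applied beyond Scheffé itself.

## Problem sizes and numerical choices

* Simulated rasters are 64 × 64 px (cell: disc of radius 30 px ≈ 217 µm²),
  which keeps a full 8-cell, 21-minute ramp (14 000 frames/cell) to well
  under a minute per cell while exercising a 6 × 6 grid.
* Frame counts are `floor(duration/Δt + 1e-9)`: the epsilon guards against
  binary-float ratios (e.g. 180 s / 0.09 s) landing fractionally below the
  intended integer.
* Event-onset frames are `floor(t/Δt)` without epsilon (onset times are
  continuous random variables; boundaries have measure zero).
* Rendering sums per-event Gaussian patches (cutoff at 4σ, decay rendered
  to 10⁻⁴ of peak), so noise-free rendering is exactly linear in the event
  set; noise is added in fixed 512-frame blocks so the RNG stream does not
  depend on memory layout.
* Matching detections to truth is greedy one-to-one in (frame, square)
  order with a smallest-|Δframe| preference; the suite checks it against an
  exhaustive maximum bipartite matching (it is within the standard factor-2
  maximal-matching bound, and equal on realistic event densities).

## What the simulation does and does not show

The generator reproduces the statistical structure the analysis depends on:
Poisson event counts with glucose-dependent rates, single-frame rise /
exponential-decay flashes, PSF spillover between neighboring grid squares,
shot/read noise and slow bleaching. It does **not** model evanescent-field
optics, granule docking or transport, drug onset kinetics, cell-to-cell
rate heterogeneity beyond Poisson sampling, focus drift, or multi-cell
fields of view. Passing tests therefore validate the *pipeline* — calling,
normalization, statistics — under realistic noise, not the biology of any
particular recording; on real data the unmodelled artefacts (drift,
heterogeneous background) would be handled upstream.
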