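# Methods

This note documents the models implemented in `calmech`, the defaults and
their units, the synthetic-data generator's scope, and the numerical design
decisions taken where the underlying procedures are conventionally left
underspecified.

## Signal model for spontaneous Ca²⁺ activity

A recorded pixel inside a soma is modelled as

    I(t) = B · (1 + a · Σ_e k(t − t_e)) · β(t) + ε(t)

with baseline `B` (counts), relative transient amplitude `a` (δF/F
fraction), an instantaneous-rise / exponential-decay kernel
`k(Δ) = exp(−Δ/τ)` for `Δ ≥ 0`, event times `t_e` drawn from a homogeneous
Poisson process, a multiplicative photobleaching decay
`β(t) = exp(−λt)` (λ set so a stated fraction of intensity is lost over the
recording), and additive Gaussian camera noise `ε` (Poisson shot noise is
available as an option but Gaussian is the tested default). Background
pixels carry `B·β(t) + ε(t)`.

The kernel has no rise time because the analysis only fits the decay; soma
footprints are hard disks without a point-spread function, since detection
and quantification operate per pixel and blur would add nothing testable.
Event trains of an optional synchronized subgroup are shared verbatim.

Generator defaults follow the acquisition geometry and physiology of the
cultures the pipeline targets: 640×250 px (tests and the acceptance run use
a 96×96 px field with 5 cells to keep runtimes in seconds), 600 frames at
30 Hz (20 s), event rate 0.05–0.6 Hz (default 0.3 Hz), τ = 1.4–1.5 s,
δF/F ≈ 3–7% (default 6%), baseline 1000 counts, noise SD 2–10 counts,
bleach fraction 0.1–0.15. Camera noise statistics and indicator rise time
are package choices, not measured values.

## Detection

- **Dual threshold.** A pixel is selected when at least one peak of its
  trace rises above the pixel's time mean by more than `0.05 × mean` *and*
  more than `4 × SD_floor`, where `SD_floor` is the minimum temporal SD
  over all pixels (population normalisation) — a stack-wide noise floor.
  When the floor is zero (noiseless stacks) the second criterion is
  trivially satisfied.
- **Peaks.** Local maxima are located on a 3-frame moving-average-smoothed
  trace (edge-replicated); the height entering the criteria is measured at
  the raw sample, because full smoothing of a τ ≈ 1.4 s transient sampled
  at 30 Hz attenuates the apparent amplitude to ~66% of truth, which would
  make the 5% criterion unsatisfiable at realistic 6% amplitudes.
- **Bleach pre-correction.** Detection runs on a provisionally de-bleached
  copy of the stack (every frame rescaled by the global-frame simple
  ratio). Under 15% bleaching the monotone trend alone displaces traces by
  more than ±5% around their time mean, so raw-trace detection would both
  flood the early frames with false positives and suppress late events.
  The switch `precorrect_for_detection=False` restores raw-trace detection
  for unbleached data. The final trace correction below is always computed
  from the background outside the detected ROIs.
- **Merging.** Selected pixels are grouped by 8-connectivity; a group
  whose bounding box reaches 20 px in either dimension is split by greedy
  seeded growth (seed at the topmost-leftmost pixel, grow while the box
  stays < 20 px). An ROI trace is the per-frame mean over member pixels.
  Indexing is 0-based, (row, col), frame 0 at t = 0 s.

## Bleach correction and event metrics

- **Simple ratio.** `ratio(t) = b(0)/b(t)` with `b(t)` the spatial mean
  over non-ROI pixels; the reference frame is frame 0, so `ratio(0) = 1`.
  At least 1% of pixels must remain outside all ROIs.
- **Baseline F₀ (two passes).** A provisional baseline (10th percentile of
  the corrected trace) locates events; F₀ is then the time mean excluding
  ±3τ windows around each event. At 0.25–0.3 Hz with τ ≈ 1.4 s these
  windows cover nearly the whole 20 s trace, in which case the estimator
  falls back to the 10th percentile (quiet-period level; with transients
  occupying a minority of samples this tracks the true baseline to a
  fraction of a percent).
- **Event amplitude.** Default δF/F is the *rise step*: the raw peak value
  minus the median pre-onset level (raw samples ending two frames before
  the peak), divided by F₀, in percent. Measuring the peak against F₀
  directly (available as `amplitude_mode="above_f0"`) inherits the decay
  tail of any earlier transient — an expected inflation of order
  `rate × τ` (≈ +35% at 0.25 Hz, τ = 1.4 s) — and is therefore not the
  default. A qualifying peak must additionally rise above its pre-onset
  level by more than 5× a robust noise scale (1.4826·MAD of first
  differences /√2), which rejects noise ripples on decay tails that pass
  the height criterion without constituting a new transient; peaks closer
  than 0.1 s are collapsed to the tallest.
- **τ fitting.** `y(t) = A·exp(−t/τ) + C` fitted by non-linear least
  squares on each segment from a peak to the next event onset (or trace
  end), requiring ≥ 10 samples. The offset C is bounded within one segment
  amplitude of F₀. Fits are rejected (flagged, τ withheld) when the mean
  squared residual relative to the segment's peak value exceeds 5·10⁻⁴
  (the 0.05% quality bound), when τ ≤ 0, or when τ exceeds 10× the segment
  span (a decay longer than the observation window is unidentifiable — a
  straight ramp would otherwise "fit" with an absurd constant). A neuron's
  reported τ is the median over its accepted event fits.
- **Frequency** is event count over recording duration; it uses the same
  corrected-trace events as the amplitude (whether the original analysis
  counted raw-trace peaks is unknowable; corrected is implemented).
- **Synchrony.** Two neurons are synchronized when ≥ 50% of the
  smaller train's events have a partner in the other within ±0.1 s
  (3 frames at 30 Hz); ≥3-neuron synchrony requires a clique of pairwise
  synchronized neurons. Window and coincidence fraction are configuration
  parameters; the criterion is a quantitative stand-in for what is usually
  judged by eye, so only its bookkeeping (case fractions across
  recordings) is comparable across studies.

## Nanoindentation and rheology

- **Sensitivity calibration.** On a rigid substrate the deflection signal
  is linear in piezo displacement once in contact; the detection
  sensitivity (m/V) is the inverse slope of a least-squares line through
  the upper 50% of the deflection range. Values outside 1–100 nm/V log a
  warning (typical colloidal-probe values are 10–20 nm/V).
- **Contact point.** First sample exceeding the pre-contact baseline mean
  by 3 baseline SDs (baseline = first 20% of the record), optionally
  refined by a Hertz fit with the contact offset free.
- **Hertz fit.** `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` with ν = 0.5 unless
  configured; indentation `δ = z − F/k` when the abscissa is piezo
  displacement. For a fixed contact point the problem is linear in E and
  solved in closed form; with a free contact offset it is a two-parameter
  non-linear fit. The reported E keeps the `(1−ν²)` factor inside the fit
  (instrument convention), i.e. it is the sample's Young modulus. At least
  20 in-contact points are required; non-positive fits are errors. No
  viscoelastic correction is applied; the loading rate is metadata.
- **Aggregation** is strictly hierarchical: per-curve E → location mean →
  sample mean → group mean ± SD across samples (SD flagged undefined for a
  single sample).
- **Rheology.** G′ at a target frequency (default 10 Hz) is obtained by
  linear interpolation in log-frequency; conversion to the compressive
  modulus uses `E = 2G′(1+ν)`, exactly linear in G′, with ν = 0.5 for
  incompressible hydrogels.

## Statistics

Group summaries report n, mean, SD (n−1), SEM, median and quartiles
(linear interpolation) — both SD and SEM are emitted and labelled, since
reporting conventions for these metrics vary. Normality is checked with
the D'Agostino–Pearson K² omnibus test (requires n ≥ 20); group differences
use the two-sided pooled-variance Student t-test (Welch by flag), with
stars at p < 0.05 / 0.01 / 0.001. No multiple-testing correction is
applied. Degenerate zero-variance comparisons return p = 1 when means are
equal.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the pipeline's rules
assume: Poisson event trains, single-exponential decays sharing one τ,
spatially uniform multiplicative bleaching, stationary Gaussian noise,
disk-shaped non-overlapping somata. Passing recovery tests therefore
demonstrates the pipeline's correctness under its own model assumptions —
not robustness to motion, focus drift, overlapping cells, indicator
saturation, shot-noise statistics, astrocytic transients or
non-exponential decays, none of which are simulated. Problem sizes in the
tests (96×96 px fields, 5 cells, 50 seeds; 100-seed Monte-Carlo fits) were
chosen to give stable medians in seconds of runtime.

## Known limitations

- The ROI splitter is greedy and deterministic, not optimal; pathological
  pixel sets may split differently than an exhaustive partition would.
- F₀'s percentile fallback biases slightly low in pure noise (≈ −1.3 noise
  SD at the 10th percentile), negligible at the tested SNRs.
- The synchrony criterion has no jitter model beyond the fixed window; it
  is not a substitute for spike-train inference.
- The Hertz fit assumes a linear-elastic half-space; thin samples or
  adhesion violate it and are not flagged automatically.
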