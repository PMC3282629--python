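# Methods

## Scope and data model

The package analyses dynamic planar renography reduced to ROI time-activity
curves: count rates (counts/s) at the midpoints of uniform frames (default
120 frames × 5 s). All intervals are half-open `[start, end)` in 0-based
frames; times are in seconds everywhere, with a single conversion to
minutes (×100 ×60) when FUR is reported in %ID/min. Curves can come from a
2-D frame stack (multi-frame TIFF + JSON timing/mask sidecar) via
`extract_tac`, or directly from the CSV curve dialect.

## Synthetic study generator

The generator (`simdata`) is the package's stand-in for animal studies; it
emulates the acquisition conditions of a mouse MAG3 study and provides
closed-form truth labels.

Forward model:

- Plasma input (cardiac ROI): `P(t) = A1·e^(−αt) + A2·e^(−βt)`.
- Kidney parenchyma: `R_k(t) = F_k ∫₀ᵗ P(τ) h_k(t−τ) dτ` with a
  plateau-then-exponential retention `h_k(u) = 1` for `u < T_min,k`, then
  `e^(−w_k(u−T_min,k))`. This is the minimal linear model for which the FUR
  definition is exact during uptake: before the minimum transit time the
  kidney is a pure integrator of plasma, the Patlak-Rutland plot is a line
  through the origin with slope `F_k`, and the IRF is a plateau of height
  `F_k` ending at `T_min,k`.
- Kidney ROIs additionally contain tissue background
  `background_fraction·P(t)`; congruent background ROIs see the background
  alone. The whole body is a conserved plateau at `ID`; an injection-site
  residual (`injection_residual_fraction·ID`) is released into circulation
  at `residual_release_rate`; excreted activity accumulates in the bladder.
- Truth labels: `FUR_k = P(0)·F_k/ID · 6000` %ID/min with `P(0) = A1+A2`,
  `DRF_k = F_k/(F_L+F_R)·100`. Labels never depend on the noise setting.

Defaults (the study conditions used throughout the tests):

| parameter | default | rationale |
|---|---|---|
| frame grid | 120 × 5 s | standard small-animal dynamic protocol |
| A1, A2 | 280, 70 counts/s | heart-ROI scale; slow tail ≈ 20% of P(0) |
| α, β | 0.012, 0.005 1/s | fast renal clearance (t½ ≈ 1 min) plus slow pool; near-mono-exponential over the uptake window, as the P(0) back-extrapolation assumes |
| F_L, F_R | 0.0140, 0.0176 1/s | gives total FUR 33.2 %ID/min split 44.3:55.7 — a typical healthy murine baseline with the right kidney dominant |
| T_min | 140, 160 s | renogram peaks near 3 min |
| washout | 0.012 1/s | downslope half-time ≈ 1 min |
| ID | 2000 counts/s | ≈ 37 MBq at typical planar sensitivity; peak kidney ≈ 2×10³ counts/frame, so Poisson mode reproduces realistic counting noise |
| background fraction | 0.10 | plausible placeholder; not derived from data |
| injection residual | 0.05, released at 0.05 1/s | plausible placeholder; the first-minute ID estimator then sees ≈ 98% of the plateau |

Poisson noise is applied to per-frame counts and converted back to rates;
under a fixed seed output is bit-reproducible. No radioactive decay is
applied by default (⁹⁹ᵐTc decays ≈ 1.9% over 10 min); a
`physical_decay_rate` switch can enable it (this deliberately breaks
whole-body conservation).

Numerics: the kidney convolution is evaluated by trapezoid quadrature on an
internal grid refined 10× relative to the frame grid and sampled at frame
midpoints; it matches an independent Δt = 0.01 s quadrature to well under
0.5% at every frame.

What the generator does *not* emulate: bolus arrival delay and dispersion
in the cardiac curve, extravascular contamination of the heart ROI, scatter
and septal penetration, dead time, motion, depth-dependent attenuation
(available only as the standalone sensitivity tool), or anatomically
realistic organ shapes in the rendered 2-D mode (uniform elliptical masks
on a 128×128 grid). Passing tests therefore demonstrate correctness of the
estimation chain under ideal tracer kinetics with Poisson statistics, not
robustness to every artefact of real camera data.

## Analysis pipeline

Correction order is fixed: background-correct, then normalise. Background
is scaled by the ROI pixel-area ratio; negative corrected rates are clipped
to zero and counted in a QC flag (Poisson noise makes occasional negatives
routine). %ID uses the scalar first-minute ID by default; frame-by-frame
division by the residual-corrected whole-body curve is available behind
`percent_id_per_frame` since the two readings of the normalisation are both
defensible.

**Patlak-Rutland plot.** `y = R/P` against `x = ∫₀ᵗP/P`. The cumulative
integral is trapezoid between midpoints plus a leading rectangle `t₀·P₀`
for the unobserved first half-frame. Frames with `P` below 1% of its
maximum are masked to avoid division blow-up.

**Deconvolution.** `R_i = Δt·Σ_j P_{i−j} H_j` is solved for `H ≥ 0`
non-increasing with a second-difference penalty. `H_k` estimates retention
at lag `k·Δt`; the lag-zero column carries half weight because only half of
the first frame's input can act by that frame's own midpoint (this removes
a one-frame bias in the recovered plateau edge). Monotonicity is enforced
exactly by writing `H` as a reversed cumulative sum of non-negative
increments and solving the stacked system with NNLS. The penalty weight
(`smoothing`, default 10⁻³ relative to the Frobenius norms of the two
blocks) is small enough not to distort noise-free solutions and only
regularises the noise-dominated tail.

**Plateau and LU segment.** The plateau is the longest stretch before the
renogram peak over which `H` falls by less than `plateau_band` (default
10%) relative to the stretch's own start; ties go to the earliest stretch.
Because `H` is monotone, defining the band against the stretch start rather
than a global running maximum makes detection immune to an isolated
lag-zero spike (vascular component or noise). The LU segment is the
plateau's frames with the first two frames after bolus arrival (plasma
exceeding 10% of max) trimmed; plateaus shorter than 4 frames raise an
error asking for a manual interval, and manual intervals are honoured and
flagged. The intercept prior for the LU fit is `(H[0] − plateau)·Δt`,
clipped at zero — the excess of the IRF at lag zero over its plateau, which
is the deconvolution's estimate of the vascular (blood-volume) fraction of
the ROI, i.e. exactly the PR-plot intercept of an integrator-plus-blood
model. The prior enters the weighted least-squares line as one ordinary
observation at `x = 0` (weight configurable).

**P(0) and FUR.** The mono-exponential plasma fit runs over the convex hull
of the two LU segments (when the segments are disjoint the hull is still
used), with a log-linear fit as the initial guess; non-convergence raises
an error carrying the log-linear fallback. `FUR = P(0)(k_l+k_r)/ID·6000`;
negative slopes are flagged, not rejected. FUR and DRF are invariant under
a global rescaling of all curves.

**DRF.** Over the hull of the two LU segments: (a) trapezoid integrals of
the corrected renograms, (b) PR slopes refitted over the common interval,
(c) medians of the IRFs over the interval. The consensus (used for split
FUR) is the PR-slope pair; a method deviating from consensus by more than
5 percentage points raises a QC flag.

**Attenuation sensitivity.** The deeper kidney's counts are scaled by
`e^(−μ·d)` and the pair renormalised; the inverse is
`d = ln(ratio_obs/ratio_true)/μ`. With μ = 0.12 cm⁻¹, 1 cm turns 50:50 into
53:47, and an observed 55.7:44.3 would need d ≈ 1.91 cm — implausible in a
mouse, justifying the pipeline's lack of depth correction.

## Cohort statistics

Mean ± SEM per timepoint, two-sided paired t-tests (left vs right at each
timepoint; each kidney vs its baseline), significance at 0.05/0.01, no
multiple-testing correction (recorded in table metadata). Percent of
baseline is computed under both definitions — ratio of group means (table
default) and mean of per-animal ratios — because they differ whenever
animals vary; both are labelled in the output. The repeat-agreement report
(Pearson r, mean ± SD of differences, paired t) quantifies reanalysis
reproducibility; in tests it is exercised by re-extracting curves with
1-pixel-dilated kidney ROIs. The cohort simulator plants multiplicative
effects on the uptake constants (defaults: day 8 ×0.79 left / ×0.56 right,
day 14 ×0.86 / ×0.69, mirroring an ischemic right kidney with partial
recovery) on top of 10% lognormal inter-animal variability, with n = 8
animals by default; group sizes are an assumption, not data.

## Problem sizes used in validation

Validation uses desk-scale simulation: an 18-point noise-free parameter
grid (uptake ratios 1:1/1:2/2:1 × transit times 100/150/200 s × mono- and
bi-exponential plasma) for deterministic recovery (total FUR within 3%,
DRF within 1 point); 50 Poisson seeds at ~2×10³ peak kidney counts/frame
for stochastic robustness (median |FUR error| < 10%, unbiased relative to
the noise-free estimate within Monte-Carlo error, three-method DRF
agreement in ≥ 90% of runs); and 3 cohort replicates of 8 animals for the
planted-effect recovery. Published cohort statistics (e.g. a 56.6 ± 7.0%
day-8 value or r = 0.99 on repeated real analyses) depend on unavailable
raw animal data and are covered instead by these property checks and by
the internal consistency of the published-style tables.

## Known limitations

- The deconvolution contract (non-negativity, monotone non-increase, light
  smoothing) is one reasonable constrained-least-squares formulation; other
  formulations could yield slightly different plateau estimates.
- The mono-exponential back-extrapolation systematically underestimates
  P(0) when the plasma curve is strongly bi-exponential within the fit
  window (≈ 1.6% at the default parameters); this is a property of the
  method, not of the implementation.
- With unequal transit times the common uptake interval extends past the
  shorter `T_min`, biasing that kidney's DRF slightly downward (≈ 0.5
  points at the defaults).
- The first-minute ID estimator sees the whole-body plateau minus the mean
  residual over the window, so a slowly-released residual leaves a small
  (< 2% at defaults) systematic offset against the nominal dose.
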