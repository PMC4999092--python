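# Methods

## Scope and model family

`petkin` quantifies dynamic brain PET data acquired with continuous
arterial blood sampling. The tissue signal is modeled with linear
compartment systems driven by the metabolite-corrected plasma input
Cp(t):

- **1C1i** (one tissue compartment): dC₁/dt = K₁Cp − k₂C₁. Appropriate for
  reversibly transported tracers (FET; FCho after metabolite correction).
- **2C1i** (two tissue compartments): dC₁/dt = K₁Cp − (k₂+k₃)C₁ + k₄C₂,
  dC₂/dt = k₃C₁ − k₄C₂. For FDG the trapping step (phosphorylation by
  hexokinase) is treated as irreversible over a 60-min scan, k₄ = 0.
- **3C2i** (dual input): for a tracer whose labelled metabolite circulates
  in plasma and enters tissue itself. The parent input drives an
  irreversible two-tissue branch (K₁, k₂, k₃); the metabolite input Cm
  drives an independent reversible compartment (K₁m, k₂m). The topology is
  a modeling choice — the three compartments and two inputs constrain but
  do not uniquely determine the wiring — and alternative wirings can be
  tested by composing the same primitives.

The measured TAC is (1 − v_B)·ΣC_tissue + v_B·C_wb. No blood-volume term
is assumed by default (v_B = 0); fitting v_B (bounded [0, 0.2]) is
available because clinical packages commonly include it.

Macro-parameters use the standard closed forms Ki = K₁k₃/(k₂+k₃),
Kp = k₃/(k₂+k₃), V_d = K₁/k₂, and the glucose metabolic rate
MR = Ki·C_glu/LC (defaults C_glu = 3.44 mmol/l, LC = 0.89). Macro values
are computed per lesion from that lesion's micro-parameters; group means
of ratios are means of per-lesion ratios, not ratios of group means.

## Forward simulation

Every impulse response above is a sum of exponentials, so tissue curves
are computed by *exact* convolution of e^(−λt) kernels with the
piecewise-linear input on its regular (nominally 1 Hz) grid. The
per-segment update is a constant-coefficient linear recurrence evaluated
in C (`scipy.signal.lfilter`); small λ·Δt uses a series expansion and λ = 0
reduces to the cumulative trapezoid. Against adaptive ODE integration
(rtol 1e-10) the simulator agrees to ~1e-8 relative error; there is no ODE
solver in the production path. Model TACs are read at frame midpoints by
default (`sampling="average"` integrates over each frame instead); the
frame midpoint is also the reference time for decay correction and
graphical transforms.

## Input-function corrections

The default pipeline order is calibrate → decay → delay → dispersion →
plasma-ratio → parent-fraction; each step is an independent function, so
other orders are composable where a study requires them.

- **Calibration**: scalar factor (counter rate → kBq/ml).
- **Decay**: multiply by e^(+λ(t−t₀)), λ = ln2/109.77 min (F-18).
- **Delay**: the external detector sees blood ~10 s after it leaves the
  artery, so the measured curve is advanced by the configured delay
  (g'(t) = g(t+δ), linear interpolation, edge hold). A negative δ delays
  instead; the sign is an explicit argument because conventions differ.
- **Dispersion**: first-order deconvolution Ca = g + τ·dg/dt with central
  differences (one-sided at the ends) and optional Savitzky-Golay
  pre-smoothing (quadratic, ~5 s window) for noisy detector data. τ is a
  configured catheter constant (default 4.63 s for a 10-cm line at
  200 µl/min withdrawal); the geometry fields are stored as metadata and
  never used to re-derive τ.
- **Plasma-to-blood ratio**: piecewise-linear in time with constant
  extrapolation. Packaged endpoint trajectories: FDG 1.59 → 1.04 over
  60 min, FET 1.10 → 1.30 over 55 min, FCho 0.97 → 1.03 over 20 min. Only
  the endpoints are constrained by measurement; the linear interior is a
  choice.
- **Parent fraction**: f(t) = a₁e^(−b₁t) + a₂e^(−b₂t) + a₃ with aⱼ ≥ 0,
  Σaⱼ = 1 (hence f(0) = 1, 0 ≤ f ≤ 1). FDG and FET are treated as
  metabolically stable (f ≡ 1). For FCho the packaged default passes
  through the measured anchors f(0) = 1 and f(15 min) = 0.172; the
  intermediate anchors (1, 5, 20 min) used to pin the fit are
  interpolation choices, not measurements. The labelled metabolite (FBet)
  fraction rises as m(t) = m∞(1 − e^(−κt)) with m∞ = 0.35 and κ solved so
  m(15 min) = 0.293 exactly; m∞ itself is unmeasured. Phospho-FCho stays
  ≤ 2.8% of plasma activity and is not modeled as an input.
- **Plasma tails** can be smoothed by a 1-3 term exponential sum fitted by
  variable projection (nonlinear search over log-rates, amplitudes solved
  linearly), which keeps the notoriously ill-conditioned multi-exponential
  problem stable.

## Fitting

Weighted nonlinear least squares with a bounded trust-region optimizer
(`least_squares`, bounds [0, 5] on rate constants, [0, 0.2] on v_B).
Default weights are the frame durations, matching the count-statistics
noise model; uniform weights are available. Ten seeded multi-starts (the
default initial vector K₁ = 0.1, k₂ = 0.1, k₃ = 0.05, k₄ = 0.01 plus
log-normal perturbations, σ = 0.5) guard against local minima; a relative
SSR tie-break keeps the default-start solution on flat ridges, so results
are deterministic given the seed. Percent standard errors come from the
scaled inverse Gauss-Newton normal matrix, SE% = 100·√(diag((JᵀJ)⁻¹·SSR/(N−p)))/|θ|.
Degenerate inputs (all-zero TACs, residuals at numerical noise level) are
flagged: SEs are reported as undefined rather than as misleading numbers.

Model comparison uses the least-squares information criteria
AIC = N·ln(SSR/N) + 2p, SC (BIC) = N·ln(SSR/N) + p·ln N, and the
Scientist/MicroMath model selection criterion
MSC = ln(Σw(y−ȳ)²/Σw(y−ŷ)²) − 2p/N, all on weighted residuals. The
preferred model has the lowest AIC, lowest SC and highest MSC; the
consensus is the majority of the three, and ties are reported rather than
broken silently. Absolute criterion values depend on constant conventions
that differ between software packages; only differences and rankings are
meaningful here. A perfect fit (SSR = 0) yields sentinel values with a
flag.

## Graphical analysis

Patlak: OLS of CT/Cp against (∫₀ᵗCp)/Cp for frame midpoints ≥ t*; the
slope is Ki, the intercept the initial distribution volume. Logan: OLS of
(∫₀ᵗCT)/CT against (∫₀ᵗCp)/CT; the slope is V_t (K₁/k₂ for 1C1i,
K₁/k₂·(1+k₃/k₄) for reversible 2C1i). ∫Cp is a cumulative trapezoid on
the input's own fine grid. ∫CT treats frame values as frame averages:
each full frame contributes value·Δt and the current frame half of that
up to its midpoint. (A trapezoid drawn *across* midpoints was tried and
rejected: it smears the bolus over the short early frames and biases the
Logan slope of even the exact-equilibrium identity case by several
percent.)

t* defaults are 20 min (Patlak/FDG) and 10 min (Logan/FET/FCho), justified
by the equilibration times 1/(k₂+k₃) ≈ 4 min (FDG) and 1/k₂ ≈ 20 min (FET)
of the fitted constants — by 20 min the FDG Patlak transient e^(−(k₂+k₃)t)
is below 1%. `select_tstar` automates the choice: the earliest frame such
that all later transformed points deviate from the tail regression by less
than 10% (configurable), with deviations measured pointwise relative to
the regression value (floored at 10% of its maximum so near-zero
predictions cannot dominate). The same measure drives the `nonlinear`
flag on every graphical fit. Tightening the tolerance can only move t*
later; the selected t* is otherwise a property of the transient's
*amplitude* as well as its rate, so it should be reviewed, not trusted
blindly, for slowly equilibrating tracers.

Parametric maps apply the linear methods voxel-wise (vectorized OLS; no
voxel-wise NLLS), set failing voxels (zero denominators) to NaN and count
them. Gaussian smoothing uses a separable kernel with σ = FWHM/2.355 per
axis in mm, reflect border handling, and normalized convolution over the
valid (non-NaN) voxels; away from borders and NaNs the map mean is
preserved to well under 0.1%.

## Synthetic data

The generator emulates the study conditions of a rat GB/RN discrimination
experiment; it is the package's test bed, not a scanner model.

- **AIF**: linear rise to a single peak at 30 s followed by a
  tri-exponential washout (fractions 0.70/0.25/0.05 of the peak, rates
  4.0/0.5/0.01 min⁻¹), peak 250 kBq/ml at the reference 37 MBq dose,
  scaling linearly with dose. The shape is internally consistent
  (non-negative, single maximum, area ∝ dose) but is a stand-in: no
  measured AIF shape is reproduced.
- **Noise**: per-frame Gaussian with σᵢ² = α·C(tᵢ)·e^(λ_decay·tᵢ)/Δtᵢ —
  the standard decay-corrected count-statistics rule. α = 7.0 kBq·s/ml by
  default, set so the TAC coefficient of variation is ≈5% at
  mid-acquisition for the FDG settings (measured 4.1% at 30 min).
- **Cohorts**: per-animal micro-parameters drawn from zero-truncated
  normals with the published group means/SDs (FDG 2C1i: GB k₂ 0.19±0.04,
  k₃ 0.07±0.03; RN k₂ 0.28±0.03, k₃ 0.04±0.01; FET 1C1i: GB K₁ 0.06±0.01,
  RN K₁ 0.02±0.01, k₂ 0.05±0.01; FCho 1C1i: K₁ 0.11±0.03 / 0.10±0.02,
  k₂ 0.05±0.02 / 0.07±0.01). Where a SD is not published (FDG/FCho K₁)
  the generator uses 20% of the mean, a typical between-animal spread.
  All generators are pure functions of (parameters, seed).
- **Phantoms**: disjoint labelled regions sharing one TAC per region feed
  the parametric-map tests.

What passing tests on this generator do *not* show: robustness to scanner
resolution and partial-volume effects, reconstruction artifacts,
attenuation, motion, real AIF shapes, or model mis-specification beyond
the topologies simulated. The noise model is Gaussian and independent
across frames; real reconstructed data are neither.

A consequence worth stating explicitly: with the published between-animal
spreads, the FDG k₃ group distributions overlap substantially
(P(GB > RN) ≈ 0.83 for a random pair). At n = 6 vs 5 the exact
Mann-Whitney test then has ≈30-40% power at α = 0.05 — a single cohort can
easily reach p ≈ 0.02, but most random cohorts of this size do not reach
significance. The package's power study reports this honestly rather than
inflating the effect size. The rank correlation between the fitted
compartmental Ki and the Patlak slope within a cohort is ≥ 0.9 in every
replicate, since both estimate the same influx rate from the same data.

## Statistics

Mann-Whitney U uses the full enumeration of group assignments (ties
handled by mid-ranks) whenever n+m ≤ 20, i.e. always at these cohort
sizes, and the tie-corrected normal approximation with continuity
correction beyond. Spearman's ρ is the Pearson correlation of mid-ranks
with the exact permutation two-sided p for n ≤ 9 and the t approximation
otherwise; constant inputs are flagged as undefined rather than raised.
Tests are two-sided throughout and no multiple-testing correction is
applied, matching common practice in small exploratory animal studies.

## Problem sizes and determinism

Default test-suite problem sizes: 1 Hz input grids over 20-120 min
acquisitions, 100-point random parameter sweeps for the simulator oracle,
1000-replicate Monte-Carlo checks of the noise rule, 200-replicate power
studies with 3 optimizer starts per fit (noiseless recovery and all
worked examples use the full 10-start default). Every stochastic step
takes an explicit seed; reruns are bit-identical.

## Known limitations

- The dual-input topology is one defensible wiring among several; k₄ > 0
  in the parent branch of 3C2i is not supported (fix k₄ or use 2C1i).
- Total tissue activity under k₄ = 0 is guaranteed non-decreasing only
  for non-decreasing free-compartment content (e.g. constant input); after
  a bolus the free compartment washes out faster than the trapped one
  accumulates, so brief decreases are physical, not numerical error. The
  trapped compartment itself never decreases.
- AIC/SC/MSC absolute values are not comparable across software packages.
- Voxel-wise fitting is linear-methods-only by design; no partial-volume
  or resolution modeling anywhere.
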