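# Methods

`petkin` implements full arterial-input quantification of dynamic brain
PET data for a fast-clearing, reversibly binding tracer: input-function
construction from blood sampling, compartmental model fitting with a
two-stage fixed-k4 scheme, AIC model selection, %SE-based reliability
filtering, macro-parameter endpoints (VT, BPND), group comparison, and a
scan-duration truncation analysis. This note records the model, the
numerical choices, the synthetic-data design, and the limits of what the
synthetic validation shows.

## Compartment models

Tissue concentration is modelled with plasma-input compartment models.
For the reversible two-tissue model (2T4k) the free and non-specifically
bound tracer C1 and the specifically bound tracer C2 obey

    dC1/dt = K1 Cp(t) − (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 − k4 C2

with Cp the metabolite-corrected plasma parent concentration, K1
(mL·cm⁻³·min⁻¹) the delivery rate, k2 the efflux rate, k3/k4 the
association/dissociation rates of specific binding (all rates min⁻¹).
Setting k4 = 0 gives the irreversible model (2T3k); collapsing the second
compartment gives the single-tissue model (1T2k). The measured signal
adds a fractional blood-volume term:

    C_T(t) = (1 − VB)(C1 + C2)(t) + VB C_wb(t).

The impulse response of each model is a sum of exponentials in closed
form; for 2T4k the decay rates are the negated eigenvalues of the 2×2
rate matrix,

    α₁,₂ = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4 k2 k4)] / 2,

with amplitudes K1(k3+k4−α1)/(α2−α1) and K1(α2−k3−k4)/(α2−α1). At a
repeated root the response degenerates to K1 e^{−αt}[1 + (k3+k4−α)t];
this limit form is implemented explicitly because the boundary k3 → 0,
k2 ≈ k4 is reachable during optimisation. The amplitudes always sum to
K1 at t = 0 (a tested invariant).

Macro parameters: VND = K1/k2, BPND = k3/k4, VT = VND(1+BPND); the
irreversible model has no VT and reports the net influx rate
Ki = K1·k3/(k2+k3) instead.

## Numerics of the forward model

Convolution of the impulse response with the input curves is computed on
a uniform 0.5 s grid (fine enough to resolve the 15 s first frame), with
the input treated as piecewise linear between samples. Each exponential
term uses the exact one-step recursion y_{i+1} = e^{−θΔ} y_i + b_i with
the per-step integral of the linearly interpolated input in closed form
(series expansion below θΔ = 10⁻⁵ for stability; the θ = 0 constant term
of the irreversible model reduces to a running integral). This makes the
forward model exact for piecewise-linear inputs up to rounding, which the
test suite confirms by agreement with stiff ODE integration to well below
the 0.1% acceptance band (errors measured relative to the curve maximum,
since both solutions pass through zero before tracer arrival). Frame
averages are trapezoidal means over [start, start+duration) — exact for
the interpolant — with time stored in seconds at the schedule boundary
and minutes everywhere else.

## Input-function construction

The arterial side combines a continuous online whole-blood record with
manual samples drawn at 5, 10, 20, 40, 60, 75 and 90 min:

* **Merging.** The continuous record is rescaled by one multiplicative
  calibration factor — the geometric mean of manual/continuous ratios at
  the draw times — and the manual samples are inserted so interruption
  gaps are bridged by interpolation. A single factor (rather than a
  time-varying one) reflects detector cross-calibration being a gain
  error.
* **Plasma/whole-blood ratio.** Linear in time, R(t) = r0 + r1·t,
  clipped at zero: two parameters are all seven samples support.
* **Parent fraction.** A Hill function f(t) = 1 − (1−a)t^b/(t^b+c^b),
  the common choice for PET metabolite curves; it guarantees f(0) = 1,
  monotone decline, and range [0, 1]. Fitted by bounded least squares
  from three half-time starting points (the profile is shallow in c).
* **Assembly.** Cp(t) = C_wb(t)·R(t)·f(t), then both curves are shifted
  by the delay so they live on the tissue clock.
* **Delay.** Grid search over ±30 s at 0.5 s steps minimising the RSS of
  a single-tissue-plus-blood-volume fit to the frames starting within the
  first 2 min. Within that window metabolism is negligible and R(t) is
  near-constant (absorbed by K1), so the whole-blood curve itself drives
  the search. Dispersion of the online detector is not corrected.

## Fitting, uncertainty and model selection

Fits minimise Σ wᵢ(yᵢ − ŷᵢ)² with a bounded trust-region least-squares
solver. Default weights are frame duration × decay factor (carbon-11
half-life 20.385 min), normalised to mean one so AIC comparisons are
invariant under rescaling; uniform weights are available. Bounds are
generous envelopes around published whole-brain values: K1 ∈ [0, 1],
k2 ∈ [10⁻³, 5], k3 ∈ [0, 1], k4 ∈ [10⁻⁴, 1], VB ∈ [0, 0.3]. Because the
small specific compartment creates local minima, every fit restarts from
10 points of a scrambled Halton sequence over the bounds (seeded) and
keeps the best optimum.

Standard errors use the Gauss–Newton covariance at the optimum,
cov = RSS_w/(n−p)·(JᵀWJ)⁻¹, reported as %SE = 100·SE/|estimate|.
Directions of the information matrix below 10⁻¹² of its largest singular
value are treated as unidentifiable and yield infinite %SE. Model
comparison uses classic AIC on the weighted RSS, n·ln(RSS_w/n) + 2p,
with ties broken toward fewer free parameters; no small-sample
correction is applied. %SE is not propagated to the macro parameters —
the reliability filter operates on the micro parameters (25% cutoff for
K1, k2, VB; 50% for k3, k4; strictly-greater-than excludes, so a value
exactly at the cutoff is retained).

The two-stage procedure first fits the free five-parameter model to the
whole-brain grey- and white-matter TACs; if either whole-brain k4 %SE
exceeds 50% the run aborts with a diagnostic. Every ROI is then refit
with k4 fixed to its tissue class's whole-brain value. Lesion ROIs
inherit the white-matter k4, since lesions are carved out of the
white-matter compartment. The justification is physiological: k4 is the
receptor off-rate and should not vary regionally, while the small
specific compartment makes free regional k4 estimates noise-prone.

A "k3-only" filter mode (exclude only on k3 %SE > 50%) is provided
alongside the full per-parameter mode because both rules appear in
published practice; the package surfaces both rather than adjudicating.

## Cohort statistics

Group comparison uses the pooled-variance Student t-test (the common
default reading of an "independent t test"; Welch is available via
configuration). P-values are reported uncorrected, with the
Bonferroni-adjusted threshold printed alongside. Lesion contrasts
(BPND, VT, K1/k2 in non-lesional white matter vs T2 vs enhancing
lesions) are descriptive only — with a handful of analysable subjects a
test would be theatre. The truncation analysis drops whole frames whose
start is at or beyond the cut (default 60 min), re-runs the complete
two-stage pipeline, and compares macro endpoints by regression of
truncated on full values plus Bland–Altman bias and 1.96·SD limits of
agreement (sample SD).

## Synthetic data

No subject data accompany the study conditions this package targets, so
validation rests on a generator that emulates their structure:

* **Schedule:** 22 frames (1×15, 3×5, 3×10, 4×60, 2×150, 2×300, 7×600 s),
  90 min total.
* **Input function:** a Feng-type bolus for total plasma,
  Cp(t) = (A1(t−τ) − A2 − A3)e^{−λ1(t−τ)} + A2e^{−λ2(t−τ)} + A3e^{−λ3(t−τ)},
  with defaults A1 = 850 kBq·mL⁻¹·min⁻¹, A2 = 21, A3 = 20 kBq·mL⁻¹,
  λ = 4.1/0.12/0.01 min⁻¹, τ = 0.5 min — a conventional bolus shape
  scaled to a ~360 MBq injection (the measured curves behind the study
  are unpublished; these are declared synthetic defaults). Parent
  fraction defaults a = 0.25, b = 1.5, c = 20 min (≈32% parent at
  90 min); plasma/whole-blood ratio 1.25 + 0.002·t. The whole-blood
  record is sampled at 1 s with 2% multiplicative Gaussian noise and
  ±15 s gaps around each manual draw; manual activities carry 2% noise
  and parent fractions 0.01 additive noise.
* **Population:** per-group (patients vs controls) × tissue-class
  (GM/WM) means and SDs for K1, k2, k3, k4, VB taken from the published
  whole-brain estimates; per-ROI parameters are truncated-normal draws
  on [10⁻⁴, upper bound]. k4 is drawn once per tissue class per subject
  and shared across that class's ROIs — the data-generating counterpart
  of the fixed-k4 assumption. Whole-brain TACs use the class means with
  the subject's class k4. No between-parameter correlation is imposed
  beyond the shared k4 (no covariance information is available).
* **Lesions:** patient subjects carry a T2-lesion ROI (k3 × 0.7) and an
  enhancing-lesion ROI (k3 × 0.5, K1 × 1.5), reproducing the qualitative
  pattern of reduced specific binding with blood-brain-barrier leakage;
  the multipliers are design choices, not calibrated to unpublished
  per-lesion values.
* **TAC noise:** frame SD = σ0·√(C(t_mid)/(Δt·DF(t_mid))) with
  DF = 2^(−t_mid/20.385 min), the count-statistics scaling under which
  late frames are noisy despite their length because the tracer has
  decayed. σ0 = 0.05 kBq^½·mL^-½·min^½ puts mid-scan relative noise at a
  few percent — ROI-level noise typical of large regions — and leaves
  whole-brain k3 %SE in the "low except for a few ROIs" regime (median
  well under 50%, checked by test).

Everything is deterministic given a seed (`numpy` Generator seeding;
identical across platforms).

**What the synthetic validation does not show.** The generator draws data
from the same model family the fits assume; passing round trips therefore
demonstrate correctness of the estimation machinery, not robustness to
model misspecification. Real data add arterial dispersion,
partial-volume and motion effects, non-Gaussian reconstruction noise,
and between-parameter correlations — none of which are simulated. In
particular the truncation analysis on synthetic data shows near-unity
agreement without the systematic underestimation that real 60-min data
exhibit, because nothing in the generator violates the 2T4k model at
late times.

## Problem sizes

Default validation sizes were chosen to keep full runs on a laptop-class
single core comfortable: 200 random parameter sets for the
analytic-vs-ODE check, 100 noisy replicates for model selection, and a
10-subject cohort (six grey-matter ROIs, one white-matter ROI, two
whole-brain ROIs, two lesion ROIs in patients) for the cohort-level
analyses. Scaling any of these up is a constructor argument.

## Known limitations

* The optimiser, weights, bounds and start values used in the original
  analysis of this tracer are unreported; the choices above are this
  package's own and are documented as such.
* Units of the published rate constants are not stated in the source
  table; min⁻¹ is assumed throughout.
* No dispersion correction of the online blood detector, no
  reference-tissue or graphical (Logan) methods, no voxelwise fitting —
  all out of scope by design.
* The Hill parent-fraction and linear plasma-ratio forms are substitutes
  for unspecified originals; both are swappable at the module surface.
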