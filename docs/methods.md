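# Methods

## Hydrostatic correction

In the supine patient the pressure system is equalized with the wire sensor
at the catheter tip. Once the sensor is advanced distally it sits above
(typical distal LAD) or below (typical LCx) that reference level, and the
intervening blood column shifts the measured distal pressure by ρ·g·h while
the aortic reference is unaffected. With ρ = 1050 kg/m³ and g = 9.81 m/s²
this is 0.7726 mmHg per cm; the package's working factor is the
conventionally rounded **0.77 mmHg/cm** so corrected pressures reproduce
clinical arithmetic digit for digit (the unrounded value is available via
`PhysicalConstants.hydrostatic_factor_exact`). Sign convention:
`height_cm > 0` means sensor above tip, and the correction *adds*
`0.77·height_cm` to the measured Pd in both states. Only the distal
pressure is corrected; Pa is the reference by construction.

Skipping the correction distorts the pressure-bounded quantities
asymmetrically: a sensor above the tip inflates both gradients, compresses
their ratio toward 1 and biases MRRpb_max *downward*; a sensor below the
tip shrinks the already-small resting gradient toward zero and can inflate
MRRpb_max arbitrarily (or destroy it entirely when the measured resting
gradient crosses zero). The test suite asserts both directions.

## Pressure bounds

The trans-lesion drop is modelled as ΔP = f·Q + s·Q². The two single-term
limits bracket the flow ratio: a purely quadratic drop gives
CFR = √(ΔP_hyp/ΔP_rest) (lower bound), a purely linear drop gives
CFR = ΔP_hyp/ΔP_rest (upper bound). This containment is exact for any
non-negative f, s (proved algebraically; verified on random mixed-loss
vessels and on every synthetic cohort). Bounds below 1 are floored to 1
with a quality flag — a reserve below unity is non-physical under the
model. MRR bounds are the CFR bounds times Pa_rest/cPd_hyp.

Classification follows the interval: abnormal when the whole CFR interval
is < 2, normal when entirely ≥ 2 (boundary counts as normal),
indeterminate when it straddles the threshold. CMD is flagged at
MRR_p-3D < 2.5 (strict).

## Loss coefficients from 3D-QCA geometry

The per-segment viscous coefficient is Poiseuille,
`f = 128 µL/(π D⁴)` with the segment's mean lumen diameter and a circular
cross-section; the lesion's separation coefficient is the classical
expansion-loss form `s = k_e (ρ/2)(1/A_sten − 1/A_ref)²` with the distal
segment's area as reference and k_e = 1.21 by default. All constants
(µ = 3.5 mPa·s, ρ = 1050 kg/m³, k_e) are exposed in `PhysicalConstants`
so alternative calibrations can be swapped in; the stenosis segment's own
viscous term is plain Poiseuille on its mean diameter (no separate
entrance term), which is the main calibration point against other
implementations of this family of models. Units at the API are clinical
(mmHg, ml/s, mm); conversions are internal.

Flow inversion uses the rationalized root
`Q = 2·ΔP / (f + √(f² + 4sΔP))`, algebraically identical to the textbook
quadratic root but numerically stable when s·ΔP ≪ f² (the subtractive form
loses all significance there). The s = 0 linear limit is analytic.
Coefficients are built once per vessel and shared between rest and
hyperemia; geometry does not change with the vasodilator.

`mrr_ratio = (MRRpb_max − MRR_p-3D)/(MRRpb_max − MRRpb_min)` locates the
actual MRR in its interval (0 = upper bound, 1 = lower); intervals
narrower than 1e-12 are reported as NaN rather than dividing by ~0.

## Prediction models

The linear predictor maps the upper MRR bound to the actual MRR. The
quadratic predictor inverts the interval-position definition: a quadratic
in AS% predicts the position (`ratio`), clamped to [0, 1], and
`MRR_pq = MRRpb_max − ratio·(MRRpb_max − MRRpb_min)`. The clamp matters —
outside roughly AS% ∈ [0, 85] the quadratic exits the unit interval, and an
unclamped ratio would extrapolate the prediction outside the bounds that
define it. Rows without AS% fall back to the linear prediction with a flag.
Published coefficient sets are immutable presets; refitting
(`derive_coefficients`) always produces a new set.

Statistics are ordinary least squares (statsmodels): the linear fit reports
the two-sided slope t-test, the quadratic fit the overall F-test; r² is
clamped to [0, 1] and reported as 0 for a constant response. Pearson r
uses scipy with the t-distribution p-value. Bland–Altman differences are
oriented reference − test (Doppler − predicted) with the sample (n−1) SD
and the 1.96 multiplier. Doppler MRR uses the hydrostatic-corrected
cPd_hyp by default (`use_corrected_pd_for_doppler=False` restores the raw
reading for sensitivity analyses).

## Synthetic cohorts

The generator forward-evaluates the same loss model: draw a three-segment
geometry (distal diameter 2.2–3.5 mm, proximal taper 1.05–1.3×, AS%
30–75 — intermediate-severity single lesions), a resting flow
(0.7–1.6 ml/s), a true CFR (1.3–3.8), aortic pressures
(Pa_rest ~ N(95, 8) mmHg, hyperemia 2–8 mmHg lower), and a height offset
by vessel label (LAD +3..+9 cm, LCx −9..−3, RCA ±4); then
`Pd_measured = Pa − (f·Q + s·Q²) − 0.77·h + ε` with optional Gaussian ε on
every measured pressure (default ε = 0: the exact-model regime). These
ranges land FFR roughly in 0.6–0.95 and were chosen once as a plausible
intermediate-lesion envelope. Draws whose implied hyperemic distal
pressure falls below 55% of Pa (a flow the microvasculature could not
sustain) are resampled — independently drawn CFR and stenosis severity can
otherwise combine into physically impossible vessels. Each vessel has its
own RNG stream keyed by (seed, index), so enlarging a cohort never
reshuffles existing rows and identical parameters give byte-identical
CSVs.

Synthetic Doppler velocities are the true flows divided by the distal
lumen area, so the velocity ratio equals the flow ratio exactly — the
assumption underlying Doppler CFR; `doppler_distortion` and
`apv_noise_sd` break it on demand.

What the generator does *not* emulate: pressure-trace dynamics (drift,
wedging, beat averaging), diffuse or multi-lesion disease, tapered
references, collateral flow, and any correlation structure between
geometry and flow beyond the feasibility screen. Passing tests therefore
certify the computational chain and its noise behaviour under the stated
model, not clinical performance.

## Noise behaviour and the bias measure

Measurement noise enters the solved resting flow through the reciprocal of
the resting gradient, which in these cohorts is small (often 1–4 mmHg).
The resulting relative-error distribution is heavy-tailed: its sample mean
does not stabilize even at thousands of vessels, so the package quantifies
noise bias as the **median** signed relative MRR error among vessels with
a true resting gradient ≥ 5 mmHg. At 1 mmHg noise this median bias is
about 1% (3000-vessel cohorts), while the median absolute error is ~12% —
the documented fragility of pressure-derived MRR at inconspicuous resting
gradients. Tests use 3000 vessels for this check; the noise-free
containment/recovery checks use 500.

## Numerical choices and degenerate inputs

- Non-positive corrected gradients (wedge, over-correction) flag the row;
  bound and hemodynamic stages return invalid/NaN for it and the cohort
  run continues.
- `solve_flow` rejects f = s = 0 and negative ΔP outright.
- Forward–inverse consistency of the flow solve is required to 1e-9
  relative (measured ~1e-16); noise-free pipeline recovery of the true MRR
  to 1e-6 relative (measured ~1e-14).
- CSV floats are written at 6 significant digits; rows are never dropped,
  and flagged rows are excluded from regressions with a logged count.

## Known limitations

Single-lesion, three-segment topology only; the stenosis viscous term is
uncalibrated against angiographic reference implementations; the
derivation/validation statistics on synthetic cohorts characterize the
algorithmic chain, not patients. The published presets are carried as
constants and are only as good as their small derivation cohort.
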