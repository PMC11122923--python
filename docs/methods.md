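# Methods

## Physical model and assumptions

The package models passive plasma separation as constant-pressure dead-end
cake filtration. The driving pressure is the Young–Laplace capillary
pressure of the plasma meniscus in the reservoir microchannel,
ΔP = 2γcosθ(1/h + 1/w); because the reservoir groove (~37 mm across) dwarfs
its height (80 µm), the thin-slit limit 2γcosθ/h is the default (`w=None`
in `DeviceGeometry`). ΔP is treated as constant over a run: the meniscus
advances through a channel of uniform height, and wetting properties are
assumed uniform after protein (BSA) treatment of the surface.

Red blood cells retained on the membrane form a growing cake whose
hydraulic resistance is proportional to the filtrate volume. With the
clean-membrane resistance expressed as an *equivalent filtrate volume* Ve,
the volume balance gives the rate law

    dV/dτ = k A² / (2 (V + Ve)),     k = 2ΔP / (r μ v),

whose integral from V(0)=0 is V(τ) = √(kA²τ + Ve²) − Ve. All downstream
quantities follow algebraically from this one law: the relative rate
q = (dV/dτ)/V, the steady-state volume Vq solving q = q_th, its inverse
(the design rule), the steady-state time τq, and the derivatives of Vq with
respect to area. The implementation keeps this family exactly
self-consistent — the test suite verifies the closed-form V(τ) against
direct numerical integration of the rate law, the derivatives against
finite differences, and the design inversion as an exact round trip.

k and Ve are *lumped empirical parameters*. No attempt is made to model
pore-scale clogging, hematocrit-dependent viscosity, cake compressibility,
hemolysis kinetics, or temperature/humidity effects; on real devices k and
Ve are simply fitted per blood sample and device treatment.

## Units and parameters

Canonical units: µL (volume), mm² (area), µm (height/width), min (time),
Pa (pressure). k then carries µL²·mm⁻⁴·min⁻¹ (1 µL²·mm⁻⁴ = 10⁻⁶ m², so
k[canonical] = k[m²/s] × 6×10⁷); realistic devices land at k ≈ 0.01–1,
which keeps fitted parameters well scaled.

| parameter | meaning | default | why |
|---|---|---|---|
| `q_th` | steady-state threshold on q | 0.05 /min | the "5 % or less" completion rule; per-minute is this package's convention since the rule is dimensionally a rate. Configurable on `FiltrationModel`. |
| `h` | channel height | 80 µm | machined groove depth of the reference device |
| `A_min` | feasibility floor | 7 mm² | below this, inlet-wall capillarity stalls filtration; device/treatment specific, hence a geometry field |
| validated range | design targets | 5–30 µL | bench-validated window; outside it the inversion still computes but flags extrapolation |

With the consistent kinetics the steady-state time is
τq = (1 + Ve/(Vq+Ve))/(2 q_th) ∈ [10, 20) min at q_th = 0.05/min: fastest
for a cake-dominated device (Ve → 0), approaching 20 min only in the
membrane-dominated limit. Every run completes within 20 min.

## Steady-state detection

On sampled data q is discretized with backward differences,
q_i = (V_i − V_{i−1}) / ((τ_i − τ_{i−1}) · V_i), normalized by the
*current* volume so q is defined whenever V_i > 0 (intervals ending at
V = 0 are skipped). Because V(τ) is concave, the discrete q_i slightly
exceeds the instantaneous q at the interval end, so detection fires at most
one sampling interval after the analytic τq — never early. The default
`consecutive=3` requires three quiet intervals in a row before declaring
steady state, suppressing single-step false alarms on noisy data; use
`consecutive=1` to reproduce the ideal-curve behaviour.

## Fitting

Both fits are unweighted nonlinear least squares (no replicate error model
is assumed), run with `scipy.optimize.least_squares` (trust-region
reflective, ftol = xtol = gtol = 10⁻¹², ≤ 10⁴ evaluations). Positivity is
enforced by optimizing (log k, log(Ve+ε)); ε is scaled to the data
(10⁻³ × max observed volume, floored at 10⁻⁶) because a fixed tiny ε
leaves the Ve = 0 start with vanishing gradient and stalls the parameter.
Initialization is fixed and documented — Ve = 0, with k seeded from the
square-root-law regression (through-origin fit of Vq on A for calibration
data; median of V²/(A²τ) for time courses) — so results are deterministic.

Identifiability: k is well determined by calibration data (median relative
error ≈ 4 % at bench conditions: 4 areas × 3 replicates, 3 % CV). Ve is
weakly identified from steady-state data because its sensitivity
∂Vq/∂Ve ≈ −0.4 is nearly constant across the bench areas, making it close
to collinear with k; its median relative error at the same conditions is
≈ 18 %, and this is intrinsic to the experiment design, not the estimator.
Crucially the *design* quantity Vq(A) — and hence the designed area — is
much better determined than Ve alone, which is why end-to-end design errors
stay small (below). Residual RMS is the only uncertainty measure reported;
bootstrap or profile confidence intervals are out of scope.

## Image quantification

V = S·h with S from thresholding 8-bit greyscale frames (fixed intensity or
Otsu's method for `"auto"`; an invert flag handles dark-plasma polarity).
No illumination correction, morphology, meniscus modelling or frame
registration is applied — reservoir images of these devices are
high-contrast and static. Pixel size is supplied by the caller, never read
from file metadata.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the bench conditions: 30-s sampling over 20-min
runs, the four calibration areas 12.56/19.63/28.26/38.47 mm², three
replicates, whole blood at 48 % hematocrit (~5×10⁶ RBC/µL), five 0.02-µL
count samples per replicate. Measurement noise is multiplicative Gaussian
on volumes (CV 3 % by default) — image-area reading error dominates on the
bench and scales with the measured area; deviates are clipped at ±3σ to
keep volumes positive without visible mean bias (relative bias < 10⁻³ at
CV 3 %). No replicate scatter is published for the bench experiments, so
the CV is this package's calibration choice: 3 % makes the device-level
±10 % accuracy claim the binding constraint rather than a foregone
conclusion. Reservoir frames render plasma as a clean annulus spreading
from the central boss (6 mm) toward the groove wall (37 mm) with additive
pixel noise (σ = 5 intensity units); real wetting fronts are ragged, but
only total area enters the pipeline. Cell counts are Poisson.

Consequently, passing tests demonstrate correctness of the *method* under
its own assumptions — they do not certify performance on real blood, where
donor-to-donor variation of hematocrit and viscosity, inlet stall,
temperature effects and irregular wetting all enter. Those effects are
deliberately outside the model (feasibility flags and this note are their
only trace).

## End-to-end accuracy

The package's headline check mirrors the device-accuracy experiment:
calibrate on noisy synthetic data (truth k = 0.05, Ve = 4, bench
conditions), fit, design areas for 5/10/15/20/30 µL, then score the
designed areas under the generating model. At seed 42 the maximum relative
deviation is 0.16 %; across 100 seeds, 99 % stay within the 10 % bound
(worst observed 11.1 %), with the 5-µL target — an extrapolation below the
smallest calibrated area — dominating the error. `scripts/acceptance.py`
recomputes this from scratch for any seed.

## Numerical choices and degenerate inputs

- The rate at V = 0 with Ve = 0 is a declared domain error (the cake-free
  model is singular there), not an infinity.
- `steady_state_volume` and the design inversion are closed forms; round
  trips hold to 10⁻⁹ or better.
- dVq/dA at Ve = 0 is returned as the exact constant √(k/(2 q_th)),
  avoiding 0/0 at A = 0; d²Vq/dA² is exactly 0 there.
- Degenerate fits: all-zero curves are rejected; physically inconsistent
  calibrations (flat Vq across areas) converge to a boundary fit and are
  flagged by large residual RMS rather than raised.
- Rounding of reported percentages is half-up at the requested decimals,
  matching hand-reported one-decimal figures (mean residue 0.2 % ↔ capture
  efficiency 99.8 %). The residue-rate denominator is the input whole-blood
  RBC concentration (configurable), a convention this package fixes since
  count-based and concentration-based definitions coincide for equal
  sample volumes.

## Known limitations

- Single (k, Ve) per fit: no hierarchical/multi-donor modelling, no robust
  loss, no uncertainty beyond residual RMS.
- Area is the only design variable; channel height and wetting are fixed
  inputs.
- The feasibility floor and validated target range are flags, not physics:
  the model itself extrapolates smoothly and silently beyond them.
- Image segmentation assumes bimodal high-contrast frames; it will fail
  loudly (uniform image) or quietly (poor contrast) outside that regime.
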