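# plasmasep

Modelling and design tools for **capillary-force-driven quantitative plasma
separation** — passive microfluidic devices that filter a drop of whole
blood through an asymmetric membrane and collect a *predetermined* plasma
volume with no pump, no centrifuge and no operator skill. Red blood cells
pile up on the membrane as a filter cake that throttles its own flow, so
the collected volume saturates at a value set by the effective filtration
area rather than by how much blood was loaded. That self-limiting behaviour
is what this package models, fits and inverts.

Intended users: microfluidics and point-of-care-diagnostics researchers who
want to size a membrane for a target plasma volume (5–30 µL scale), analyse
bench filtration curves, or quantify separation performance from reservoir
images and cell counts.

## The model

Constant-pressure dead-end cake filtration driven by Young–Laplace
capillary pressure in a thin slit of height *h*:

```
ΔP = 2 γ cosθ (1/h + 1/w)  →  2 γ cosθ / h   (w ≫ h)

dV/dτ = k A² / (2 (V + Ve)),      k = 2 ΔP / (r μ v)
V(τ)  = √(k A² τ + Ve²) − Ve
q(V)  = (dV/dτ)/V = k A² / (2 V (V + Ve))
```

where *V* is plasma volume (µL), *A* effective filtration area (mm²),
*k* the filtering constant (µL²·mm⁻⁴·min⁻¹), *Ve* the equivalent filtrate
volume (µL, the filtrate at which cake resistance matches the clean
membrane), *r* the specific cake resistance, *μ* plasma viscosity and *v*
cake volume per unit filtrate. Separation is declared complete when the
relative rate *q* falls to `q_th` (5 %/min by default), giving the
steady-state volume and its closed-form inverse — the design rule:

```
Vq(A) = √(k A²/(2 q_th) + Ve²/4) − Ve/2
A(Vq) = √(2 q_th · Vq (Vq + Ve) / k)
```

`Vq(A)` is strictly increasing and convex; the steady-state time is bounded
between 1/(2 q_th) and 1/q_th (10–20 min at the default threshold), so a
run always finishes within 20 min.

## Worked example

Simulate a bench calibration experiment (ground truth k = 0.05, Ve = 4 µL,
3 % measurement noise at the four bench areas 12.56/19.63/28.26/38.47 mm²),
fit the model, and design membrane areas for five target volumes:

```sh
$ plasmasep simulate --seed 42 --k 0.05 --ve 4 --cv 0.03 --out-dir sim
wrote calibration + 12 curves to sim (seed=42)

$ plasmasep fit --calibration sim/calibration.csv --out model.yaml
k = 0.0500392 uL^2 mm^-4 min^-1, Ve = 4.02945 uL (rms 0.4578 uL, converged=True) -> model.yaml

$ plasmasep design --model model.yaml --targets 5,10,15,20,30 --out design.csv
 target_uL  area_mm2  predicted_uL  rel_error  feasible
         5     9.499             5          0      True
        10     16.74            10          0      True
        15     23.88            15  1.184e-16      True
        20     30.99            20          0      True
        30     45.17            30          0      True
```

Reading the output: the fitted k and Ve land within ~1 % of the generating
values despite the noise; the design table lists, per target volume, the
membrane area to machine, the volume that area delivers under the fitted
model (an exact round trip, hence zero `rel_error` here), and a feasibility
flag (areas under 7 mm² stall on inlet capillarity and are marked
infeasible). Scoring these designed areas against the *generating* model —
the honest measure of design accuracy under noisy calibration — gives a
maximum deviation of 0.16 % for this seed (see below).

The same library drives image-based volume quantification
(`plasmasep quantify`: threshold each reservoir frame, area × channel
height = volume) and purity metrics (`plasmasep quality`: red-blood-cell
residue rate and capture efficiency from hemocytometer count tables);
everything is importable from Python (`import plasmasep`).

## Layout

- `plasmasep.core` — closed-form physics (pressure, rate law, kinetics,
  steady state, derivatives), pure functions, explicit units.
- `plasmasep.estimation` — steady-state detection and (k, Ve) fitting from
  curves or calibration tables.
- `plasmasep.design` — area-for-volume inversion with feasibility checks.
- `plasmasep.imaging` — segmentation and V = S·h volume quantification.
- `plasmasep.quality` — residue rate and capture efficiency from counts.
- `plasmasep.simulate` — synthetic bench data with known ground truth.
- `plasmasep.io` / `plasmasep.cli` — delimited-text formats and the
  `plasmasep` command.

See `docs/methods.md` for modelling assumptions, parameter conventions and
limitations.
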