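"""Invert the fitted filtration model to size the membrane for a target
plasma volume.

Because the steady-state volume satisfies Vq (Vq + Ve) = k A^2 / (2 q_th),
the effective filtration area delivering a requested volume has the closed
form

    A = sqrt(2 q_th * V * (V + Ve) / k).

Feasibility: below roughly 7 mm^2 the capillary pull of the inlet tube wall
stalls filtration altogether, so areas under ``DeviceGeometry.A_min`` are
flagged infeasible.  Bench validation of the method covered targets of
5-30 uL; targets outside that window are still computed but marked as
extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import DeviceGeometry, FiltrationModel, steady_state_volume

__all__ = ["DesignSpec", "VALIDATED_RANGE_UL", "required_area", "design_report"]

#: Target plasma volumes (uL) over which the design rule has been validated.
VALIDATED_RANGE_UL: tuple[float, float] = (5.0, 30.0)


@dataclass(frozen=True)
class DesignSpec:
    """One design result: the target volume (uL), the required effective
    filtration area (mm^2), the volume that area is predicted to deliver
    under the evaluation model (uL), the signed relative error versus the
    target, and feasibility flags."""

    target_volume: float
    required_area: float
    predicted_vq: float
    relative_error: float
    feasible: bool
    in_validated_range: bool
    reason: str = ""


def required_area(
    target: float,
    model: FiltrationModel,
    geom: DeviceGeometry,
    eval_model: FiltrationModel | None = None,
) -> DesignSpec:
    """Effective filtration area that yields ``target`` uL at steady state.

    ``eval_model`` lets the designed area be re-evaluated under a different
    (e.g. ground-truth) model than the one used for the inversion, which is
    how a calibrate-on-noisy / evaluate-on-truth experiment is scored; by
    default the design model evaluates itself and the round trip is exact.
    """
    if not target > 0:
        raise ValueError(f"target volume must be positive, got {target}")
    area = math.sqrt(2.0 * model.q_th * target * (target + model.Ve) / model.k)
    predicted = float(steady_state_volume(eval_model or model, area))
    rel_err = (predicted - target) / target

    feasible = True
    reasons = []
    if area < geom.A_min:
        feasible = False
        reasons.append(
            f"required area {area:.3g} mm^2 is below the minimum feasible "
            f"area {geom.A_min:g} mm^2 (inlet capillary stall)"
        )
    lo, hi = VALIDATED_RANGE_UL
    in_range = lo <= target <= hi
    if not in_range:
        reasons.append(
            f"target {target:g} uL lies outside the validated {lo:g}-{hi:g} uL "
            "range; result is an extrapolation"
        )
    return DesignSpec(
        target_volume=float(target),
        required_area=float(area),
        predicted_vq=predicted,
        relative_error=float(rel_err),
        feasible=feasible,
        in_validated_range=in_range,
        reason="; ".join(reasons),
    )


def design_report(
    targets: list[float],
    model: FiltrationModel,
    geom: DeviceGeometry,
    eval_model: FiltrationModel | None = None,
) -> list[DesignSpec]:
    """One :class:`DesignSpec` per requested target volume."""
    if not targets:
        raise ValueError("target list is empty")
    return [required_area(t, model, geom, eval_model=eval_model) for t in targets]
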