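"""Fit the filtration model (k, Ve) to measured data and detect steady state.

Two data routes estimate the same two parameters:

* ``fit_time_course`` — nonlinear least squares of the closed-form V(tau)
  law against one or more sampled filtration curves (possibly at different
  filtration areas, sharing one (k, Ve)).
* ``fit_steady_state`` — least squares of the steady-state volume Vq(A)
  against an (area, volume) calibration table, the route used to design
  devices for a target plasma volume.

``detect_steady_state`` applies the q <= q_th stopping rule to a sampled
curve using backward differences, the discrete analogue of the relative
rate q = (dV/dtau)/V.

Positivity of both parameters is enforced by optimizing log k and
log(Ve + eps); the epsilon is scaled to the data (1e-3 of the largest
observed volume) so a Ve = 0 start retains a usable gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import FiltrationModel, steady_state_volume, volume_at_time

__all__ = [
    "FiltrationCurve",
    "CalibrationSet",
    "FitResult",
    "SteadyStateDetection",
    "detect_steady_state",
    "fit_time_course",
    "fit_steady_state",
]


@dataclass
class FiltrationCurve:
    """One device run: plasma volume sampled over time.

    ``times`` are in seconds (the bench protocol images the reservoir every
    30 s), ``volumes`` in uL, ``area`` is the device's effective filtration
    area in mm^2 (``None`` if unknown, e.g. a curve quantified from images
    of an uncharacterized device).
    """

    times: np.ndarray
    volumes: np.ndarray
    area: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must be 1-D arrays of equal length")
        if len(self.times) < 3:
            raise ValueError(f"a filtration curve needs >= 3 samples, got {len(self.times)}")
        if self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be nonnegative")
        if self.area is not None and not self.area > 0:
            raise ValueError(f"area must be positive when given, got {self.area}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class CalibrationSet:
    """(effective filtration area, steady-state plasma volume) pairs.

    Replicates are plain repeated areas; ``distinct_areas`` collapses them.
    """

    areas: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.areas.ndim != 1 or self.areas.shape != self.volumes.shape:
            raise ValueError("areas and volumes must be 1-D arrays of equal length")
        if len(self.areas) == 0:
            raise ValueError("calibration set is empty")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be nonnegative")

    @property
    def distinct_areas(self) -> np.ndarray:
        return np.unique(self.areas)

    def __len__(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a (k, Ve) fit: the model, per-point residuals
    (observed - predicted, uL), their RMS, and optimizer diagnostics."""

    model: FiltrationModel
    residuals: np.ndarray
    rms_error: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class SteadyStateDetection:
    """Steady-state point of a sampled curve: the sample index at which the
    q <= q_th rule fires, its time (s) and volume (uL), and whether the
    rule fired at all within the record."""

    tau_q: float
    v_q: float
    index: int
    achieved: bool


def _discrete_q(curve: FiltrationCurve) -> np.ndarray:
    """Backward-difference relative rate per interval, per minute.

    q_i = (V_i - V_{i-1}) / ((t_i - t_{i-1})/60 * V_i); intervals whose
    endpoint volume is zero are NaN (q undefined before any filtrate).
    """
    dv = np.diff(curve.volumes)
    dt_min = np.diff(curve.times) / 60.0
    v_end = curve.volumes[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        q = dv / (dt_min * v_end)
    q[v_end == 0] = np.nan
    return q


def detect_steady_state(
    curve: FiltrationCurve, q_th: float = 0.05, consecutive: int = 3
) -> SteadyStateDetection:
    """First sample at which the relative rate stays at or below ``q_th``
    (per minute) for ``consecutive`` successive intervals.

    Requiring several quiet intervals in a row (default 3) suppresses
    spurious early detections on noisy data, where a single flat step can
    occur long before the cake has actually sealed the membrane.  Returns
    ``achieved=False`` with the final sample if the rule never fires.
    """
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    if len(curve) < consecutive + 1:
        raise ValueError(
            f"curve has {len(curve)} points; need at least {consecutive + 1} "
            f"for {consecutive} consecutive intervals"
        )
    q = _discrete_q(curve)
    ok = (q <= q_th) & ~np.isnan(q)  # NaN (V=0) breaks a run
    run = 0
    for i, good in enumerate(ok):
        run = run + 1 if good else 0
        if run >= consecutive:
            idx = i + 1  # interval i ends at sample i+1
            return SteadyStateDetection(
                tau_q=float(curve.times[idx]),
                v_q=float(curve.volumes[idx]),
                index=idx,
                achieved=True,
            )
    last = len(curve) - 1
    return SteadyStateDetection(
        tau_q=float(curve.times[last]),
        v_q=float(curve.volumes[last]),
        index=last,
        achieved=False,
    )


def _fit_positive(predict, observed: np.ndarray, k0: float, q_th: float) -> FitResult:
    """Shared least-squares machinery over (log k, log(Ve + eps)).

    ``predict(k, Ve)`` returns model values aligned with ``observed``.
    Deterministic: fixed Ve = 0 start, tolerances 1e-12, <= 1e4 evaluations.
    """
    eps = max(1.0e-6, 1.0e-3 * float(np.max(observed)))
    x0 = np.array([np.log(k0), np.log(eps)])  # Ve = 0 start

    def unpack(x):
        k = float(np.exp(x[0]))
        ve = max(float(np.exp(x[1])) - eps, 0.0)
        return k, ve

    def resid(x):
        k, ve = unpack(x)
        return observed - predict(k, ve)

    res = least_squares(
        resid,
        x0,
        bounds=([-np.inf, np.log(eps)], [np.inf, np.inf]),
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=10_000,
    )
    k_hat, ve_hat = unpack(res.x)
    model = FiltrationModel(k=k_hat, Ve=ve_hat, q_th=q_th)
    return FitResult(
        model=model,
        residuals=res.fun,
        rms_error=float(np.sqrt(np.mean(res.fun**2))),
        converged=bool(res.status > 0),
        n_iter=int(res.nfev),
    )


def fit_time_course(
    curves: FiltrationCurve | list[FiltrationCurve], q_th: float = 0.05
) -> FitResult:
    """Fit (k, Ve) to one or more filtration curves by least squares on the
    closed-form V(tau) law, sharing the parameters across curves.

    Each curve must carry its filtration area.  The start value for k comes
    from the Ve = 0 square-root law, k0 = median(V^2 / (A^2 tau)) over
    nonzero samples.
    """
    if isinstance(curves, FiltrationCurve):
        curves = [curves]
    if not curves:
        raise ValueError("need at least one curve")
    for c in curves:
        if c.area is None:
            raise ValueError(f"curve {c.label!r} has no filtration area; cannot fit")
    tau_min = [c.times / 60.0 for c in curves]
    obs = np.concatenate([c.volumes for c in curves])
    if not np.any(obs > 0):
        raise ValueError("degenerate input: all volumes are zero")

    k0_samples = np.concatenate(
        [c.volumes[tau > 0] ** 2 / (c.area**2 * tau[tau > 0]) for c, tau in zip(curves, tau_min)]
    )
    k0_samples = k0_samples[k0_samples > 0]
    k0 = float(np.median(k0_samples)) if len(k0_samples) else 1e-3

    def predict(k, ve):
        m = FiltrationModel(k=k, Ve=ve, q_th=q_th)
        return np.concatenate(
            [volume_at_time(m, c.area, tau) for c, tau in zip(curves, tau_min)]
        )

    return _fit_positive(predict, obs, k0, q_th)


def fit_steady_state(cal: CalibrationSet, q_th: float = 0.05) -> FitResult:
    """Fit (k, Ve) to an (area, steady-state volume) calibration table by
    least squares on Vq(A).

    Needs at least two distinct areas (three or more recommended: with two
    the fit is exactly determined and residuals carry no information).  The
    start value for k comes from a through-origin linear fit of Vq on A
    (the Ve = 0 regime, where Vq = A sqrt(k / (2 q_th)))."""
    if len(cal.distinct_areas) < 2:
        raise ValueError(
            f"need >= 2 distinct areas to fit, got {len(cal.distinct_areas)}"
        )
    slope = float(np.sum(cal.areas * cal.volumes) / np.sum(cal.areas**2))
    k0 = max(2.0 * q_th * slope**2, 1e-12)

    def predict(k, ve):
        m = FiltrationModel(k=k, Ve=ve, q_th=q_th)
        return steady_state_volume(m, cal.areas)

    return _fit_positive(predict, cal.volumes, k0, q_th)
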