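"""Closed-form cake-filtration physics for capillary-driven plasma separation.

A drop of whole blood placed on an asymmetric membrane is filtered passively:
the Young–Laplace capillary pressure of the plasma meniscus in a thin
microchannel pulls plasma through the membrane while red blood cells pile up
on it as a resistive cake.  The cake grows with the filtrate volume, so the
flow is self-limiting and the collected plasma volume saturates — which is
exactly what makes the device *quantitative*: the steady-state volume is set
by the effective filtration area, not by how much blood was loaded.

The lumped kinetic model is the constant-pressure dead-end cake-filtration
law

    dV/dtau = k A^2 / (2 (V + Ve)),        k = 2 dP / (r mu v)

with ``V`` the filtrate (plasma) volume, ``A`` the effective filtration
area, ``Ve`` the equivalent filtrate volume at which cake resistance equals
the clean-membrane resistance, ``r`` the specific cake resistance, ``mu``
the plasma viscosity, ``v`` the cake volume deposited per unit filtrate and
``dP`` the capillary driving pressure.  Integrating from V(0) = 0 gives

    V(tau) = sqrt(k A^2 tau + Ve^2) - Ve.

Separation is declared complete when the relative volumetric growth rate

    q(V) = (dV/dtau) / V = k A^2 / (2 V (V + Ve))

falls below a threshold ``q_th`` (5 %/min by convention), which defines the
steady-state volume ``Vq`` through V (V + Ve) = k A^2 / (2 q_th).

Canonical units throughout this package: volume in uL, area in mm^2,
channel height/width in um, time in min, pressure in Pa.  The filtering
constant ``k`` therefore carries uL^2 mm^-4 min^-1; with these units the
fitted parameters land at O(0.01-1) for real devices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidProperties",
    "CakeProperties",
    "DeviceGeometry",
    "FiltrationModel",
    "PressureResult",
    "capillary_pressure",
    "filtering_constant",
    "filtration_rate",
    "volume_at_time",
    "relative_rate_q",
    "steady_state_volume",
    "steady_state_time",
    "dVq_dA",
    "d2Vq_dA2",
    "K_SI_TO_CANONICAL",
]

#: 1 uL^2 mm^-4 = (1e-9 m^3)^2 / (1e-3 m)^4 = 1e-6 m^2, and 1 min = 60 s,
#: so k[uL^2 mm^-4 min^-1] = k[m^2 s^-1] * 60 / 1e-6.
K_SI_TO_CANONICAL = 60.0 / 1.0e-6


@dataclass(frozen=True)
class FluidProperties:
    """Wetting and transport properties of the filtrate (plasma).

    Parameters
    ----------
    gamma : float
        Surface tension at the meniscus, N/m.
    theta : float
        Contact angle on the channel surface, degrees.  BSA treatment of the
        channel lowers it from ~78 deg to ~27 deg.
    mu : float
        Dynamic viscosity, Pa*s.
    """

    gamma: float
    theta: float
    mu: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"surface tension must be positive, got {self.gamma}")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError(f"contact angle must lie in [0, 180] deg, got {self.theta}")
        if not self.mu > 0:
            raise ValueError(f"viscosity must be positive, got {self.mu}")


@dataclass(frozen=True)
class CakeProperties:
    """Red-blood-cell cake properties: specific resistance ``r`` (m^-2) and
    cake volume per unit filtrate volume ``v`` (dimensionless)."""

    r: float
    v: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"specific cake resistance must be positive, got {self.r}")
        if not self.v > 0:
            raise ValueError(f"cake volume ratio must be positive, got {self.v}")


@dataclass(frozen=True)
class DeviceGeometry:
    """Microchannel and membrane geometry.

    Parameters
    ----------
    h : float
        Microchannel (reservoir groove) height, um.
    w : float or None
        Channel width, um; ``None`` means unbounded (thin-slit limit,
        appropriate when the groove diameter ~37 mm dwarfs the 80 um height).
    A : float
        Effective filtration area, mm^2.
    A_min : float
        Minimum feasible filtration area, mm^2.  Below ~7 mm^2 the capillary
        pull of the inlet tube wall stalls filtration entirely.
    """

    h: float = 80.0
    w: float | None = None
    A: float = 0.0
    A_min: float = 7.0

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError(f"channel height must be positive, got {self.h}")
        if self.w is not None and not self.w > self.h:
            raise ValueError(f"bounded width must exceed height, got w={self.w}, h={self.h}")
        if self.A < 0:
            raise ValueError(f"filtration area must be nonnegative, got {self.A}")
        if self.A_min < 0:
            raise ValueError(f"minimum area must be nonnegative, got {self.A_min}")


@dataclass(frozen=True)
class FiltrationModel:
    """The two-parameter filtration model plus the steady-state threshold.

    Parameters
    ----------
    k : float
        Filtering constant 2*dP/(r*mu*v), uL^2 mm^-4 min^-1.
    Ve : float
        Equivalent filtrate volume, uL.
    q_th : float
        Steady-state threshold on the relative rate q, fraction per minute
        (default 0.05, i.e. "5 % per minute or less means done").
    """

    k: float
    Ve: float = 0.0
    q_th: float = 0.05

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"filtering constant k must be positive, got {self.k}")
        if self.Ve < 0:
            raise ValueError(f"equivalent filtrate volume must be nonnegative, got {self.Ve}")
        if not 0.0 < self.q_th < 1.0:
            raise ValueError(f"q_th must lie in (0, 1), got {self.q_th}")


@dataclass(frozen=True)
class PressureResult:
    """Capillary driving pressure, Pa.  Negative when theta > 90 deg."""

    delta_p: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_p):
            raise ValueError("capillary pressure must be finite")


def capillary_pressure(fluid: FluidProperties, geom: DeviceGeometry) -> PressureResult:
    """Young–Laplace pressure of a meniscus in a rectangular microchannel.

    dP = 2 gamma cos(theta) (1/h + 1/w); with ``w`` unbounded the thin-slit
    form 2 gamma cos(theta) / h applies.  Heights are supplied in um and
    converted to m internally; the result is in Pa.
    """
    cos_t = math.cos(math.radians(fluid.theta))
    h_m = geom.h * 1.0e-6
    if geom.w is None:
        curvature = 1.0 / h_m
    else:
        curvature = 1.0 / h_m + 1.0 / (geom.w * 1.0e-6)
    return PressureResult(delta_p=2.0 * fluid.gamma * cos_t * curvature)


def filtering_constant(delta_p: float, cake: CakeProperties, mu: float) -> float:
    """Filtering constant k = 2*dP/(r*mu*v), converted from SI (m^2/s) to
    the canonical uL^2 mm^-4 min^-1.

    Parameters are the capillary pressure in Pa, the cake properties, and
    the filtrate viscosity in Pa*s.  All must be strictly positive.
    """
    if not delta_p > 0:
        raise ValueError(f"driving pressure must be positive, got {delta_p}")
    if not mu > 0:
        raise ValueError(f"viscosity must be positive, got {mu}")
    k_si = 2.0 * delta_p / (cake.r * mu * cake.v)  # m^2 / s
    return k_si * K_SI_TO_CANONICAL


def filtration_rate(model: FiltrationModel, A: float, V) -> np.ndarray | float:
    """Instantaneous filtration rate dV/dtau = k A^2 / (2 (V + Ve)), uL/min.

    Strictly positive and strictly decreasing in V.  Undefined at V = 0 for
    a cake-free membrane (Ve = 0): the model has infinite initial rate there,
    which is rejected as a domain error.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("volume must be nonnegative")
    if np.any(V + model.Ve <= 0):
        raise ValueError("rate undefined at V=0 with Ve=0 (cake-free membrane)")
    out = model.k * A**2 / (2.0 * (V + model.Ve))
    return out if out.ndim else float(out)


def volume_at_time(model: FiltrationModel, A: float, tau) -> np.ndarray | float:
    """Collected plasma volume after ``tau`` minutes of filtration, uL.

    Closed-form integral of the rate law: V = sqrt(k A^2 tau + Ve^2) - Ve.
    Nondecreasing and concave in tau with V(0) = 0; for Ve = 0 it reduces to
    the square-root law A*sqrt(k*tau).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("time must be nonnegative")
    out = np.sqrt(model.k * A**2 * tau + model.Ve**2) - model.Ve
    return out if out.ndim else float(out)


def relative_rate_q(model: FiltrationModel, A: float, V) -> np.ndarray | float:
    """Relative volumetric growth rate q = (dV/dtau)/V = k A^2/(2 V (V+Ve)),
    per minute.  Strictly decreasing in V; crosses ``model.q_th`` exactly at
    the steady-state volume."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("relative rate requires V > 0")
    out = model.k * A**2 / (2.0 * V * (V + model.Ve))
    return out if out.ndim else float(out)


def steady_state_volume(model: FiltrationModel, A) -> np.ndarray | float:
    """Steady-state plasma volume Vq at which q drops to q_th, uL.

    Solves Vq (Vq + Ve) = k A^2 / (2 q_th):

        Vq = sqrt(k A^2 / (2 q_th) + 0.25 Ve^2) - 0.5 Ve

    which at the conventional q_th = 0.05/min is sqrt(10 k A^2 + 0.25 Ve^2)
    - 0.5 Ve.  Strictly increasing and convex in A.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("area must be nonnegative")
    c = model.k / (2.0 * model.q_th)
    out = np.sqrt(c * A**2 + 0.25 * model.Ve**2) - 0.5 * model.Ve
    return out if out.ndim else float(out)


def steady_state_time(model: FiltrationModel, A: float) -> float:
    """Time tau_q at which the curve reaches the steady-state volume, min.

    From V(tau_q) = Vq:  tau_q = (Vq^2 + 2 Vq Ve) / (k A^2), equivalently
    (1 + Ve/(Vq+Ve)) / (2 q_th) — bounded in [1/(2 q_th), 1/q_th) for all
    Ve >= 0, i.e. between 10 and 20 min at the default 5 %/min threshold.
    The whole separation therefore completes within 20 min.
    """
    if not A > 0:
        raise ValueError("area must be positive")
    vq = steady_state_volume(model, A)
    return (vq**2 + 2.0 * vq * model.Ve) / (model.k * A**2)


def dVq_dA(model: FiltrationModel, A) -> np.ndarray | float:
    """First derivative of the steady-state volume with respect to area,
    uL/mm^2: (k A / (2 q_th)) / sqrt(k A^2/(2 q_th) + 0.25 Ve^2) > 0 for
    A > 0.  For Ve = 0 it is the constant sqrt(k/(2 q_th))."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("area must be nonnegative")
    c = model.k / (2.0 * model.q_th)
    if model.Ve == 0.0:
        out = np.full_like(A, math.sqrt(c))
    else:
        out = c * A / np.sqrt(c * A**2 + 0.25 * model.Ve**2)
    return out if out.ndim else float(out)


def d2Vq_dA2(model: FiltrationModel, A) -> np.ndarray | float:
    """Second derivative of the steady-state volume with respect to area,
    uL/mm^4: (k/(2 q_th)) * 0.25 Ve^2 / (k A^2/(2 q_th) + 0.25 Ve^2)^(3/2).

    Nonnegative everywhere and identically zero iff Ve = 0 (the linear
    regime); Vq(A) is therefore convex.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("area must be nonnegative")
    if model.Ve == 0.0:
        out = np.zeros_like(A)
    else:
        c = model.k / (2.0 * model.q_th)
        out = c * 0.25 * model.Ve**2 / (c * A**2 + 0.25 * model.Ve**2) ** 1.5
    return out if out.ndim else float(out)
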