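"""Synthetic bench data with known ground truth.

Generators for everything the analysis pipeline consumes:

* filtration curves — the closed-form V(tau) law sampled every 30 s with
  multiplicative Gaussian measurement noise (image-area reading error
  dominates on the bench, and it scales with the measured volume);
* calibration sets — steady-state volumes at the four bench areas
  (12.56, 19.63, 28.26, 38.47 mm^2), replicated;
* reservoir images — a 37 mm circular groove with a 6 mm central boss,
  plasma rendered as a bright annulus of area S = V/h spreading outward
  from the boss, plus additive pixel noise;
* hemocytometer counts — Poisson cell counts for a given true residue rate
  against whole blood at 48 % hematocrit (~5e6 RBC/uL).

Every generator is a pure function of (parameters, seed): the same
:class:`SimulationConfig` always yields the same data.  Noise deviates are
clipped at +/- 3 standard deviations, which keeps volumes positive at the
default 3 % coefficient of variation without visibly biasing the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DeviceGeometry, FiltrationModel, steady_state_volume, volume_at_time
from .estimation import CalibrationSet, FiltrationCurve
from .imaging import ReservoirImage

__all__ = [
    "SimulationConfig",
    "GROOVE_DIAMETER_MM",
    "BOSS_DIAMETER_MM",
    "gen_filtration_curve",
    "gen_calibration_set",
    "gen_reservoir_image",
    "gen_reservoir_series",
    "gen_cell_count_samples",
    "reservoir_capacity",
]

#: Reservoir groove outer diameter (mm) and central boss diameter (mm).
GROOVE_DIAMETER_MM = 37.0
BOSS_DIAMETER_MM = 6.0


@dataclass(frozen=True)
class SimulationConfig:
    """Bench-experiment conditions for all generators.

    Defaults mirror the study conditions: 30-s imaging over a 20-min run,
    3 % multiplicative measurement noise, the four calibration areas,
    three replicates, and whole blood of 48 % hematocrit at 5e6 RBC/uL.
    The seed is mandatory — synthetic data is only useful when reproducible.
    """

    seed: int
    noise_cv: float = 0.03
    interval: float = 30.0  # s between samples
    duration: float = 20.0  # min, total run length
    areas: tuple[float, ...] = (12.56, 19.63, 28.26, 38.47)  # mm^2
    replicates: int = 3
    blood_conc: float = 5.0e6  # cells/uL
    hematocrit: float = 0.48

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise CV must be nonnegative, got {self.noise_cv}")
        if not self.interval > 0 or not self.duration > 0:
            raise ValueError("interval and duration must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(a <= 0 for a in self.areas):
            raise ValueError("areas must be positive")
        if not 0 <= self.hematocrit <= 1:
            raise ValueError(f"hematocrit must be a fraction, got {self.hematocrit}")


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    """Deterministic sub-stream: the config seed plus integer stream tags."""
    return np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, *stream])


def _multiplicative_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    eps = rng.normal(0.0, cv, size=shape) if cv > 0 else np.zeros(shape)
    return 1.0 + np.clip(eps, -3.0 * cv, 3.0 * cv)


def gen_filtration_curve(
    model: FiltrationModel, A: float, cfg: SimulationConfig, replicate: int = 0
) -> FiltrationCurve:
    """Noisy sampled filtration curve for one device run.

    Samples V(tau) at t = 0, interval, 2*interval, ... up to ``duration``
    minutes, then applies independent multiplicative Gaussian noise
    (1 + eps), eps ~ N(0, cv^2) clipped at 3 sigma.  ``replicate`` selects
    an independent noise sub-stream under the same seed.
    """
    times_s = np.arange(0.0, cfg.duration * 60.0 + 0.5 * cfg.interval, cfg.interval)
    truth = volume_at_time(model, A, times_s / 60.0)
    rng = _rng(cfg, 1, replicate, int(round(A * 1000)))
    noisy = truth * _multiplicative_noise(rng, truth.shape, cfg.noise_cv)
    return FiltrationCurve(
        times=times_s, volumes=noisy, area=A, label=f"sim A={A:g} rep={replicate}"
    )


def gen_calibration_set(model: FiltrationModel, cfg: SimulationConfig) -> CalibrationSet:
    """Noisy (area, steady-state volume) table: every configured area times
    every replicate, with the same multiplicative noise model."""
    areas = np.repeat(np.asarray(cfg.areas, dtype=float), cfg.replicates)
    truth = steady_state_volume(model, areas)
    rng = _rng(cfg, 2)
    noisy = truth * _multiplicative_noise(rng, truth.shape, cfg.noise_cv)
    return CalibrationSet(areas=areas, volumes=noisy)


def reservoir_capacity(geom: DeviceGeometry) -> float:
    """Plasma capacity (uL) of the annulus between boss and groove wall at
    channel height ``geom.h``."""
    r_out = GROOVE_DIAMETER_MM / 2.0
    r_in = BOSS_DIAMETER_MM / 2.0
    return math.pi * (r_out**2 - r_in**2) * geom.h * 1.0e-3


def gen_reservoir_image(
    fill_volume: float,
    geom: DeviceGeometry,
    pixel_size: float,
    cfg: SimulationConfig,
    timestamp: float | None = None,
    frame: int = 0,
) -> tuple[ReservoirImage, float]:
    """Render a reservoir frame at a given plasma fill volume.

    Plasma occupies the annulus from the boss edge (3 mm radius) outward to
    the radius enclosing area S = V/h; it is drawn bright (200) on a dark
    (30) background with additive N(0, 5) pixel noise, clipped to [0, 255].
    Returns the image and the exactly rendered plasma area in mm^2 (the
    pixelated ground truth, for oracle use).
    """
    if fill_volume < 0:
        raise ValueError(f"fill volume must be nonnegative, got {fill_volume}")
    cap = reservoir_capacity(geom)
    if fill_volume > cap * (1 + 1e-12):
        raise ValueError(
            f"fill volume {fill_volume:g} uL exceeds reservoir capacity {cap:g} uL"
        )
    if not pixel_size > 0:
        raise ValueError("pixel size must be positive")

    s_mm2 = fill_volume * 1.0e3 / geom.h  # S = V/h
    r_in = BOSS_DIAMETER_MM / 2.0
    r_fill = math.sqrt(s_mm2 / math.pi + r_in**2)

    px_mm = pixel_size / 1000.0
    half_extent = GROOVE_DIAMETER_MM / 2.0 + 0.5  # mm, small margin
    n = int(math.ceil(2 * half_extent / px_mm))
    coords = (np.arange(n) - (n - 1) / 2.0) * px_mm
    rr = np.hypot(coords[None, :], coords[:, None])
    plasma = (rr >= r_in) & (rr < r_fill) & (rr <= GROOVE_DIAMETER_MM / 2.0)

    img = np.where(plasma, 200.0, 30.0)
    rng = _rng(cfg, 3, frame)
    img = np.clip(img + rng.normal(0.0, 5.0, size=img.shape), 0, 255).astype(np.uint8)
    true_area = float(plasma.sum()) * px_mm**2
    return ReservoirImage(image=img, pixel_size=pixel_size, timestamp=timestamp), true_area


def gen_reservoir_series(
    model: FiltrationModel,
    A: float,
    geom: DeviceGeometry,
    pixel_size: float,
    cfg: SimulationConfig,
) -> tuple[list[ReservoirImage], np.ndarray]:
    """Time-ordered reservoir frames following the filtration law, one per
    sampling interval.  Returns the frames (timestamped in seconds) and the
    noise-free generating volumes (uL)."""
    times_s = np.arange(0.0, cfg.duration * 60.0 + 0.5 * cfg.interval, cfg.interval)
    truth = volume_at_time(model, A, times_s / 60.0)
    frames = [
        gen_reservoir_image(v, geom, pixel_size, cfg, timestamp=t, frame=i)[0]
        for i, (t, v) in enumerate(zip(times_s, truth))
    ]
    return frames, np.asarray(truth)


def gen_cell_count_samples(
    true_residue: float,
    cfg: SimulationConfig,
    n_points: int = 5,
    sample_volume: float = 0.02,
    replicates: int | None = None,
) -> pd.DataFrame:
    """Hemocytometer-style count table for a known residue rate.

    Per sample point, cells ~ Poisson(residue/100 * blood_conc *
    sample_volume).  Returns a tidy table with columns ``replicate``,
    ``sample_point``, ``cells``, ``volume_uL``; the default 5 points x
    3 replicates at 0.02 uL each mirrors the bench counting protocol.
    """
    if not 0.0 <= true_residue <= 100.0:
        raise ValueError(f"residue rate must lie in [0, 100] %, got {true_residue}")
    if n_points < 1 or not sample_volume > 0:
        raise ValueError("need n_points >= 1 and a positive sample volume")
    reps = cfg.replicates if replicates is None else replicates
    rng = _rng(cfg, 4)
    lam = true_residue / 100.0 * cfg.blood_conc * sample_volume
    rows = [
        {
            "replicate": rep,
            "sample_point": pt,
            "cells": int(rng.poisson(lam)),
            "volume_uL": sample_volume,
        }
        for rep in range(reps)
        for pt in range(n_points)
    ]
    return pd.DataFrame(rows)
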