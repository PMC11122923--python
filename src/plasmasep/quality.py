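"""Plasma purity metrics: red-blood-cell residue rate and capture efficiency.

Separated plasma is scored by hemocytometer-style counting: several small
samples are drawn from the plasma, cells are counted per known sample
volume, and the pooled concentration is compared with the red-blood-cell
concentration of the input whole blood.  The residue rate is that
concentration ratio in percent; the capture efficiency is its complement to
100 %.

Whole blood at 48 % hematocrit carries roughly 5e6 red blood cells per uL,
the default reference concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DEFAULT_BLOOD_CONC",
    "CountSample",
    "QualityResult",
    "concentration",
    "residue_rate",
    "capture_efficiency",
    "round_half_up",
]

#: Red-blood-cell concentration of whole blood at ~48 % hematocrit, cells/uL.
DEFAULT_BLOOD_CONC = 5.0e6


@dataclass(frozen=True)
class CountSample:
    """One counting-chamber observation: cells seen in a known volume (uL)."""

    cells_counted: int
    sampled_volume: float

    def __post_init__(self) -> None:
        if self.cells_counted < 0:
            raise ValueError(f"cell count must be nonnegative, got {self.cells_counted}")
        if not self.sampled_volume > 0:
            raise ValueError(f"sampled volume must be positive, got {self.sampled_volume}")


@dataclass(frozen=True)
class QualityResult:
    """Residue rates per replicate (%), their rounded mean (%), and the
    derived capture efficiency (% = 100 - mean residue)."""

    replicate_residue_rates: tuple[float, ...]
    mean_residue_rate: float
    capture_efficiency: float


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero at the given decimal place, matching
    the convention of hand-reported one-decimal percentages."""
    scale = 10.0**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


def concentration(samples: list[CountSample]) -> float:
    """Pooled cell concentration (cells/uL): total cells over total sampled
    volume.  Pooling weights each sample by its volume, so the estimate is
    order-invariant and unbiased for Poisson counting noise."""
    if not samples:
        raise ValueError("need at least one count sample")
    total_cells = sum(s.cells_counted for s in samples)
    total_volume = sum(s.sampled_volume for s in samples)
    return total_cells / total_volume


def residue_rate(plasma_conc: float, blood_conc: float = DEFAULT_BLOOD_CONC) -> float:
    """Red-blood-cell residue rate in percent: 100 * plasma concentration /
    whole-blood concentration.  Scale-invariant in the pair."""
    if not blood_conc > 0:
        raise ValueError(f"blood concentration must be positive, got {blood_conc}")
    if plasma_conc < 0:
        raise ValueError(f"plasma concentration must be nonnegative, got {plasma_conc}")
    return 100.0 * plasma_conc / blood_conc


def capture_efficiency(
    replicate_rates: list[float] | tuple[float, ...], decimals: int = 1
) -> QualityResult:
    """Mean residue rate over replicates and the capture efficiency.

    The mean is rounded half-up to ``decimals`` places and the efficiency is
    100 minus that rounded mean, so the pair is reported consistently (e.g.
    replicate rates 0.202/0.266/0.248 % give 0.2 % residue and 99.8 %
    efficiency at one decimal).
    """
    rates = tuple(float(r) for r in replicate_rates)
    if not rates:
        raise ValueError("need at least one replicate rate")
    for r in rates:
        if not 0.0 <= r <= 100.0:
            raise ValueError(f"residue rate must lie in [0, 100] %, got {r}")
    mean = round_half_up(sum(rates) / len(rates), decimals)
    return QualityResult(
        replicate_residue_rates=rates,
        mean_residue_rate=mean,
        capture_efficiency=round_half_up(100.0 - mean, decimals),
    )
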