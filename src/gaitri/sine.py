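"""Sine-curve simulator for the confusing-factor case studies.

Curves follow a two-harmonic sine model

    k(t) = O + (1 + alpha) * (ROM / C) * [0.5 sin(2 pi (t - tau)/100)
                                          + 0.5 sin(4 pi (t - tau)/100)]

sampled at t = 1..100 (% gait cycle).  C is the peak-to-peak amplitude
of the bracketed term (~1.76), so that with alpha = O = tau = 0 the
curve's range of motion equals the ROM parameter up to discretization.

Four case studies vary exactly one confusing-factor across a group of
five equally spaced curves, six levels each:

* Case 1 — ROM grows 5..60 deg at fixed amplitude fluctuation alpha;
* Case 2 — alpha grows (2.5..15 %ROM) at ROM = 5 deg;
* Case 3 — constant offsets O grow (5..100 %ROM) at ROM = 5 deg;
* Case 4 — time shifts tau grow (up to 5..30 %cycle) at ROM = 5 deg.

The five-curve spacings are fixed by calibration against the published
index values: offsets are symmetric with extremes at the stated +-O,
time shifts span [0, tau_max], and amplitude factors are spaced by the
stated alpha so their extremes reach +-2x the stated value (the
``doubled`` convention; ``stated`` with extremes +-alpha is kept as an
alternative because the published CMC column is only consistent with
that narrower spread).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd

from .indices import compute_all
from .waveform import SINE_GRID_SIZE, Waveform, WaveformGroup, sine_grid

__all__ = [
    "SineParams",
    "CaseLevel",
    "bracket_amplitude",
    "sine_waveform",
    "case_group",
    "run_table3",
    "LEVELS",
    "TABLE1",
]

AlphaConvention = Literal["doubled", "stated"]

LEVELS = ("I", "II", "III", "IV", "V", "VI")

#: Case-study parameter grid: per level (ROM deg, alpha stated fraction,
#: offset stated %ROM, tau_max %cycle).
TABLE1: dict[tuple[int, str], tuple[float, float, float, float]] = {}
for _i, _lvl in enumerate(LEVELS):
    TABLE1[(1, _lvl)] = ([5, 15, 30, 40, 50, 60][_i], 0.025, 0.0, 0.0)
    TABLE1[(2, _lvl)] = (5.0, 0.025 * (_i + 1), 0.0, 0.0)
    TABLE1[(3, _lvl)] = (5.0, 0.0, [5, 20, 40, 60, 80, 100][_i], 0.0)
    TABLE1[(4, _lvl)] = (5.0, 0.0, 0.0, 5.0 * (_i + 1))

OFFSET_SPACING = (-1.0, -0.5, 0.0, 0.5, 1.0)
TAU_SPACING = (0.0, 0.25, 0.5, 0.75, 1.0)
ALPHA_SPACING = {
    "doubled": (-2.0, -1.0, 0.0, 1.0, 2.0),
    "stated": (-1.0, -0.5, 0.0, 0.5, 1.0),
}


def _bracket(x: np.ndarray) -> np.ndarray:
    """0.5 sin(2 pi x) + 0.5 sin(4 pi x) with x the cycle fraction."""
    return 0.5 * np.sin(2 * np.pi * x) + 0.5 * np.sin(4 * np.pi * x)


@lru_cache(maxsize=1)
def bracket_amplitude() -> float:
    """Peak-to-peak amplitude of the two-harmonic bracket (~1.76018).

    Evaluated on a dense cycle grid; quadratic behaviour at the extrema
    makes the result accurate far beyond the needs of degree-scale
    curves.
    """
    x = np.linspace(0.0, 1.0, 2_000_001)
    b = _bracket(x)
    return float(b.max() - b.min())


@dataclass(frozen=True)
class SineParams:
    """Parameters of one simulated curve.

    rom: peak-to-peak amplitude to impose, degrees.
    alpha: fractional amplitude fluctuation (0.05 = +5%).
    offset: constant offset O, degrees.
    tau: time shift, % of the gait cycle (continuous phase shift).
    grid_size: number of samples on the t = 1..T grid.
    """

    rom: float
    alpha: float = 0.0
    offset: float = 0.0
    tau: float = 0.0
    grid_size: int = SINE_GRID_SIZE

    def __post_init__(self) -> None:
        if self.rom <= 0:
            raise ValueError("rom must be positive")
        if self.grid_size < 3:
            raise ValueError("grid_size must be at least 3")


@dataclass(frozen=True)
class CaseLevel:
    case_id: int
    level: str
    rom: float
    alpha_stated: float
    offset_pct_rom: float
    tau_max: float


def describe_level(case_id: int, level: str) -> CaseLevel:
    try:
        rom, alpha, off, tau = TABLE1[(case_id, level)]
    except KeyError:
        raise ValueError(f"unknown case/level ({case_id}, {level})") from None
    return CaseLevel(case_id, level, rom, alpha, off, tau)


def sine_waveform(params: SineParams) -> Waveform:
    """Evaluate the sine model on the t = 1..T grid."""
    t = np.arange(1, params.grid_size + 1, dtype=float) * (
        100.0 / params.grid_size
    )
    shape = _bracket((t - params.tau) / 100.0)
    values = params.offset + (1.0 + params.alpha) * (
        params.rom / bracket_amplitude()
    ) * shape
    return Waveform(values, sine_grid(params.grid_size))


def case_group(
    case_id: int,
    level: str,
    alpha_convention: AlphaConvention = "doubled",
) -> WaveformGroup:
    """Five-curve group for one case/level of the parameter grid."""
    spec = describe_level(case_id, level)
    if alpha_convention not in ALPHA_SPACING:
        raise ValueError(f"unknown alpha convention {alpha_convention!r}")
    curves = []
    if case_id in (1, 2):
        for s in ALPHA_SPACING[alpha_convention]:
            curves.append(
                sine_waveform(
                    SineParams(spec.rom, alpha=spec.alpha_stated * s)
                )
            )
    elif case_id == 3:
        omax = spec.offset_pct_rom / 100.0 * spec.rom
        for s in OFFSET_SPACING:
            curves.append(sine_waveform(SineParams(spec.rom, offset=omax * s)))
    else:  # case 4
        for s in TAU_SPACING:
            curves.append(sine_waveform(SineParams(spec.rom, tau=spec.tau_max * s)))
    labels = tuple(f"case{case_id}_{level}_{j + 1}" for j in range(5))
    return WaveformGroup(tuple(curves), labels)


def run_table3(
    alpha_convention: AlphaConvention = "doubled",
) -> pd.DataFrame:
    """Index values for the full 4-case x 6-level sine grid.

    Returns one row per case/level with full-precision index values;
    ``cmc`` is NaN where the index is undefined (negative radicand).
    """
    rows = []
    for case_id in (1, 2, 3, 4):
        for level in LEVELS:
            group = case_group(case_id, level, alpha_convention)
            rep = compute_all(group)
            rows.append(
                {
                    "case": case_id,
                    "level": level,
                    "cmc": rep.cmc.value if rep.cmc.defined else np.nan,
                    "cmc_defined": rep.cmc.defined,
                    "a1_mean": rep.lfm.a1_mean,
                    "a1_sd": rep.lfm.a1_sd,
                    "a0_mean": rep.lfm.a0_mean,
                    "a0_sd": rep.lfm.a0_sd,
                    "r2_mean": rep.lfm.r2_mean,
                    "r2_sd": rep.lfm.r2_sd,
                    "mav": rep.mav,
                    "rmsd_mean": rep.rmsd_mean,
                    "rmsd_sd": rep.rmsd_sd,
                }
            )
    return pd.DataFrame(rows)
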