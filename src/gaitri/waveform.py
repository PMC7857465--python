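"""Core waveform containers and plain-CSV I/O.

A joint-angle waveform is one gait cycle of a sagittal joint angle
(degrees), time-normalized to 0-100% of the cycle and sampled on a
uniform grid.  Two canonical grids coexist in this package:

* the sine simulator samples ``t = 1..100`` (100 points, no duplicated
  endpoint), and
* the Fourier reconstruction samples ``t = 0..100`` (101 points,
  duplicated endpoint for a cyclic curve).

Index computations are grid-agnostic; only the generators care which
convention they are on, so :class:`Waveform` stores its percent grid
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "WaveformGroup",
    "sine_grid",
    "fourier_grid",
    "resample_to_grid",
    "rom",
    "mean_waveform",
    "read_waveform_group",
    "write_waveform_group",
]

#: Grid size used by the sine-curve simulator (t = 1..100).
SINE_GRID_SIZE = 100
#: Grid size used by the Fourier reconstruction (t = 0..100).
FOURIER_GRID_SIZE = 101


def sine_grid(grid_size: int = SINE_GRID_SIZE) -> np.ndarray:
    """Percent grid ``t = 1..T`` scaled to one cycle (100/T .. 100)."""
    return np.arange(1, grid_size + 1, dtype=float) * (100.0 / grid_size)


def fourier_grid(grid_size: int = FOURIER_GRID_SIZE) -> np.ndarray:
    """Percent grid spanning 0..100 inclusive with ``grid_size`` points."""
    return np.linspace(0.0, 100.0, grid_size)


def _check_uniform(percent: np.ndarray) -> None:
    if percent.ndim != 1 or percent.size < 3:
        raise ValueError("waveform needs at least 3 samples")
    steps = np.diff(percent)
    if np.any(steps <= 0):
        raise ValueError("percent grid must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-9):
        raise ValueError("percent grid must be uniform")


@dataclass(frozen=True)
class Waveform:
    """One time-normalized joint-angle curve (degrees) on a uniform grid."""

    values: np.ndarray
    percent: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        percent = np.asarray(self.percent, dtype=float)
        if values.shape != percent.shape:
            raise ValueError("values and percent must have the same length")
        if not np.all(np.isfinite(values)):
            raise ValueError("waveform samples must be finite")
        _check_uniform(percent)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "percent", percent)

    @property
    def grid_size(self) -> int:
        return self.values.size

    def shifted(self, offset: float) -> "Waveform":
        """Return the curve with a constant angular offset added."""
        return Waveform(self.values + offset, self.percent)


@dataclass(frozen=True)
class WaveformGroup:
    """M >= 2 waveforms on one shared grid (the curves an index compares)."""

    curves: tuple[Waveform, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        curves = tuple(self.curves)
        if len(curves) < 2:
            raise ValueError("need at least 2 curves")
        ref = curves[0].percent
        for c in curves[1:]:
            if c.grid_size != ref.size or not np.allclose(c.percent, ref):
                raise ValueError("all curves must share one grid")
        labels = tuple(self.labels) if self.labels else tuple(
            f"curve_{j + 1}" for j in range(len(curves))
        )
        if len(labels) != len(curves):
            raise ValueError("one label per curve required")
        object.__setattr__(self, "curves", curves)
        object.__setattr__(self, "labels", labels)

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def grid_size(self) -> int:
        return self.curves[0].grid_size

    @property
    def percent(self) -> np.ndarray:
        return self.curves[0].percent

    def matrix(self) -> np.ndarray:
        """The (M, T) matrix Y with Y[j, t] the j-th curve's t-th sample."""
        return np.vstack([c.values for c in self.curves])

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        percent: np.ndarray,
        labels: Sequence[str] = (),
    ) -> "WaveformGroup":
        matrix = np.asarray(matrix, dtype=float)
        return cls(
            tuple(Waveform(row, percent) for row in matrix), tuple(labels)
        )


def resample_to_grid(
    percent: np.ndarray, values: np.ndarray, grid_size: int
) -> Waveform:
    """Linearly interpolate (percent, angle) samples onto a uniform grid.

    The target grid spans 0..100% with ``grid_size`` points; query points
    outside the provided percent range are clamped to the nearest sample.
    """
    percent = np.asarray(percent, dtype=float)
    values = np.asarray(values, dtype=float)
    if percent.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if np.any(np.diff(percent) <= 0):
        raise ValueError("percent values must be strictly increasing")
    if percent[0] < 0.0 or percent[-1] > 100.0:
        raise ValueError("percent values must lie within [0, 100]")
    target = fourier_grid(grid_size)
    return Waveform(np.interp(target, percent, values), target)


def rom(curve: Waveform) -> float:
    """Range of motion: peak-to-peak excursion of the curve, in degrees."""
    return float(curve.values.max() - curve.values.min())


def mean_waveform(group: WaveformGroup) -> Waveform:
    """Pointwise arithmetic mean across curves (the reference curve)."""
    return Waveform(group.matrix().mean(axis=0), group.percent)


def read_waveform_group(
    path: str | Path, grid_size: int | None = None
) -> WaveformGroup:
    """Read a curve group from CSV.

    The file has a header row, a first ``pct_gait_cycle`` column and one
    column of angles (degrees) per curve.  With ``grid_size=None`` the
    file's own (uniform) grid is kept, so write/read round-trips are
    sample-exact; pass an integer to resample onto a uniform 0-100% grid
    of that many points.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ValueError(f"malformed curve CSV {path}: {exc}") from exc
    if frame.shape[1] < 3:
        raise ValueError("need at least 2 curves (3 CSV columns)")
    data = frame.apply(pd.to_numeric, errors="coerce")
    if data.isna().any().any():
        raise ValueError(f"non-numeric cells in curve CSV {path}")
    percent = data.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(percent) <= 0):
        raise ValueError("percent column must be strictly increasing")
    labels = [str(c) for c in frame.columns[1:]]
    if grid_size is None:
        curves = tuple(
            Waveform(data.iloc[:, k].to_numpy(dtype=float), percent)
            for k in range(1, data.shape[1])
        )
    else:
        curves = tuple(
            resample_to_grid(
                percent, data.iloc[:, k].to_numpy(dtype=float), grid_size
            )
            for k in range(1, data.shape[1])
        )
    return WaveformGroup(curves, tuple(labels))


def write_waveform_group(group: WaveformGroup, path: str | Path) -> None:
    """Write a group as CSV in the layout read_waveform_group expects."""
    frame = pd.DataFrame({"pct_gait_cycle": group.percent})
    for label, curve in zip(group.labels, group.curves):
        frame[label] = curve.values
    frame.to_csv(path, index=False, float_format="%.12g")
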