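"""Fourier model of a mean gait curve, with perturbation operators.

A cyclic joint-angle curve over t = 0..100 %cycle is represented as

    y(t) = A0/2 + sum_{k=1..n} [ Ak cos(2 pi k t / 100)
                               + Bk sin(2 pi k t / 100) ]

fitted by linear least squares on the sampled grid.  The decomposition
order n is the smallest one whose reconstruction RMSE drops below a
tolerance (default 0.01 deg, i.e. 1/100 of the 1-deg precision of a
typical optical gait measurement chain).

The three confusing-factors act directly on the coefficients:

* amplitude fluctuation alpha scales every harmonic pair by (1+alpha);
* a constant offset O adds 2*O to A0;
* a time shift tau rotates each pair by k * 2 pi tau / 100, which for a
  band-limited curve is identical to circularly shifting it in time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .waveform import Waveform, WaveformGroup, fourier_grid

__all__ = ["FourierModel", "FourierFitError", "fit_fourier", "reconstruct", "perturb"]


class FourierFitError(ValueError):
    """Raised when the stopping tolerance is unreachable on a grid."""

    def __init__(self, message: str, best_rmse: float):
        super().__init__(message)
        self.best_rmse = best_rmse


@dataclass(frozen=True)
class FourierModel:
    """Coefficients (A0, (Ak, Bk)) of the cyclic model, degrees.

    ``a0`` stores A0 (the constant contribution is A0/2).  ``rmse`` is
    the reconstruction RMSE recorded by the fit, None for hand-built
    models.
    """

    a0: float
    harmonics: tuple[tuple[float, float], ...]
    period: float = 100.0
    rmse: float | None = None

    def __post_init__(self) -> None:
        if len(self.harmonics) < 1:
            raise ValueError("model needs at least one harmonic")
        coeffs = np.asarray(self.harmonics, dtype=float)
        if coeffs.ndim != 2 or coeffs.shape[1] != 2:
            raise ValueError("harmonics must be (Ak, Bk) pairs")
        if not (np.isfinite(self.a0) and np.all(np.isfinite(coeffs))):
            raise ValueError("coefficients must be finite")
        object.__setattr__(
            self, "harmonics", tuple((float(a), float(b)) for a, b in coeffs)
        )

    @property
    def order(self) -> int:
        return len(self.harmonics)

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "harmonics": [list(h) for h in self.harmonics],
            "period": self.period,
            "rmse": self.rmse,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FourierModel":
        return cls(
            a0=float(payload["a0"]),
            harmonics=tuple(tuple(h) for h in payload["harmonics"]),
            period=float(payload.get("period", 100.0)),
            rmse=payload.get("rmse"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FourierModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _design_matrix(t: np.ndarray, n: int, period: float) -> np.ndarray:
    cols = [np.full(t.size, 0.5)]
    for k in range(1, n + 1):
        w = 2.0 * np.pi * k * t / period
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def fit_fourier(curve: Waveform, tol: float = 0.01) -> FourierModel:
    """Least-squares Fourier fit with the RMSE stopping rule.

    The order n is increased from 1 until the reconstruction RMSE on the
    curve's own grid falls below ``tol`` (degrees).  Raises
    :class:`FourierFitError` if the Nyquist order of the grid cannot
    reach the tolerance.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    t = curve.percent
    y = curve.values
    n_max = (curve.grid_size - 1) // 2
    best_rmse = np.inf
    for n in range(1, n_max + 1):
        X = _design_matrix(t, n, 100.0)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rmse = float(np.sqrt(np.mean((X @ beta - y) ** 2)))
        best_rmse = min(best_rmse, rmse)
        if rmse < tol:
            harmonics = tuple(
                (float(beta[1 + 2 * k]), float(beta[2 + 2 * k]))
                for k in range(n)
            )
            return FourierModel(float(beta[0]), harmonics, 100.0, rmse)
    raise FourierFitError(
        f"tolerance {tol} deg unreachable at order {n_max} "
        f"(best RMSE {best_rmse:.4g} deg)",
        best_rmse,
    )


def reconstruct(model: FourierModel, grid_size: int = 101) -> Waveform:
    """Evaluate the model on a uniform 0..100% grid of ``grid_size`` points."""
    if grid_size < 3:
        raise ValueError("grid_size must be at least 3")
    t = fourier_grid(grid_size)
    y = np.full(t.size, model.a0 / 2.0)
    for k, (ak, bk) in enumerate(model.harmonics, start=1):
        w = 2.0 * np.pi * k * t / model.period
        y = y + ak * np.cos(w) + bk * np.sin(w)
    return Waveform(y, t)


def perturb(
    model: FourierModel,
    alpha: float = 0.0,
    offset: float = 0.0,
    tau: float = 0.0,
) -> FourierModel:
    """Apply amplitude, offset and time-shift perturbations in coefficient space.

    alpha scales every harmonic pair by (1 + alpha); offset (degrees)
    adds 2*offset to A0; tau (% cycle) rotates pair k by k*theta with
    theta = 2 pi tau / period, the coefficient-space equivalent of the
    circular shift t -> t - tau.
    """
    theta = 2.0 * np.pi * tau / model.period
    scale = 1.0 + alpha
    harmonics = []
    for k, (ak, bk) in enumerate(model.harmonics, start=1):
        c, s = np.cos(k * theta), np.sin(k * theta)
        harmonics.append(
            (scale * (ak * c - bk * s), scale * (ak * s + bk * c))
        )
    return replace(
        model,
        a0=model.a0 + 2.0 * offset,
        harmonics=tuple(harmonics),
        rmse=None,
    )
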