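"""Waveform repeatability/reproducibility indices: RMSD, MAV, CMC, LFM.

All four indices compare M time-normalized curves sampled on a common
grid (the matrix ``Y[j, t]``, j = 1..M curves, t = 1..T samples):

* RMSD_j — per-curve root mean square deviation from the pointwise mean
  curve, summarized as sample mean +- SD over curves.
* MAV — mean over the cycle of the per-sample range (max - min) across
  curves.
* CMC — square root of the adjusted coefficient of multiple
  determination.  Its radicand can be negative when the within-frame
  variance exceeds the variance about the grand mean, in which case the
  index is undefined (classically reported as "complex").
* LFM — per-curve ordinary least squares against the mean curve,
  yielding a scale a1, an intercept a0 (degrees) and R^2, each
  summarized over curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import WaveformGroup, mean_waveform

__all__ = [
    "CMCResult",
    "LFMResult",
    "IndexReport",
    "compute_rmsd",
    "compute_mav",
    "compute_cmc",
    "classify_cmc",
    "compute_lfm",
    "compute_all",
]

#: Similarity strata for a defined CMC value, lower bound inclusive.
CMC_STRATA: tuple[tuple[float, str], ...] = (
    (0.95, "excellent"),
    (0.85, "very good"),
    (0.75, "good"),
    (0.60, "moderate"),
    (0.00, "poor"),
)


@dataclass(frozen=True)
class CMCResult:
    """CMC value with its radicand kept as a diagnostic.

    ``defined`` is False when the radicand is negative (the classical
    "complex CMC") or when the group is degenerate (zero total
    variance); the value is then None and reports render it as "–".
    """

    value: float | None
    defined: bool
    radicand: float
    reason: str | None = None


@dataclass(frozen=True)
class LFMResult:
    per_curve: tuple[tuple[float, float, float], ...]  # (a1, a0, r2)
    a1_mean: float
    a1_sd: float
    a0_mean: float
    a0_sd: float
    r2_mean: float
    r2_sd: float
    #: linearity considered meaningful when mean R^2 exceeds 0.5
    linear_assumption_valid: bool


@dataclass(frozen=True)
class IndexReport:
    cmc: CMCResult
    mav: float
    rmsd_per_curve: tuple[float, ...]
    rmsd_mean: float
    rmsd_sd: float
    lfm: LFMResult


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    """Sample mean and sample SD (denominator M - 1)."""
    return float(np.mean(values)), float(np.std(values, ddof=1))


def compute_rmsd(
    group: WaveformGroup,
) -> tuple[tuple[float, ...], float, float]:
    """Per-curve RMSD versus the group-mean curve, plus mean and SD.

    RMSD_j = sqrt( (1/T) * sum_t (Y_jt - Ybar_t)^2 ).
    """
    Y = group.matrix()
    dev = Y - Y.mean(axis=0)
    per_curve = np.sqrt((dev**2).mean(axis=1))
    mean, sd = _mean_sd(per_curve)
    return tuple(float(r) for r in per_curve), mean, sd


def compute_mav(group: WaveformGroup) -> float:
    """Mean absolute variability: cycle-average of the per-sample range."""
    Y = group.matrix()
    return float((Y.max(axis=0) - Y.min(axis=0)).mean())


def compute_cmc(group: WaveformGroup) -> CMCResult:
    """Coefficient of multiple correlation.

    radicand = 1 - [ sum_jt (Y_jt - Ybar_t)^2 / (T (M-1)) ]
                 / [ sum_jt (Y_jt - Ybar)^2  / (M T - 1) ]

    with Ybar_t the per-sample mean over curves and Ybar the grand mean
    over all samples of all curves.
    """
    Y = group.matrix()
    M, T = Y.shape
    within = ((Y - Y.mean(axis=0)) ** 2).sum() / (T * (M - 1))
    total = ((Y - Y.mean()) ** 2).sum() / (M * T - 1)
    if total == 0.0:
        return CMCResult(None, False, float("nan"), reason="degenerate")
    radicand = 1.0 - within / total
    if radicand < 0.0:
        return CMCResult(None, False, radicand, reason="negative radicand")
    return CMCResult(float(np.sqrt(radicand)), True, radicand)


def classify_cmc(value: float) -> str:
    """Similarity stratum of a defined CMC value.

    poor [0, 0.60) < moderate [0.60, 0.75) < good [0.75, 0.85)
    < very good [0.85, 0.95) < excellent [0.95, 1].
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"CMC value {value!r} outside [0, 1]")
    for lower, label in CMC_STRATA:
        if value >= lower:
            return label
    return "poor"  # pragma: no cover - value 0 caught above


def compute_lfm(group: WaveformGroup) -> LFMResult:
    """Linear fit method: OLS of each curve on the group-mean curve.

    For curve j against reference m: a1_j = cov(m, Y_j)/var(m),
    a0_j = mean(Y_j) - a1_j * mean(m), R^2_j = squared Pearson
    correlation (the OLS coefficient of determination for a simple
    regression with intercept).
    """
    Y = group.matrix()
    m = mean_waveform(group).values
    m_centered = m - m.mean()
    var_m = float(m_centered @ m_centered)
    if var_m == 0.0:
        raise ValueError("degenerate reference: group-mean curve is constant")
    per_curve = []
    for y in Y:
        y_centered = y - y.mean()
        cov = float(m_centered @ y_centered)
        a1 = cov / var_m
        a0 = float(y.mean() - a1 * m.mean())
        var_y = float(y_centered @ y_centered)
        r2 = 0.0 if var_y == 0.0 else cov**2 / (var_m * var_y)
        per_curve.append((a1, a0, r2))
    arr = np.asarray(per_curve)
    a1_mean, a1_sd = _mean_sd(arr[:, 0])
    a0_mean, a0_sd = _mean_sd(arr[:, 1])
    r2_mean, r2_sd = _mean_sd(arr[:, 2])
    return LFMResult(
        per_curve=tuple((float(a), float(b), float(c)) for a, b, c in per_curve),
        a1_mean=a1_mean,
        a1_sd=a1_sd,
        a0_mean=a0_mean,
        a0_sd=a0_sd,
        r2_mean=r2_mean,
        r2_sd=r2_sd,
        linear_assumption_valid=r2_mean > 0.5,
    )


def compute_all(group: WaveformGroup) -> IndexReport:
    """All four indices of one curve group in a single report."""
    per_curve, rmsd_mean, rmsd_sd = compute_rmsd(group)
    return IndexReport(
        cmc=compute_cmc(group),
        mav=compute_mav(group),
        rmsd_per_curve=per_curve,
        rmsd_mean=rmsd_mean,
        rmsd_sd=rmsd_sd,
        lfm=compute_lfm(group),
    )
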