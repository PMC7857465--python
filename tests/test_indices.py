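import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitri import (
    WaveformGroup,
    classify_cmc,
    compute_all,
    compute_cmc,
    compute_lfm,
    compute_mav,
    compute_rmsd,
)
from gaitri.waveform import fourier_grid

from conftest import random_group


# ---------------------------------------------------------------- oracles

def oracle_cmc_radicand(Y):
    """Explicit double-loop evaluation of the CMC radicand."""
    M, T = Y.shape
    grand = sum(Y[j, t] for j in range(M) for t in range(T)) / (M * T)
    num = den = 0.0
    for t in range(T):
        col_mean = sum(Y[j, t] for j in range(M)) / M
        for j in range(M):
            num += (Y[j, t] - col_mean) ** 2
            den += (Y[j, t] - grand) ** 2
    return 1.0 - (num / (T * (M - 1))) / (den / (M * T - 1))


def oracle_rmsd(Y):
    M, T = Y.shape
    out = []
    for j in range(M):
        acc = 0.0
        for t in range(T):
            col_mean = sum(Y[i, t] for i in range(M)) / M
            acc += (Y[j, t] - col_mean) ** 2
        out.append(math.sqrt(acc / T))
    return out


def oracle_mav(Y):
    M, T = Y.shape
    return sum(
        max(Y[j, t] for j in range(M)) - min(Y[j, t] for j in range(M))
        for t in range(T)
    ) / T


def oracle_lfm(Y):
    """Per-curve OLS against the column-mean reference via polyfit."""
    m = Y.mean(axis=0)
    rows = []
    for y in Y:
        a1, a0 = np.polyfit(m, y, 1)
        r = np.corrcoef(m, y)[0, 1]
        rows.append((a1, a0, r**2))
    return rows


def test_indices_match_brute_force_oracles_on_random_groups(rng):
    for _ in range(100):
        group = random_group(rng)
        Y = group.matrix()
        assert compute_cmc(group).radicand == pytest.approx(
            oracle_cmc_radicand(Y), rel=1e-10
        )
        per_curve, _, _ = compute_rmsd(group)
        np.testing.assert_allclose(per_curve, oracle_rmsd(Y), rtol=1e-10)
        assert compute_mav(group) == pytest.approx(oracle_mav(Y), rel=1e-10)
        np.testing.assert_allclose(
            np.asarray(compute_lfm(group).per_curve),
            np.asarray(oracle_lfm(Y)),
            rtol=1e-8, atol=1e-10,
        )


# ----------------------------------------------------------- index basics

@pytest.fixture()
def identical_group():
    grid = fourier_grid(20)
    curve = np.sin(2 * np.pi * grid / 100) * 10
    return WaveformGroup.from_matrix(np.tile(curve, (5, 1)), grid)


def test_identical_curves_are_perfectly_similar(identical_group):
    report = compute_all(identical_group)
    assert report.cmc.defined and report.cmc.value == pytest.approx(1.0)
    assert report.mav == 0.0
    assert report.rmsd_mean == pytest.approx(0.0, abs=1e-12)
    assert report.rmsd_sd == pytest.approx(0.0, abs=1e-12)
    for a1, a0, r2 in report.lfm.per_curve:
        assert (a1, a0, r2) == (pytest.approx(1.0), pytest.approx(0.0),
                                pytest.approx(1.0))


def test_constant_curve_pairs():
    grid = fourier_grid(10)
    g = WaveformGroup.from_matrix(
        np.vstack([np.full(10, 3.0), np.full(10, -3.0)]), grid
    )
    per_curve, mean, sd = compute_rmsd(g)
    assert per_curve == (pytest.approx(3.0), pytest.approx(3.0))
    assert sd == pytest.approx(0.0)
    assert compute_mav(g) == pytest.approx(6.0)
    # all samples of all curves equal -> zero total variance
    flat = WaveformGroup.from_matrix(np.zeros((3, 10)), grid)
    result = compute_cmc(flat)
    assert not result.defined and result.reason == "degenerate"
    with pytest.raises(ValueError, match="degenerate reference"):
        compute_lfm(flat)


def test_negative_radicand_flags_undefined(rng):
    # large distinct offsets on a nearly flat shape push the within-frame
    # variance above the variance about the grand mean
    grid = fourier_grid(50)
    shape = 0.1 * np.sin(2 * np.pi * grid / 100)
    offsets = np.array([-6.0, -3.0, 0.0, 3.0, 6.0])
    g = WaveformGroup.from_matrix(shape + offsets[:, None], grid)
    result = compute_cmc(g)
    assert not result.defined
    assert result.radicand < 0
    assert result.value is None


@pytest.mark.parametrize(
    "value,label",
    [
        (0.0, "poor"), (0.50, "poor"), (0.60, "moderate"), (0.74, "moderate"),
        (0.75, "good"), (0.85, "very good"), (0.87, "very good"),
        (0.95, "excellent"), (1.0, "excellent"),
    ],
)
def test_cmc_strata(value, label):
    assert classify_cmc(value) == label


def test_cmc_strata_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_cmc(1.2)
    with pytest.raises(ValueError):
        classify_cmc(-0.1)


def test_compute_all_consistent_with_individual_indices(rng):
    group = random_group(rng, m=4, t=15)
    report = compute_all(group)
    assert report.cmc == compute_cmc(group)
    assert report.mav == compute_mav(group)
    assert report.rmsd_per_curve == compute_rmsd(group)[0]
    assert report.lfm == compute_lfm(group)


# ------------------------------------------------- invariance properties

@settings(max_examples=30, derandomize=True)
@given(
    c=st.floats(-50, 50, allow_nan=False),
    seed=st.integers(0, 2**16),
)
def test_common_offset_invariance(c, seed):
    """Adding one constant to every curve leaves CMC, MAV, RMSD, a1 and
    R^2 unchanged; intercepts move by c*(1 - a1)."""
    rng = np.random.default_rng(seed)
    group = random_group(rng, m=4, t=12)
    shifted = WaveformGroup.from_matrix(group.matrix() + c, group.percent)
    assert compute_cmc(shifted).radicand == pytest.approx(
        compute_cmc(group).radicand, rel=1e-9, abs=1e-9
    )
    assert compute_mav(shifted) == pytest.approx(compute_mav(group), rel=1e-9)
    np.testing.assert_allclose(
        compute_rmsd(shifted)[0], compute_rmsd(group)[0], rtol=1e-9
    )
    base, moved = compute_lfm(group), compute_lfm(shifted)
    for (a1, a0, r2), (b1, b0, s2) in zip(base.per_curve, moved.per_curve):
        assert b1 == pytest.approx(a1, rel=1e-9)
        assert s2 == pytest.approx(r2, rel=1e-9)
        assert b0 == pytest.approx(a0 + c * (1 - a1), rel=1e-7, abs=1e-7)


@settings(max_examples=30, derandomize=True)
@given(
    s=st.floats(0.01, 40, allow_nan=False),
    seed=st.integers(0, 2**16),
)
def test_positive_scaling_equivariance(s, seed):
    """Scaling all curves by s > 0 preserves CMC, a1 and R^2 and scales
    MAV, RMSD and a0 by s."""
    rng = np.random.default_rng(seed)
    group = random_group(rng, m=3, t=14)
    scaled = WaveformGroup.from_matrix(group.matrix() * s, group.percent)
    assert compute_cmc(scaled).radicand == pytest.approx(
        compute_cmc(group).radicand, rel=1e-9, abs=1e-9
    )
    assert compute_mav(scaled) == pytest.approx(
        s * compute_mav(group), rel=1e-9
    )
    np.testing.assert_allclose(
        compute_rmsd(scaled)[0],
        s * np.asarray(compute_rmsd(group)[0]),
        rtol=1e-9,
    )
    base, mult = compute_lfm(group), compute_lfm(scaled)
    for (a1, a0, r2), (b1, b0, s2) in zip(base.per_curve, mult.per_curve):
        assert b1 == pytest.approx(a1, rel=1e-9)
        assert s2 == pytest.approx(r2, rel=1e-9)
        assert b0 == pytest.approx(s * a0, rel=1e-7, abs=1e-9)
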