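"""Monte Carlo engine for index behaviour on Fourier-based gait data.

Each simulation draws a five-stride group — from one subject template
(within-subject, WS) or five distinct templates (between-subject, BS) —
perturbs it with uniform amplitude/offset/time-shift draws, and
computes all four indices.  Summaries follow a two-level aggregation:

* CMC and MAV: mean and SD across simulations (undefined CMC draws are
  excluded and counted);
* LFM coefficients and RMSD: mean and SD across the five curves of each
  group first, then the across-simulation average of those means and of
  those SDs;
* ROM: mean and SD across simulations of the group-mean curve's range
  of motion.

Default perturbation ranges are the within-/between-subject ranges
typical of repeated treadmill gait sessions in healthy adults (WS:
alpha 5 %ROM, O 5 %ROM, tau 5 %cycle for every joint; BS: hip 10/30/10,
knee 5/15/10, ankle 10/20/10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .indices import compute_all
from .synthetic import PopulationSpec, builtin_population, generate_group, sample_subject
from .waveform import mean_waveform, rom

__all__ = [
    "PerturbationRanges",
    "MCConfig",
    "MCSummary",
    "run_simulation",
    "run_table4",
    "TABLE2_RANGES",
]

logger = logging.getLogger(__name__)

Mode = Literal["WS", "BS"]
FACTORS = ("alpha", "offset", "tau")

#: Default maximum perturbation ranges per (joint, mode):
#: (alpha %ROM, offset %ROM, tau %cycle).
TABLE2_RANGES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("hip", "WS"): (5.0, 5.0, 5.0),
    ("hip", "BS"): (10.0, 30.0, 10.0),
    ("knee", "WS"): (5.0, 5.0, 5.0),
    ("knee", "BS"): (5.0, 15.0, 10.0),
    ("ankle", "WS"): (5.0, 5.0, 5.0),
    ("ankle", "BS"): (10.0, 20.0, 10.0),
}


@dataclass(frozen=True)
class PerturbationRanges:
    """Maximum uniform perturbation ranges for one joint/mode."""

    alpha_max: float  # %ROM
    offset_max: float  # %ROM
    tau_max: float  # %cycle
    mode: Mode = "WS"

    def __post_init__(self) -> None:
        if min(self.alpha_max, self.offset_max, self.tau_max) < 0:
            raise ValueError("ranges must be non-negative")

    @classmethod
    def for_joint(cls, joint: str, mode: Mode) -> "PerturbationRanges":
        try:
            a, o, t = TABLE2_RANGES[(joint, mode)]
        except KeyError:
            raise ValueError(f"no default ranges for ({joint!r}, {mode!r})") from None
        return cls(a, o, t, mode)

    def restricted_to(self, factors: Iterable[str]) -> "PerturbationRanges":
        """Zero every factor outside ``factors``."""
        active = set(factors)
        unknown = active - set(FACTORS)
        if unknown:
            raise ValueError(f"unknown factors {sorted(unknown)}")
        return replace(
            self,
            alpha_max=self.alpha_max if "alpha" in active else 0.0,
            offset_max=self.offset_max if "offset" in active else 0.0,
            tau_max=self.tau_max if "tau" in active else 0.0,
        )


@dataclass(frozen=True)
class MCConfig:
    """One Monte Carlo run: joint, WS/BS mode, active factors, sizes."""

    joint: str
    mode: Mode = "WS"
    factors: tuple[str, ...] | str = "mixed"
    n_sim: int = 1000
    group_size: int = 5
    seed: int = 0
    ranges: PerturbationRanges | None = None  # defaults to joint/mode table

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be at least 1")
        if self.group_size < 2:
            raise ValueError("group_size must be at least 2")

    def active_ranges(self) -> PerturbationRanges:
        base = self.ranges or PerturbationRanges.for_joint(self.joint, self.mode)
        if self.factors == "mixed":
            return base
        return base.restricted_to(self.factors)


@dataclass(frozen=True)
class MCSummary:
    """Two-level aggregated index statistics over n_sim simulations."""

    n_sim: int
    rom_mean: float
    rom_sd: float
    cmc_mean: float
    cmc_sd: float
    mav_mean: float
    mav_sd: float
    a1_mean_of_means: float
    a1_mean_of_sds: float
    a0_mean_of_means: float
    a0_mean_of_sds: float
    r2_mean_of_means: float
    r2_mean_of_sds: float
    rmsd_mean_of_means: float
    rmsd_mean_of_sds: float
    n_undefined_cmc: int


def _sd(values: np.ndarray) -> float:
    """Across-simulation sample SD; 0 for a single simulation."""
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def run_simulation(
    config: MCConfig, population: PopulationSpec | None = None
) -> MCSummary:
    """Run one Monte Carlo block and aggregate it.

    Deterministic given ``config.seed``.  Per simulation: subject
    template draws (one for WS, ``group_size`` for BS), then the group
    generation draws.
    """
    population = population or builtin_population()
    ranges = config.active_ranges()
    rng = np.random.default_rng(config.seed)
    logger.info(
        "MC run: joint=%s mode=%s factors=%s n_sim=%d M=%d seed=%d ranges=%s",
        config.joint, config.mode, config.factors, config.n_sim,
        config.group_size, config.seed, ranges,
    )
    cmcs, mavs, roms = [], [], []
    a1_m, a1_s, a0_m, a0_s, r2_m, r2_s, rmsd_m, rmsd_s = ([] for _ in range(8))
    n_undefined = 0
    for _ in range(config.n_sim):
        if config.mode == "WS":
            templates = sample_subject(config.joint, rng, population)
        else:
            templates = [
                sample_subject(config.joint, rng, population)
                for _ in range(config.group_size)
            ]
        generated = generate_group(templates, ranges, config.group_size, rng)
        report = compute_all(generated.group)
        if report.cmc.defined:
            cmcs.append(report.cmc.value)
        else:
            n_undefined += 1
        mavs.append(report.mav)
        roms.append(rom(mean_waveform(generated.group)))
        a1_m.append(report.lfm.a1_mean)
        a1_s.append(report.lfm.a1_sd)
        a0_m.append(report.lfm.a0_mean)
        a0_s.append(report.lfm.a0_sd)
        r2_m.append(report.lfm.r2_mean)
        r2_s.append(report.lfm.r2_sd)
        rmsd_m.append(report.rmsd_mean)
        rmsd_s.append(report.rmsd_sd)
    if n_undefined:
        logger.warning(
            "%d of %d simulations produced an undefined CMC (excluded "
            "from the CMC mean/SD)", n_undefined, config.n_sim,
        )
    cmc_arr = np.asarray(cmcs)
    return MCSummary(
        n_sim=config.n_sim,
        rom_mean=float(np.mean(roms)),
        rom_sd=_sd(np.asarray(roms)),
        cmc_mean=float(np.mean(cmc_arr)) if cmc_arr.size else float("nan"),
        cmc_sd=_sd(cmc_arr) if cmc_arr.size else float("nan"),
        mav_mean=float(np.mean(mavs)),
        mav_sd=_sd(np.asarray(mavs)),
        a1_mean_of_means=float(np.mean(a1_m)),
        a1_mean_of_sds=float(np.mean(a1_s)),
        a0_mean_of_means=float(np.mean(a0_m)),
        a0_mean_of_sds=float(np.mean(a0_s)),
        r2_mean_of_means=float(np.mean(r2_m)),
        r2_mean_of_sds=float(np.mean(r2_s)),
        rmsd_mean_of_means=float(np.mean(rmsd_m)),
        rmsd_mean_of_sds=float(np.mean(rmsd_s)),
        n_undefined_cmc=n_undefined,
    )


def run_table4(
    n_sim: int = 1000,
    seed: int = 0,
    population: PopulationSpec | None = None,
    group_size: int = 5,
) -> pd.DataFrame:
    """Full factor x joint x mode Monte Carlo grid (24 rows).

    Factor blocks: single-factor alpha, offset and tau runs, then the
    mixed simulation (MS) drawing all three at once, each for
    hip/knee/ankle and WS/BS.  Row seeds derive deterministically from
    ``seed`` via a spawned seed sequence.
    """
    population = population or builtin_population()
    blocks = [("alpha",), ("offset",), ("tau",), "mixed"]
    rows = []
    children = np.random.SeedSequence(seed).spawn(24)
    i = 0
    for factors in blocks:
        for joint in ("hip", "knee", "ankle"):
            for mode in ("WS", "BS"):
                row_seed = int(children[i].generate_state(1)[0] % (2**31))
                i += 1
                config = MCConfig(
                    joint=joint,
                    mode=mode,
                    factors=factors,
                    n_sim=n_sim,
                    group_size=group_size,
                    seed=row_seed,
                )
                summary = run_simulation(config, population)
                rows.append(
                    {
                        "factor": "MS" if factors == "mixed" else factors[0],
                        "joint": joint,
                        "mode": mode,
                        **summary.__dict__,
                    }
                )
    return pd.DataFrame(rows)
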