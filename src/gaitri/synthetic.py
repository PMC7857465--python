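"""Synthetic sagittal gait kinematics generator.

Produces subject-level hip/knee/ankle flexion-angle templates and
stride groups with the statistical structure a repeatability analysis
assumes: a joint-specific base curve shape, subject-to-subject scaling
of the range of motion, subject offsets, and stride-to-stride
amplitude/offset/time-shift perturbations drawn uniformly within
configurable ranges.

The base curve shapes are synthetic fixtures: band-limited trigonometric
curves hand-tuned to the qualitative features of normative sagittal
gait (hip: one dominant flexion-extension wave; knee: small stance
flexion bump and a large swing flexion peak; ankle: biphasic
dorsi/plantar-flexion with a push-off plantarflexion trough).  They are
not measured cohort curves, so analyses built on them reproduce
qualitative orderings, not any cohort's exact index values.
Range-of-motion distributions are calibrated to typical adult treadmill
walking (hip ~ 43 +- 6 deg, knee ~ 64 +- 6 deg, ankle ~ 19 +- 1.5 deg
between subjects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .fourier import FourierModel, perturb, reconstruct
from .waveform import FOURIER_GRID_SIZE, WaveformGroup, rom

__all__ = [
    "JointSpec",
    "PopulationSpec",
    "SubjectTemplate",
    "GeneratedGroup",
    "builtin_population",
    "sample_subject",
    "generate_group",
]

JOINTS = ("hip", "knee", "ankle")


@dataclass(frozen=True)
class JointSpec:
    """Base shape and between-subject variability of one joint.

    rom_mean/rom_sd parametrize the normal distribution of subject
    ranges of motion (degrees); offset_sd the SD of the subject-specific
    constant offset (degrees).
    """

    joint: str
    base_model: FourierModel
    rom_mean: float
    rom_sd: float
    offset_sd: float

    def to_dict(self) -> dict:
        return {
            "joint": self.joint,
            "base_model": self.base_model.to_dict(),
            "rom_mean": self.rom_mean,
            "rom_sd": self.rom_sd,
            "offset_sd": self.offset_sd,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "JointSpec":
        return cls(
            joint=payload["joint"],
            base_model=FourierModel.from_dict(payload["base_model"]),
            rom_mean=float(payload["rom_mean"]),
            rom_sd=float(payload["rom_sd"]),
            offset_sd=float(payload["offset_sd"]),
        )


@dataclass(frozen=True)
class PopulationSpec:
    """Per-joint generation parameters for a synthetic cohort."""

    joints: Mapping[str, JointSpec]

    def to_json(self) -> str:
        return json.dumps(
            {name: spec.to_dict() for name, spec in self.joints.items()},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PopulationSpec":
        payload = json.loads(text)
        return cls(
            {name: JointSpec.from_dict(spec) for name, spec in payload.items()}
        )

    @classmethod
    def load(cls, path: str | Path) -> "PopulationSpec":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class SubjectTemplate:
    """One subject's mean curve for one joint, as a Fourier model."""

    joint: str
    model: FourierModel
    nominal_rom: float


@dataclass(frozen=True)
class GeneratedGroup:
    """A stride group plus the perturbation draws that produced it.

    The recorded draws make parameter-recovery checks possible:
    ``alphas`` are fractional amplitude factors, ``offsets`` degrees,
    ``taus`` % of the gait cycle.
    """

    group: WaveformGroup
    alphas: tuple[float, ...]
    offsets: tuple[float, ...]
    taus: tuple[float, ...]


# Fixture base shapes (synthetic; see module docstring).  Coefficients in
# degrees; constant level is a0/2.
_HIP_BASE = FourierModel(a0=18.0, harmonics=((19.0, 4.0), (2.5, -1.5)))
_KNEE_BASE = FourierModel(
    a0=24.5127,
    harmonics=(
        (0.2659, -9.0105),
        (-11.6210, 7.4873),
        (2.7761, 8.4154),
        (3.9471, -5.3665),
        (-3.7367, -3.3129),
    ),
)
_ANKLE_BASE = FourierModel(
    a0=-1.5968,
    harmonics=(
        (-1.9454, 3.5782),
        (0.6057, -4.8570),
        (-2.2400, 1.8425),
        (1.6292, -0.4678),
    ),
)


def builtin_population() -> PopulationSpec:
    """The packaged synthetic cohort (hip/knee/ankle sagittal flexion)."""
    return PopulationSpec(
        {
            "hip": JointSpec("hip", _HIP_BASE, 43.0, 6.0, 3.0),
            "knee": JointSpec("knee", _KNEE_BASE, 64.0, 6.0, 3.0),
            "ankle": JointSpec("ankle", _ANKLE_BASE, 19.0, 1.5, 1.5),
        }
    )


def _model_rom(model: FourierModel) -> float:
    return rom(reconstruct(model, FOURIER_GRID_SIZE))


def sample_subject(
    joint: str,
    rng: np.random.Generator,
    population: PopulationSpec | None = None,
) -> SubjectTemplate:
    """Draw one subject template: ROM-rescaled base shape plus offset.

    Draw order (fixed for reproducibility): ROM first, then the subject
    offset.  The ROM draw is truncated below at 1 deg to keep templates
    non-degenerate.
    """
    population = population or builtin_population()
    try:
        spec = population.joints[joint]
    except KeyError:
        raise ValueError(f"unknown joint {joint!r}") from None
    rom_draw = max(1.0, rng.normal(spec.rom_mean, spec.rom_sd))
    offset_draw = rng.normal(0.0, spec.offset_sd)
    base_rom = _model_rom(spec.base_model)
    scale = rom_draw / base_rom
    model = FourierModel(
        a0=spec.base_model.a0 * scale + 2.0 * offset_draw,
        harmonics=tuple(
            (ak * scale, bk * scale) for ak, bk in spec.base_model.harmonics
        ),
        period=spec.base_model.period,
    )
    return SubjectTemplate(joint, model, _model_rom(model))


def generate_group(
    templates: SubjectTemplate | Sequence[SubjectTemplate],
    ranges,
    m: int = 5,
    rng: np.random.Generator | None = None,
    grid_size: int = FOURIER_GRID_SIZE,
) -> GeneratedGroup:
    """Generate a stride group by perturbing subject templates.

    ``templates`` is either one template shared by all curves (a
    within-subject group) or a sequence of exactly ``m`` templates (a
    between-subject group).  ``ranges`` carries ``alpha_max`` and
    ``offset_max`` in % of the template ROM and ``tau_max`` in % of the
    gait cycle.  Per curve j the draws are, in order:

        alpha_j ~ U(-alpha_max, alpha_max) / 100
        O_j     ~ U(-offset_max, offset_max) / 100 * ROM_template  [deg]
        tau_j   ~ U(0, tau_max)                                    [%cycle]

    and curve_j = reconstruct(perturb(template_j, alpha_j, O_j, tau_j)).
    """
    if rng is None:
        rng = np.random.default_rng()
    if m < 2:
        raise ValueError("need at least 2 curves per group")
    if isinstance(templates, SubjectTemplate):
        templates = [templates] * m
    else:
        templates = list(templates)
        if len(templates) != m:
            raise ValueError(
                f"need 1 or {m} templates, got {len(templates)}"
            )
    for name in ("alpha_max", "offset_max", "tau_max"):
        if getattr(ranges, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    curves, alphas, offsets, taus = [], [], [], []
    for template in templates:
        a = rng.uniform(-ranges.alpha_max, ranges.alpha_max) / 100.0
        o = (
            rng.uniform(-ranges.offset_max, ranges.offset_max)
            / 100.0
            * template.nominal_rom
        )
        tau = rng.uniform(0.0, ranges.tau_max)
        curves.append(
            reconstruct(perturb(template.model, a, o, tau), grid_size)
        )
        alphas.append(a)
        offsets.append(o)
        taus.append(tau)
    return GeneratedGroup(
        group=WaveformGroup(tuple(curves)),
        alphas=tuple(alphas),
        offsets=tuple(offsets),
        taus=tuple(taus),
    )
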