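"""Synthetic pointing cohorts with the structure the analysis assumes.

Each simulated subject points at the nine true target directions of the
3x3 wall matrix (100 cm spacing, 192 cm viewing distance by default).
The generative model per pointing response is:

1. the true target direction is projected to the tangent plane and
   distorted by a per-subject affine map (isotropic *scale* for mental-map
   magnification — the phenomenological carrier of the female > male area
   difference — plus a *shear* term coupling azimuth into polar);
2. Gaussian angular jitter is added per axis, at full strength in the
   five closed-eyes task paradigms and reduced to a fraction (default
   25%) in the two calibrations, where visual feedback is available;
3. in task paradigms only, each response is independently a *gross
   (large-scale) error* with probability ``gross_error_prob``: the
   response is redirected toward a wrong matrix column (azimuth-dominant
   target confusion, the error mode that leaves frames unrecognizable in
   cognitive impairment), or — in the alternative additive modes — a
   large zero-mean azimuth error is added instead.

Column-confusion gross errors preferentially move off-center vertices
inward, which is what shrinks the mean caliper diameter and breaks
convexity in impaired frames; the additive modes are kept as switches
but do not reproduce the diameter decrease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io import (
    CALIBRATION_PARADIGMS,
    Paradigm,
    PointingRecord,
    SubjectMeta,
    TargetLabel,
)

__all__ = [
    "SubjectProfile",
    "GroupSpec",
    "CohortConfig",
    "true_target_angles",
    "simulate_subject",
    "simulate_cohort",
]

GROSS_ERROR_MODES = ("column_confusion", "additive_azimuth", "additive_isotropic")

_CLIP_DEG = 88.9  # keep simulated angles strictly inside the record domain


def true_target_angles(
    spacing_cm: float = 100.0, distance_cm: float = 192.0
) -> dict[TargetLabel, tuple[float, float]]:
    """Ground-truth (azimuth, polar) degrees for the nine targets.

    Per-axis angles: ``azimuth = atan(col * spacing / distance)``,
    ``polar = atan(row * spacing / distance)`` for row, col in {-1, 0, 1}.
    At the default geometry neighboring targets are separated by
    ``atan(100/192) = 27.5`` degrees and the full scope is 55 degrees.
    """
    if spacing_cm <= 0 or distance_cm <= 0:
        raise ValueError("geometry must be positive")
    out = {}
    for t in TargetLabel:
        col, row = t.grid
        out[t] = (
            math.degrees(math.atan(col * spacing_cm / distance_cm)),
            math.degrees(math.atan(row * spacing_cm / distance_cm)),
        )
    return out


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one simulated subject.

    ``angular_noise_sd`` (degrees) is the per-axis Gaussian jitter in task
    paradigms; calibrations use ``calibration_noise_frac`` of it.
    ``scale_factor`` magnifies the mental map (frame area scales with its
    square); ``shear`` couples azimuth into polar.  ``gross_error_prob``
    is the per-response probability of a large-scale error in task
    paradigms and ``gross_error_sd`` the jitter of that error component.
    ``paradigm_effects`` optionally maps a paradigm to (azimuth, polar)
    scale multipliers (e.g. frame narrowing after dominant-side rotation).
    """

    angular_noise_sd: float = 3.0
    scale_factor: float = 1.0
    shear: float = 0.0
    gross_error_prob: float = 0.0
    gross_error_sd: float = 6.0
    gross_error_mode: str = "column_confusion"
    calibration_noise_frac: float = 0.25
    paradigm_effects: Mapping[Paradigm, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.angular_noise_sd < 0:
            raise ValueError("angular_noise_sd must be >= 0")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if not 0 <= self.gross_error_prob <= 1:
            raise ValueError("gross_error_prob must be in [0, 1]")
        if self.gross_error_sd < self.angular_noise_sd:
            raise ValueError("gross_error_sd must be >= angular_noise_sd")
        if self.gross_error_mode not in GROSS_ERROR_MODES:
            raise ValueError(f"unknown gross_error_mode {self.gross_error_mode!r}")


def _distort(
    x: float, y: float, profile: SubjectProfile, mult: tuple[float, float]
) -> tuple[float, float]:
    s = profile.scale_factor
    xd = (s * x + profile.shear * y) * mult[0]
    yd = s * y * mult[1]
    return xd, yd


def simulate_subject(
    subject_id: str,
    profile: SubjectProfile,
    rng: np.random.Generator,
    spacing_cm: float = 100.0,
    distance_cm: float = 192.0,
) -> list[PointingRecord]:
    """Simulate all 7 paradigms x 9 targets for one subject."""
    truth = true_target_angles(spacing_cm, distance_cm)
    records = []
    for paradigm in Paradigm:
        is_calibration = paradigm in CALIBRATION_PARADIGMS
        noise_sd = profile.angular_noise_sd * (
            profile.calibration_noise_frac if is_calibration else 1.0
        )
        mult = (1.0, 1.0)
        if profile.paradigm_effects and paradigm in profile.paradigm_effects:
            mult = profile.paradigm_effects[paradigm]
        for target in TargetLabel:
            az_true, pol_true = truth[target]
            x = math.tan(math.radians(az_true))
            y = math.tan(math.radians(pol_true))
            xd, yd = _distort(x, y, profile, mult)
            az0 = math.degrees(math.atan(xd))
            pol0 = math.degrees(math.atan(yd))
            gross = (not is_calibration) and (
                profile.gross_error_prob > 0
                and rng.random() < profile.gross_error_prob
            )
            if gross:
                if profile.gross_error_mode == "column_confusion":
                    col = target.grid[0]
                    wrong = int(rng.choice([c for c in (-1, 0, 1) if c != col]))
                    xw, yw = _distort(
                        wrong * spacing_cm / distance_cm, y, profile, mult
                    )
                    az = (
                        math.degrees(math.atan(xw))
                        + rng.normal(0.0, profile.gross_error_sd)
                    )
                    pol = pol0 + rng.normal(0.0, noise_sd)
                elif profile.gross_error_mode == "additive_azimuth":
                    az = az0 + rng.normal(0.0, profile.gross_error_sd)
                    pol = pol0 + rng.normal(0.0, noise_sd)
                else:  # additive_isotropic
                    az = az0 + rng.normal(0.0, profile.gross_error_sd)
                    pol = pol0 + rng.normal(0.0, profile.gross_error_sd)
            else:
                az = az0 + rng.normal(0.0, noise_sd)
                pol = pol0 + rng.normal(0.0, noise_sd)
            records.append(
                PointingRecord(
                    subject_id=subject_id,
                    paradigm=paradigm,
                    target=target,
                    azimuth_deg=float(np.clip(az, -_CLIP_DEG, _CLIP_DEG)),
                    polar_deg=float(np.clip(pol, -_CLIP_DEG, _CLIP_DEG)),
                )
            )
    return records


@dataclass(frozen=True)
class GroupSpec:
    """Population-level parameters for one cognition group.

    Subject profiles are drawn from this spec: the scale factor is
    Gaussian around a sex-specific mean (females larger, the
    phenomenological sex area effect), shear is zero-mean Gaussian, ages
    and MoCA scores uniform within the given ranges.  Age has no effect
    on frame morphology by default; ``age_area_slope`` (tangent-scale
    per year) adds an optional drift.
    """

    cognition: str = "normal"
    gross_error_prob: float = 0.03
    angular_noise_sd: float = 3.0
    gross_error_sd: float = 6.0
    gross_error_mode: str = "column_confusion"
    scale_mean_female: float = 1.04
    scale_mean_male: float = 0.96
    scale_sd: float = 0.06
    shear_sd: float = 0.03
    age_range: tuple[float, float] = (20.0, 80.0)
    moca_range: tuple[int, int] = (27, 30)
    age_area_slope: float = 0.0
    paradigm_effects: Mapping[Paradigm, tuple[float, float]] | None = None


DEFAULT_NORMAL = GroupSpec()
DEFAULT_IMPAIRED = GroupSpec(
    cognition="impaired",
    gross_error_prob=0.3,
    angular_noise_sd=4.0,
    gross_error_sd=6.0,
    age_range=(60.0, 84.0),
    moca_range=(18, 26),
)


@dataclass(frozen=True)
class CohortConfig:
    """A two-group cohort: sample sizes, group specs, geometry, seed."""

    n_per_group: int = 30
    seed: int = 0
    spacing_cm: float = 100.0
    distance_cm: float = 192.0
    normal: GroupSpec = DEFAULT_NORMAL
    impaired: GroupSpec = DEFAULT_IMPAIRED
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.spacing_cm <= 0 or self.distance_cm <= 0:
            raise ValueError("geometry must be positive")


def _draw_profile(
    spec: GroupSpec, sex: str, age: float, rng: np.random.Generator
) -> SubjectProfile:
    mean_scale = spec.scale_mean_female if sex == "female" else spec.scale_mean_male
    mean_scale = mean_scale + spec.age_area_slope * (age - 50.0)
    scale = float(np.clip(rng.normal(mean_scale, spec.scale_sd), 0.5, 2.0))
    shear = float(rng.normal(0.0, spec.shear_sd))
    return SubjectProfile(
        angular_noise_sd=spec.angular_noise_sd,
        scale_factor=scale,
        shear=shear,
        gross_error_prob=spec.gross_error_prob,
        gross_error_sd=max(spec.gross_error_sd, spec.angular_noise_sd),
        gross_error_mode=spec.gross_error_mode,
        paradigm_effects=spec.paradigm_effects,
    )


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[PointingRecord], list[SubjectMeta]]:
    """Simulate a two-group cohort; deterministic given ``config.seed``.

    Returns 7 x 9 records per subject and one metadata row each.  Subject
    ids are ``N###`` (normal) and ``P###`` (impaired); sexes alternate to
    hit ``female_fraction`` deterministically.
    """
    rng = np.random.default_rng(config.seed)
    records: list[PointingRecord] = []
    meta: list[SubjectMeta] = []
    for prefix, spec in (("N", config.normal), ("P", config.impaired)):
        n_female = round(config.n_per_group * config.female_fraction)
        for i in range(config.n_per_group):
            sid = f"{prefix}{i + 1:03d}"
            sex = "female" if i < n_female else "male"
            age = float(rng.uniform(*spec.age_range))
            moca = int(rng.integers(spec.moca_range[0], spec.moca_range[1] + 1))
            profile = _draw_profile(spec, sex, age, rng)
            meta.append(
                SubjectMeta(
                    subject_id=sid,
                    sex=sex,
                    age_years=round(age, 1),
                    cognition=spec.cognition,
                    moca_points=moca,
                    handedness="right",
                )
            )
            records.extend(
                simulate_subject(
                    sid, profile, rng, config.spacing_cm, config.distance_cm
                )
            )
    return records, meta
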