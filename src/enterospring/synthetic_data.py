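"""Synthetic tensile curves and geometry cohorts.

No public dataset of intestinal tensile records or geometry measurements
exists, so this module generates inputs with the statistical structure
the downstream analysis assumes:

* tensile force-displacement curves with the classic soft-tissue
  J-shape — a compliant toe that rises to the 2 N preload, a linear
  elastic region whose slope encodes the Young's modulus
  (k = E * A / L0), and a post-peak failure drop — plus additive
  Gaussian load-cell noise;

* geometry cohorts (wall thickness, flattened half-circumference width)
  whose trends increase monotonically with age, emulating paediatric-to-
  adult growth: thickness ~1-4 mm and lumen radius ~1-2 cm over ages
  2 months to 69 years.

Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import GeometryMeasurement


@dataclass(frozen=True)
class TensileSpecimenSpec:
    """Rectangular tensile specimen cut longitudinally from the opened tract."""

    gauge_length: float  # mm
    width: float  # mm
    thickness: float  # mm

    def __post_init__(self):
        for name in ("gauge_length", "width", "thickness"):
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidParameterError(f"{name} must be > 0, got {v}")

    @property
    def area(self) -> float:
        """Cross-section area in mm^2."""
        return self.width * self.thickness


@dataclass(frozen=True)
class SyntheticCurveParams:
    """Shape parameters of a synthetic tensile curve.

    true_modulus in MPa; strains are engineering strains (displacement /
    gauge length). The toe rises to ``preload`` (2 N by default — the
    preload applied to remove slack before recording) at ``toe_strain``;
    the linear region runs to ``failure_strain``; failure is a linear
    force drop over the following 5% strain.
    """

    true_modulus: float
    toe_strain: float = 0.05
    failure_strain: float = 0.50
    preload: float = 2.0
    noise_sd: float = 0.0
    n_points: int = 200
    seed: int = 0

    #: extra strain over which the post-peak force drops to zero
    FAILURE_DROP_STRAIN = 0.05
    #: exponent of the exponential-approach toe segment
    TOE_SHAPE = 3.0

    def __post_init__(self):
        if not (self.true_modulus > 0):
            raise InvalidParameterError(
                f"true_modulus must be > 0, got {self.true_modulus}")
        if self.toe_strain < 0:
            raise InvalidParameterError("toe_strain must be >= 0")
        if not (self.failure_strain > self.toe_strain):
            raise InvalidParameterError(
                "failure_strain must exceed toe_strain")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_points < 10:
            raise InvalidParameterError("n_points must be >= 10")
        if self.preload < 0:
            raise InvalidParameterError("preload must be >= 0")


def _noiseless_force(strain: np.ndarray, spec: TensileSpecimenSpec,
                     p: SyntheticCurveParams) -> np.ndarray:
    """Piecewise toe / linear / failure force law (N) vs engineering strain."""
    k = p.true_modulus * spec.area / spec.gauge_length  # N per mm displacement
    slope_strain = k * spec.gauge_length                # N per unit strain
    peak = p.preload + slope_strain * (p.failure_strain - p.toe_strain)

    force = np.empty_like(strain)

    # toe: exponential approach from 0 to the preload at toe_strain
    if p.toe_strain > 0:
        xi = np.clip(strain / p.toe_strain, 0.0, 1.0)
        a = p.TOE_SHAPE
        toe = p.preload * (np.expm1(a * xi) / np.expm1(a))
    else:
        toe = np.zeros_like(strain)

    linear = p.preload + slope_strain * (strain - p.toe_strain)
    drop = peak * (1.0 - (strain - p.failure_strain) / p.FAILURE_DROP_STRAIN)

    force = np.where(strain <= p.toe_strain, toe,
                     np.where(strain <= p.failure_strain, linear,
                              np.maximum(drop, 0.0)))
    return force


def generate_tensile_curve(spec: TensileSpecimenSpec, params: SyntheticCurveParams):
    """Synthesize one tensile pull as a :class:`~enterospring.tensile.TensileCurve`.

    Displacements are an even grid from 0 to
    (failure_strain + FAILURE_DROP_STRAIN) * gauge_length; the linear
    region has exact slope E*A/L0 when noise_sd = 0.
    """
    from .tensile import TensileCurve  # local import to avoid a cycle

    if spec.area <= 0:
        raise InvalidParameterError("specimen cross-section must be positive")
    p = params
    end_strain = p.failure_strain + p.FAILURE_DROP_STRAIN
    strain = np.linspace(0.0, end_strain, p.n_points)
    displacement = strain * spec.gauge_length
    force = _noiseless_force(strain, spec, p)
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        force = force + rng.normal(0.0, p.noise_sd, size=force.shape)
    return TensileCurve(displacement=displacement, force=force,
                        specimen=spec, label="synthetic")


@dataclass(frozen=True)
class GeometryCohortParams:
    """Cohort-level generation parameters.

    Defaults follow the measured human cohort: 61 subjects, ages 2
    months to 69 years, wall thickness ~1-4 mm and radius ~1-2 cm, both
    increasing with age. Trends are linear in log-age (growth slows with
    age but never reverses); ``trend_noise_sd`` is the Gaussian sd (in
    mm for thickness and scaled to cm for the width) around the trend,
    clipped back to the stated ranges.
    """

    n_subjects: int = 61
    age_range: tuple[float, float] = (2.0 / 12.0, 69.0)
    thickness_range: tuple[float, float] = (1.0, 4.0)  # mm
    radius_range: tuple[float, float] = (1.0, 2.0)  # cm
    trend_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        for name in ("age_range", "thickness_range", "radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise InvalidParameterError(
                    f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if self.trend_noise_sd < 0:
            raise InvalidParameterError("trend_noise_sd must be >= 0")


def generate_geometry_cohort(params: GeometryCohortParams) -> list[GeometryMeasurement]:
    """Draw a cohort of geometry measurements, ordered by age.

    Ages are log-uniform over the age range (paediatric subjects are as
    represented as adults). Thickness and radius follow linear-in-
    log-age trends spanning their stated ranges, plus clipped Gaussian
    noise. The flattened width is d = pi * R.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    log_lo, log_hi = math.log(p.age_range[0]), math.log(p.age_range[1])
    log_ages = np.sort(rng.uniform(log_lo, log_hi, size=p.n_subjects))
    frac = (log_ages - log_lo) / (log_hi - log_lo)

    t_lo, t_hi = p.thickness_range
    r_lo, r_hi = p.radius_range
    thickness = t_lo + frac * (t_hi - t_lo)
    radius = r_lo + frac * (r_hi - r_lo)
    if p.trend_noise_sd > 0:
        thickness = thickness + rng.normal(0.0, p.trend_noise_sd, p.n_subjects)
        # same relative noise scale for the radius trend (cm)
        radius_sd = p.trend_noise_sd * (r_hi - r_lo) / (t_hi - t_lo)
        radius = radius + rng.normal(0.0, radius_sd, p.n_subjects)
    thickness = np.clip(thickness, t_lo, t_hi)
    radius = np.clip(radius, r_lo, r_hi)

    return [
        GeometryMeasurement(
            subject_id=f"S{i + 1:03d}",
            age=float(np.exp(log_ages[i])),
            wall_thickness=float(thickness[i]),
            flat_width_d=float(math.pi * radius[i]),
        )
        for i in range(p.n_subjects)
    ]


def write_tensile_csv(curve, path: str | Path) -> None:
    """Write a tensile curve as two-column CSV (displacement_mm, force_N)."""
    pd.DataFrame({
        "displacement_mm": curve.displacement,
        "force_N": curve.force,
    }).to_csv(path, index=False)


def write_cohort_csv(cohort: list[GeometryMeasurement], path: str | Path) -> None:
    """Write a geometry cohort CSV (subject_id, age_years, thickness_mm, flat_width_cm)."""
    pd.DataFrame({
        "subject_id": [m.subject_id for m in cohort],
        "age_years": [m.age for m in cohort],
        "thickness_mm": [m.wall_thickness for m in cohort],
        "flat_width_cm": [m.flat_width_d for m in cohort],
    }).to_csv(path, index=False)
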