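"""Model geometry: radius from flattened width, wall partition, model grids.

Units convention (used package-wide): lengths are stored in the units the
field reports them in — radii and segment lengths in cm, wall thicknesses
in mm — and converted to a consistent N/mm/MPa system at the point of use
(:func:`IntestineModelSpec.radii_mm` and the solvers). Stress is MPa,
force N.

The intestinal wall is modelled as three concentric layers — mucosa
(innermost), submucosa, muscularis propria (outermost) — whose thicknesses
are fixed fractions of the total wall thickness (default 75/5/20%,
measured on histology cross-sections).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidMeasurementError

MM_PER_CM = 10.0

#: Default wall-layer thickness fractions (mucosa, submucosa, muscularis).
DEFAULT_LAYER_FRACTIONS = (0.75, 0.05, 0.20)

#: Canonical layer names, inner to outer.
LAYER_NAMES = ("mucosa", "submucosa", "muscularis")


@dataclass(frozen=True)
class GeometryMeasurement:
    """One subject's raw intestinal geometry.

    ``flat_width_d`` is the mesentery-to-antimesentery distance of the
    flattened (cut-open collapsed) tract, i.e. half the circumference.
    """

    subject_id: str
    age: float  # years
    wall_thickness: float  # mm
    flat_width_d: float  # cm

    def __post_init__(self):
        if self.wall_thickness <= 0:
            raise InvalidMeasurementError(
                f"wall_thickness must be > 0, got {self.wall_thickness}")
        if self.flat_width_d <= 0:
            raise InvalidMeasurementError(
                f"flat_width_d must be > 0, got {self.flat_width_d}")

    @property
    def radius(self) -> float:
        """Derived lumen radius in cm."""
        return radius_from_flat_width(self.flat_width_d)


@dataclass(frozen=True)
class WallPartition:
    """Per-layer thicknesses (mm) for a given total wall thickness."""

    t_mucosa: float
    t_submucosa: float
    t_muscularis: float
    fractions: tuple[float, float, float] = DEFAULT_LAYER_FRACTIONS

    @property
    def total(self) -> float:
        return self.t_mucosa + self.t_submucosa + self.t_muscularis

    @property
    def thicknesses(self) -> tuple[float, float, float]:
        """Layer thicknesses inner to outer (mucosa, submucosa, muscularis)."""
        return (self.t_mucosa, self.t_submucosa, self.t_muscularis)


@dataclass(frozen=True)
class MesenteryOptions:
    """Geometry/material of the tied mesentery sheet.

    The sheet hangs radially off one generatrix of the outer wall, spans
    the full segment length, and its far edge (the base) is fixed.
    ``height_mm=None`` means "equal to the lumen inner radius".
    """

    height_mm: float | None = None
    thickness_mm: float = 0.5
    material_name: str = "mesentery"

    def resolved_height_mm(self, inner_radius_cm: float) -> float:
        h = self.height_mm if self.height_mm is not None else inner_radius_cm * MM_PER_CM
        if h <= 0:
            raise ConfigurationError(f"mesentery height must be > 0, got {h}")
        return h


@dataclass(frozen=True)
class IntestineModelSpec:
    """Geometry of one layered-cylinder model.

    inner_radius in cm, wall_thickness in mm, segment_length in cm (the
    distracted segment; default 1.5 cm matches the ink-marked segment
    length used in vivo).
    """

    inner_radius: float  # cm
    wall_thickness: float  # mm
    segment_length: float = 1.5  # cm
    partition: WallPartition | None = None
    mesentery: MesenteryOptions | None = None

    def __post_init__(self):
        if self.inner_radius <= 0:
            raise ConfigurationError(
                f"inner_radius must be > 0, got {self.inner_radius}")
        if self.wall_thickness <= 0:
            raise ConfigurationError(
                f"wall_thickness must be > 0, got {self.wall_thickness}")
        if self.segment_length <= 0:
            raise ConfigurationError(
                f"segment_length must be > 0, got {self.segment_length}")
        if self.partition is None:
            object.__setattr__(
                self, "partition", partition_wall(self.wall_thickness))
        else:
            if abs(self.partition.total - self.wall_thickness) > 1e-9:
                raise ConfigurationError(
                    "partition total does not match wall_thickness")

    @property
    def inner_radius_mm(self) -> float:
        return self.inner_radius * MM_PER_CM

    @property
    def segment_length_mm(self) -> float:
        return self.segment_length * MM_PER_CM

    def radii_mm(self) -> np.ndarray:
        """Cumulative layer boundary radii in mm, inner wall outward.

        Returns 4 radii: lumen, mucosa/submucosa, submucosa/muscularis,
        outer wall.
        """
        t = np.asarray(self.partition.thicknesses)
        return self.inner_radius_mm + np.concatenate([[0.0], np.cumsum(t)])

    def layer_areas_mm2(self) -> np.ndarray:
        """Undeformed annular cross-section area (mm^2) of each wall layer."""
        r = self.radii_mm()
        return math.pi * (r[1:] ** 2 - r[:-1] ** 2)


def radius_from_flat_width(d: float) -> float:
    """Lumen radius from the flattened half-circumference width ``d``.

    The collapsed tract flattened on a slide measures half its
    circumference between the mesenteric and anti-mesenteric edges, so
    d = pi * R and R = d / pi. Units in = units out.
    """
    if d <= 0:
        raise InvalidMeasurementError(f"flat width must be > 0, got {d}")
    return d / math.pi


def partition_wall(
    t_total: float,
    fractions: Sequence[float] = DEFAULT_LAYER_FRACTIONS,
) -> WallPartition:
    """Split a total wall thickness (mm) into the three layers."""
    if t_total <= 0:
        raise ConfigurationError(f"total thickness must be > 0, got {t_total}")
    fr = tuple(float(f) for f in fractions)
    if len(fr) != 3 or any(f <= 0 for f in fr):
        raise ConfigurationError(f"need 3 positive fractions, got {fr}")
    if abs(sum(fr) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got sum={sum(fr)}")
    t = [f * t_total for f in fr]
    # force exact conservation against float round-off
    t[2] = t_total - t[0] - t[1]
    return WallPartition(t[0], t[1], t[2], fractions=fr)


def make_model_grid(
    radius_range: tuple[float, float],
    thickness_range: tuple[float, float],
    n_r: int,
    n_t: int,
    *,
    segment_length: float = 1.5,
    fractions: Sequence[float] = DEFAULT_LAYER_FRACTIONS,
    mesentery: MesenteryOptions | None = None,
) -> list[IntestineModelSpec]:
    """Cartesian (thickness, radius) grid of model specs, endpoints included.

    radius_range in cm, thickness_range in mm. Ordered by (t, R).
    """
    if n_r < 2 or n_t < 2:
        raise ConfigurationError("n_r and n_t must both be >= 2")
    for name, (lo, hi) in (("radius", radius_range), ("thickness", thickness_range)):
        if not (0 < lo < hi):
            raise ConfigurationError(f"{name} range must satisfy 0 < lo < hi, got ({lo}, {hi})")
    radii = np.linspace(radius_range[0], radius_range[1], n_r)
    thicknesses = np.linspace(thickness_range[0], thickness_range[1], n_t)
    specs = []
    for t in thicknesses:
        for r in radii:
            specs.append(IntestineModelSpec(
                inner_radius=float(r),
                wall_thickness=float(t),
                segment_length=segment_length,
                partition=partition_wall(float(t), fractions),
                mesentery=mesentery,
            ))
    return specs


def read_geometry_csv(path: str | Path) -> list[GeometryMeasurement]:
    """Read a geometry cohort CSV (subject_id, age_years, thickness_mm, flat_width_cm)."""
    df = pd.read_csv(path)
    required = {"subject_id", "age_years", "thickness_mm", "flat_width_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"geometry CSV missing columns: {sorted(missing)}")
    return [
        GeometryMeasurement(
            subject_id=str(row.subject_id),
            age=float(row.age_years),
            wall_thickness=float(row.thickness_mm),
            flat_width_d=float(row.flat_width_cm),
        )
        for row in df.itertuples()
    ]


def write_grid_manifest(specs: Sequence[IntestineModelSpec], path: str | Path) -> None:
    """Write a model-grid manifest as JSON."""
    payload = [
        {
            "inner_radius_cm": s.inner_radius,
            "wall_thickness_mm": s.wall_thickness,
            "segment_length_cm": s.segment_length,
            "layer_fractions": list(s.partition.fractions),
            "mesentery": (
                None if s.mesentery is None else {
                    "height_mm": s.mesentery.height_mm,
                    "thickness_mm": s.mesentery.thickness_mm,
                    "material_name": s.mesentery.material_name,
                }
            ),
        }
        for s in specs
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
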