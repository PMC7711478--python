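"""Force-map pipeline: (thickness, radius) sweeps, linearity fits, spring design.

The deliverable of the analysis is a reference table mapping intestinal
geometry (wall thickness t, lumen radius R) to the axial force required
to double the distracted segment's length, from which the spring
constant of a patient-specific nitinol spring follows by Hooke's law
(k = F / working displacement).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, PipelineError
from .geometry import IntestineModelSpec, make_model_grid
from .materials import LayerMaterial
from .mechanics_core import layered_doubling_force

logger = logging.getLogger(__name__)

#: Default sweep over the modelled geometry ranges: R 0.25-3 cm, t 0.5-3 mm.
DEFAULT_RADIUS_RANGE = (0.25, 3.0)  # cm
DEFAULT_THICKNESS_RANGE = (0.5, 3.0)  # mm
DEFAULT_N_RADII = 12
DEFAULT_N_THICKNESSES = 6

#: Default spring working displacement: 7.5 cm relaxed spring compressed
#: into the 1.5 cm distracted segment -> 60 mm of travel.
DEFAULT_WORKING_DISPLACEMENT_MM = 60.0

FORCE_MAP_COLUMNS = ("t_mm", "R_cm", "force_N", "solver", "converged")


def default_grid(**kwargs) -> list[IntestineModelSpec]:
    """The standard 6 thickness x 12 radius sweep of the modelled ranges."""
    return make_model_grid(
        kwargs.pop("radius_range", DEFAULT_RADIUS_RANGE),
        kwargs.pop("thickness_range", DEFAULT_THICKNESS_RANGE),
        kwargs.pop("n_r", DEFAULT_N_RADII),
        kwargs.pop("n_t", DEFAULT_N_THICKNESSES),
        **kwargs,
    )


def _materials_id(materials: Mapping[str, LayerMaterial]) -> str:
    blob = json.dumps(
        {k: (m.young_modulus, m.poisson) for k, m in sorted(materials.items())},
        sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def compute_force_map(
    grid: Sequence[IntestineModelSpec],
    materials: Mapping[str, LayerMaterial],
    solver: str = "semi-analytic",
    stretch: float = 2.0,
    fem_resolution=None,
    fem_options=None,
) -> pd.DataFrame:
    """Required doubling force for every spec of the grid.

    ``solver`` is "semi-analytic" (iso-strain layered closed form; fast,
    mesentery ignored) or "fem" (full hexahedral model). Failures are
    recorded per entry (converged=False, force=NaN) rather than dropped;
    if every entry fails a :class:`PipelineError` carries the reasons.
    Entries are ordered by (t, R); duplicate grid keys are rejected.
    """
    if len(grid) == 0:
        raise ConfigurationError("empty model grid")
    if solver not in ("semi-analytic", "fem"):
        raise ConfigurationError(f"unknown solver {solver!r}")
    keys = [(s.wall_thickness, s.inner_radius) for s in grid]
    if len(set(keys)) != len(keys):
        raise ConfigurationError("duplicate (t, R) grid keys")

    mat_id = _materials_id(materials)
    rows, failures = [], {}
    for spec in sorted(grid, key=lambda s: (s.wall_thickness, s.inner_radius)):
        entry = {
            "t_mm": spec.wall_thickness,
            "R_cm": spec.inner_radius,
            "solver": solver,
            "converged": True,
            "material_set": mat_id,
        }
        try:
            if solver == "semi-analytic":
                entry["force_N"] = layered_doubling_force(spec, materials, stretch)
            else:
                from .fem.solver import find_doubling_force
                result = find_doubling_force(
                    spec, materials, resolution=fem_resolution,
                    stretch=stretch, options=fem_options)
                entry["force_N"] = result.force
        except Exception as exc:  # recorded, not silently dropped
            entry["force_N"] = float("nan")
            entry["converged"] = False
            failures[(spec.wall_thickness, spec.inner_radius)] = repr(exc)
            logger.warning("force-map entry (t=%.3g, R=%.3g) failed: %s",
                           spec.wall_thickness, spec.inner_radius, exc)
        rows.append(entry)
    if len(failures) == len(grid):
        raise PipelineError("every force-map entry failed", failures=failures)
    df = pd.DataFrame(rows)
    return df[["t_mm", "R_cm", "force_N", "solver", "converged", "material_set"]]


def fit_linearity(force_map: pd.DataFrame) -> pd.DataFrame:
    """Per-axis ordinary least-squares fits of the force map.

    For every fixed radius, F vs t; for every fixed thickness, F vs R.
    Requires >= 3 points per line. Returns one row per line with the
    slope, intercept and R^2 — quantifying the approximate linearity of
    force in both geometric parameters.
    """
    df = force_map[force_map["converged"]]
    rows = []
    for axis, fixed in (("t_mm", "R_cm"), ("R_cm", "t_mm")):
        for fval, g in df.groupby(fixed):
            if len(g) < 3:
                raise ConfigurationError(
                    f"need >= 3 points per line, got {len(g)} at {fixed}={fval}")
            x = g[axis].to_numpy()
            y = g["force_N"].to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
            rows.append({"varied": axis, "fixed": fixed, "fixed_value": fval,
                         "slope": slope, "intercept": intercept,
                         "r_squared": min(max(r2, 0.0), 1.0)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SpringDesign:
    """Hooke's-law spring sizing for a predicted tissue force."""

    required_force: float  # N
    working_displacement: float  # mm
    spring_constant: float  # N/mm


def spring_constant(
    required_force: float,
    working_displacement: float = DEFAULT_WORKING_DISPLACEMENT_MM,
) -> SpringDesign:
    """k = F / dx for a spring delivering ``required_force`` over its travel."""
    if working_displacement <= 0:
        raise ConfigurationError(
            f"working displacement must be > 0, got {working_displacement}")
    if required_force < 0:
        raise ConfigurationError("required force must be >= 0")
    return SpringDesign(
        required_force=required_force,
        working_displacement=working_displacement,
        spring_constant=required_force / working_displacement,
    )


def write_force_map(force_map: pd.DataFrame, path: str | Path,
                    metadata: dict | None = None) -> None:
    """CSV (12 significant digits) plus a JSON metadata sidecar."""
    path = Path(path)
    cols = [c for c in FORCE_MAP_COLUMNS if c in force_map.columns]
    force_map.to_csv(path, index=False, columns=cols, float_format="%.12g")
    meta = dict(metadata or {})
    meta.setdefault("columns", cols)
    if "material_set" in force_map.columns and len(force_map):
        meta.setdefault("material_set", str(force_map["material_set"].iloc[0]))
    meta["content_sha256"] = hashlib.sha256(path.read_bytes()).hexdigest()
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


def read_force_map(path: str | Path) -> pd.DataFrame:
    """Read a force-map CSV; verifies columns and the sidecar hash.

    Raises :class:`ParseError` (with line number where determinable) on
    malformed content; a metadata hash mismatch only logs a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse force map {path}: {exc}") from exc
    missing = set(FORCE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"force map missing columns {sorted(missing)}", line=1)
    for i, v in enumerate(df["force_N"]):
        if not isinstance(v, (int, float, np.integer, np.floating)):
            raise ParseError("non-numeric force value", line=i + 2)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        actual = hashlib.sha256(path.read_bytes()).hexdigest()
        if meta.get("content_sha256") not in (None, actual):
            warnings.warn(f"force-map metadata hash mismatch for {path}")
            logger.warning("force-map metadata hash mismatch for %s", path)
    return df
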