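"""Tensile-curve processing: trimming, slope fitting, modulus aggregation.

A uniaxial pull on a rectangular strip of intestinal wall produces a
force-displacement record with three regimes: a toe (slack and fibre
recruitment, below the 2 N preload), a linear elastic region, and a
failure drop. The Young's modulus is the slope k of the linear region
converted through the specimen geometry:

    E = k * L0 / (w * t)        [MPa, with k in N/mm and lengths in mm]

``trim_curve`` removes the preload toe and everything from the force
peak onward (when a genuine post-peak drop exists); ``estimate_modulus``
then picks the best linear window by R^2 and reports E.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateSpecimenError,
    EmptyAfterTrimError,
    InvalidParameterError,
    LabellingError,
)
from .synthetic_data import TensileSpecimenSpec

#: Fig-style layer-group codes: P = porcine, H = human; mu = mucosa,
#: sm = submucosa, (mu+sm removed) etc.
KNOWN_GROUPS = ("P-intact", "P-(mu+sm)", "P-sm", "H-intact")

#: A post-peak force drop larger than this fraction of the peak marks failure.
FAILURE_DROP_FRACTION = 0.05

#: Default preload used to clear slack before recording (N).
DEFAULT_PRELOAD = 2.0


@dataclass(frozen=True)
class TensileCurve:
    """Ordered displacement/force samples from one pull."""

    displacement: np.ndarray  # mm, strictly increasing
    force: np.ndarray  # N
    specimen: TensileSpecimenSpec
    label: str = ""

    def __post_init__(self):
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise InvalidParameterError("displacement/force must be equal-length 1-D")
        if len(d) < 10:
            raise InvalidParameterError(f"need >= 10 samples, got {len(d)}")
        if not np.all(np.diff(d) > 0):
            raise InvalidParameterError("displacements must be strictly increasing")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)

    def __len__(self) -> int:
        return len(self.displacement)

    @property
    def strain(self) -> np.ndarray:
        """Engineering strain: displacement / gauge length."""
        return self.displacement / self.specimen.gauge_length


def read_tensile_csv(path: str | Path, specimen: TensileSpecimenSpec,
                     label: str = "") -> TensileCurve:
    """Read a two-column curve CSV (displacement_mm, force_N)."""
    df = pd.read_csv(path)
    for col in ("displacement_mm", "force_N"):
        if col not in df.columns:
            raise ConfigurationError(f"curve CSV missing column {col!r}")
    return TensileCurve(displacement=df["displacement_mm"].to_numpy(),
                        force=df["force_N"].to_numpy(),
                        specimen=specimen, label=label or str(path))


def trim_curve(curve: TensileCurve, preload: float = DEFAULT_PRELOAD) -> TensileCurve:
    """Remove the preload toe and the failure tail.

    Leading samples with force <= preload are dropped. If the record
    contains a post-peak drop exceeding ``FAILURE_DROP_FRACTION`` of the
    peak force, all samples at and after the global peak are dropped
    too. Idempotent: trimming a trimmed curve changes nothing.
    """
    if preload < 0:
        raise InvalidParameterError("preload must be >= 0")
    f = curve.force
    above = np.nonzero(f > preload)[0]
    if len(above) == 0:
        raise EmptyAfterTrimError(
            f"every sample is at or below the {preload} N preload")
    start = above[0]

    peak = int(np.argmax(f))
    end = len(f)
    if peak < len(f) - 1 and np.min(f[peak + 1:]) < (1.0 - FAILURE_DROP_FRACTION) * f[peak]:
        end = peak  # drop the peak sample itself and everything after
    if end - start < 2:
        raise EmptyAfterTrimError("fewer than 2 samples remain after trimming")
    return TensileCurve(displacement=curve.displacement[start:end],
                        force=f[start:end],
                        specimen=curve.specimen, label=curve.label)


@dataclass(frozen=True)
class ModulusEstimate:
    """Result of a linear fit on a trimmed curve."""

    young_modulus: float  # MPa
    slope: float  # N/mm
    fit_window: tuple[int, int]  # [start, end) indices into the trimmed curve
    r_squared: float


def _best_linear_window(x: np.ndarray, y: np.ndarray,
                        min_frac: float) -> tuple[int, int, float, float]:
    """Sliding-window least squares: maximize R^2, ties -> longer window.

    Evaluates every contiguous window of length >= max(5, min_frac * n)
    using prefix sums (vectorized over all start/length pairs). R^2 is
    rounded to 1e-10 before comparison so that numerically tied windows
    resolve to the longest one.
    """
    n = len(x)
    w_min = max(5, int(np.ceil(min_frac * n)))
    ox = np.concatenate([[0.0], np.cumsum(x)])
    oy = np.concatenate([[0.0], np.cumsum(y)])
    oxx = np.concatenate([[0.0], np.cumsum(x * x)])
    oxy = np.concatenate([[0.0], np.cumsum(x * y)])
    oyy = np.concatenate([[0.0], np.cumsum(y * y)])

    starts = np.arange(n - w_min + 1)
    best = (-np.inf, -1, 0, 0.0)  # (r2_rounded, length, start, slope)
    for w in range(w_min, n + 1):
        s = starts[: n - w + 1]
        e = s + w
        Sx = ox[e] - ox[s]
        Sy = oy[e] - oy[s]
        Sxx = oxx[e] - oxx[s]
        Sxy = oxy[e] - oxy[s]
        Syy = oyy[e] - oyy[s]
        vx = Sxx - Sx * Sx / w
        vy = Syy - Sy * Sy / w
        cov = Sxy - Sx * Sy / w
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = cov / vx
            r2 = np.where(vy > 0, cov * cov / (vx * vy), 1.0)
        r2r = np.round(r2 / 1e-10) * 1e-10
        i = int(np.argmax(r2r))
        cand = (float(r2r[i]), w, int(s[i]), float(slope[i]))
        if (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    r2, w, s0, slope = best
    return s0, s0 + w, slope, min(max(r2, 0.0), 1.0)


def estimate_modulus(curve: TensileCurve, min_window_frac: float = 0.4) -> ModulusEstimate:
    """Young's modulus from a trimmed curve.

    Least-squares slope k over the best linear window (sliding window of
    at least ``min_window_frac`` of the samples, maximizing R^2, ties to
    the longer window); E = k * L0 / (width * thickness).
    """
    if len(curve) < 5:
        raise InvalidParameterError("need >= 5 samples to fit a slope")
    s0, s1, slope, r2 = _best_linear_window(
        curve.displacement, curve.force, min_window_frac)
    if not (slope > 0):
        raise DegenerateSpecimenError(
            f"fitted slope is non-positive ({slope:.3g} N/mm)")
    E = slope * curve.specimen.gauge_length / curve.specimen.area
    return ModulusEstimate(young_modulus=E, slope=slope,
                           fit_window=(s0, s1), r_squared=r2)


@dataclass(frozen=True)
class LabelledEstimate:
    """A modulus estimate tagged with its subject and layer group."""

    estimate: ModulusEstimate
    subject_id: str
    group: str


def aggregate_moduli(
    estimates: Iterable[LabelledEstimate],
    allowed_groups: Sequence[str] | None = KNOWN_GROUPS,
) -> pd.DataFrame:
    """Per-group modulus summary.

    Reports both the specimen-pooled mean/sd (every pull weighted
    equally) and the subject-level mean/sd (mean of per-subject means) —
    the hierarchy matters because subjects contribute unequal specimen
    counts. SDs are sample standard deviations (ddof=1, NaN for n=1).
    """
    rows = list(estimates)
    if not rows:
        raise InvalidParameterError("no estimates to aggregate")
    if allowed_groups is not None:
        unknown = {r.group for r in rows} - set(allowed_groups)
        if unknown:
            raise LabellingError(f"unknown group labels: {sorted(unknown)}")
    df = pd.DataFrame({
        "group": [r.group for r in rows],
        "subject_id": [r.subject_id for r in rows],
        "E_MPa": [r.estimate.young_modulus for r in rows],
    })
    out = []
    for group, g in df.groupby("group", sort=True):
        subj_means = g.groupby("subject_id")["E_MPa"].mean()
        out.append({
            "group": group,
            "specimen_mean_MPa": g["E_MPa"].mean(),
            "specimen_sd_MPa": g["E_MPa"].std(ddof=1),
            "n_specimens": len(g),
            "subject_mean_MPa": subj_means.mean(),
            "subject_sd_MPa": subj_means.std(ddof=1),
            "n_subjects": subj_means.size,
        })
    return pd.DataFrame(out)


def write_summary_csv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, index=False)
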