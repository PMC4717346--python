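"""Site- and occasion-level covariates for the detection/occupancy models.

Covers the human-development kernel density built from structure points
(HOPs), AICc-based selection of its spatial scale, the daily puma-lag
indicator covariates P1-P4 with grid interactions, and z-score
standardization with a recorded transform for back-conversion of
coefficients.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .camera_records import DetectionHistory

__all__ = [
    "StructurePointSet",
    "hop_kernel_density",
    "ScaleSelection",
    "select_scale",
    "build_lag_covariates",
    "LagCovariateMatrix",
    "StandardizeTransform",
    "standardize",
]


@dataclass(frozen=True)
class StructurePointSet:
    """Planar coordinates (metres) of human occurrence points (structures)."""

    points: np.ndarray  # shape (n, 2); may be empty

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("structure coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def hop_kernel_density(
    points: StructurePointSet,
    site_location: Sequence[float],
    radius: float,
    *,
    sigma_fraction: float = 1.0 / 3.0,
    amplitude: float = 1.0,
) -> float:
    """Cumulative truncated-Gaussian kernel intensity of structures at a site.

    Each structure contributes ``amplitude * exp(-d^2 / (2 sigma^2))`` at
    distance ``d`` with ``sigma = sigma_fraction * radius``, and exactly 0
    beyond ``radius``; contributions sum over structures.  Only relative
    (later standardized) values are meaningful, so the kernel is left
    unnormalized with peak ``amplitude`` at distance 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(points) == 0:
        return 0.0
    site = np.asarray(site_location, dtype=float)
    d = np.hypot(*(points.points - site).T)
    sigma = sigma_fraction * radius
    vals = amplitude * np.exp(-0.5 * (d / sigma) ** 2)
    vals[d > radius] = 0.0
    return float(vals.sum())


def hd_columns(
    points: StructurePointSet,
    site_xy: Mapping[str, Sequence[float]],
    radii: Sequence[float],
    **kernel_kwargs,
) -> pd.DataFrame:
    """HD covariate table: one column per candidate radius, one row per site."""
    data = {
        f"HD_{int(r)}": [
            hop_kernel_density(points, xy, r, **kernel_kwargs)
            for xy in site_xy.values()
        ]
        for r in radii
    }
    return pd.DataFrame(data, index=pd.Index(list(site_xy), name="site_id"))


@dataclass
class ScaleSelection:
    """Result of AICc scale selection for the human-development covariate."""

    chosen_radius: float
    table: pd.DataFrame  # columns: radius, AICc, converged; sorted by AICc
    tie: bool = False
    excluded: list[float] = field(default_factory=list)


def select_scale(
    candidate_radii: Sequence[float],
    fit_at_radius: Callable[[float], tuple[float, bool]],
) -> ScaleSelection:
    """Pick the spatial scale of the HD covariate by AICc ranking.

    ``fit_at_radius`` fits the univariate detection model p(HD_r) for one
    radius and returns ``(aicc, converged)``; models share everything but the
    HD column.  The minimum-AICc radius wins; exact ties go to the smallest
    radius with a tie flag; non-convergent radii are excluded with a warning.
    """
    radii = list(candidate_radii)
    if len(radii) < 2:
        raise ValueError("at least two candidate radii are required")
    rows = []
    excluded: list[float] = []
    for r in radii:
        aicc, converged = fit_at_radius(r)
        if not converged or not np.isfinite(aicc):
            excluded.append(r)
            warnings.warn(f"radius {r}: model did not converge; excluded", stacklevel=2)
            continue
        rows.append({"radius": r, "AICc": aicc, "converged": True})
    if not rows:
        raise RuntimeError("no candidate radius produced a convergent fit")
    table = pd.DataFrame(rows).sort_values(["AICc", "radius"]).reset_index(drop=True)
    best_aicc = table["AICc"].iloc[0]
    tied = table[np.isclose(table["AICc"], best_aicc, rtol=0, atol=1e-9)]
    return ScaleSelection(
        chosen_radius=float(tied["radius"].min()),
        table=table,
        tie=len(tied) > 1,
        excluded=excluded,
    )


@dataclass
class LagCovariateMatrix:
    """Daily puma-lag indicators P1..Pk and their grid interactions.

    ``lags[k]`` is a sites x days 0/1 matrix: entry (i, t) is 1 iff the
    dominant species was detected at site i on any of days t-k+1 .. t, i.e.
    the detection day plus k-1 following days carry the effect.  Windows from
    multiple detections union; P1 <= P2 <= P3 <= P4 elementwise.
    """

    lags: dict[int, np.ndarray]
    interactions: dict[int, np.ndarray]
    sites: list[str]

    def column(self, name: str) -> np.ndarray:
        """Look up a lag or interaction matrix by name ('P3' or 'G*P3')."""
        name = name.replace(" ", "").replace(":", "*")
        m = re.fullmatch(r"(G\*)?P(\d+)", name)
        if not m:
            raise KeyError(name)
        k = int(m.group(2))
        if m.group(1):
            if not self.interactions:
                raise KeyError(f"{name}: no grid indicator was supplied")
            return self.interactions[k]
        return self.lags[k]


def build_lag_covariates(
    puma_history: DetectionHistory,
    grid: Sequence[int] | None = None,
    max_lag: int = 4,
) -> LagCovariateMatrix:
    """Build P1..P{max_lag} from the dominant species' daily history.

    The history must be daily (the lag covariates are daily constructs).
    Missing days in the dominant history count as no detection for lag
    purposes; windows truncate at the survey end.  When ``grid`` (0/1 per
    site) is given, interaction columns G*Pk = G x Pk are included.
    """
    if not puma_history.is_daily:
        raise ValueError("lag covariates require a daily (unpooled) history")
    det = np.nan_to_num(puma_history.Y, nan=0.0)
    n, t = det.shape
    lags: dict[int, np.ndarray] = {}
    for k in range(1, max_lag + 1):
        P = np.zeros((n, t))
        for shift in range(k):
            P[:, shift:] = np.maximum(P[:, shift:], det[:, : t - shift])
        lags[k] = P
    interactions: dict[int, np.ndarray] = {}
    if grid is not None:
        g = np.asarray(grid, dtype=float).reshape(-1, 1)
        if g.shape[0] != n:
            raise ValueError("grid vector length does not match site count")
        interactions = {k: g * P for k, P in lags.items()}
    return LagCovariateMatrix(lags, interactions, list(puma_history.sites))


@dataclass
class StandardizeTransform:
    """Per-column (mean, sd) used to z-score continuous covariates."""

    means: pd.Series
    sds: pd.Series

    def unscale_coef(self, column: str, beta_std: float) -> float:
        """Convert a slope on the standardized scale back to raw units."""
        return beta_std / self.sds[column]

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means.index:
            out[col] = (out[col] - self.means[col]) / self.sds[col]
        return out


def standardize(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, StandardizeTransform]:
    """Z-score the named continuous columns; binary columns are untouched.

    Columns are auto-detected as continuous when not supplied (more than two
    distinct values).  Zero-variance columns are left unscaled with a
    warning.  Returns the transformed table and the transform record.
    """
    if columns is None:
        columns = [
            c
            for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c]) and table[c].nunique() > 2
        ]
    means, sds = {}, {}
    out = table.copy()
    for col in columns:
        mu = float(table[col].mean())
        sd = float(table[col].std(ddof=0))
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"column {col!r} has zero variance; left unscaled", stacklevel=2)
            continue
        out[col] = (table[col] - mu) / sd
        means[col] = mu
        sds[col] = sd
    return out, StandardizeTransform(pd.Series(means), pd.Series(sds))
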