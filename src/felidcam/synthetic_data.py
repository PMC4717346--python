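"""Synthetic camera-trap data with the statistical structure the pipeline assumes.

The generator emulates a two-study-area camera survey for a dominant (puma)
and a subordinate (bobcat) felid:

* a landscape of two 80 km^2 sampling grids of 20 sites each (one site per
  2 x 2 km cell), one grid urbanized and one wildland, with human structure
  points (HOPs) drawn from a Poisson process whose intensity differs by grid;
* latent two-species occupancy with optional conditional dependence
  (psiBA vs psiBa);
* daily detection on the logit scale with a human-development effect, and a
  multiplicative suppression of the subordinate's daily detection for a fixed
  number of days after each dominant detection, on the wildland grid only
  (the short-term avoidance mechanism the fine-scale models are built to
  detect);
* detection timestamps drawn from species-specific bimodal von Mises
  circadian mixtures (subordinate crepuscular, dominant evening/nocturnal);
* optional sub-hour "burst" photographs around each event to exercise the
  independence filter.

Every draw flows from a single seed, and the returned truth record stores the
latent states and parameters so that estimators can be checked against known
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .camera_records import Deployment, PhotoRecord, SurveyDesign
from .occupancy_twospecies import TwoSpeciesParams

__all__ = [
    "VonMisesMixture",
    "LagAvoidance",
    "SimulationConfig",
    "Landscape",
    "simulate_landscape",
    "simulate_detection_data",
    "write_fixture",
]

KM = 1000.0  # metres


@dataclass(frozen=True)
class VonMisesMixture:
    """Circadian activity distribution as a mixture of von Mises components.

    Component means are clock hours (0-24); concentrations kappa control the
    peak sharpness; weights sum to 1.
    """

    means_hours: tuple[float, ...]
    kappas: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if not (len(self.means_hours) == len(self.kappas) == len(self.weights)):
            raise ValueError("mixture component lists must have equal length")

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample clock times in radians on [0, 2*pi)."""
        comp = rng.choice(len(self.weights), size=n, p=list(self.weights))
        mus = 2 * np.pi * np.asarray(self.means_hours) / 24.0
        out = np.empty(n)
        for c in range(len(self.weights)):
            m = comp == c
            out[m] = rng.vonmises(mus[c], self.kappas[c], size=int(m.sum()))
        return out % (2 * np.pi)

    def pdf(self, theta: np.ndarray) -> np.ndarray:
        from scipy.stats import vonmises

        theta = np.asarray(theta, dtype=float)
        mus = 2 * np.pi * np.asarray(self.means_hours) / 24.0
        return sum(
            w * vonmises.pdf(theta, kappa=k, loc=mu)
            for w, k, mu in zip(self.weights, self.kappas, mus)
        )


@dataclass(frozen=True)
class LagAvoidance:
    """Short-term suppression of the subordinate after a dominant visit.

    For ``length_days`` days starting with the day of each dominant
    detection, the subordinate's daily detection probability is multiplied by
    ``suppression`` (0 = complete avoidance, 1 = no effect) on the grids
    named in ``grids_affected``.
    """

    length_days: int = 3
    suppression: float = 0.0
    grids_affected: tuple[str, ...] = ("wildland",)

    def __post_init__(self) -> None:
        if self.length_days < 0:
            raise ValueError("length_days must be >= 0")
        if not (0.0 <= self.suppression <= 1.0):
            raise ValueError("suppression multiplier must lie in [0, 1]")


# Default daily rates reflect the photographic rates of a realistic felid
# camera survey: the dominant species averages about 3 independent events per
# occupied site over a ~3-month survey (daily detection ~0.03) and the
# subordinate about 4-5 (daily ~0.045); dominant occupancy is moderate
# (~0.6) and subordinate occupancy high (~0.85), independent of the dominant
# by default.
DEFAULT_TRUTH = TwoSpeciesParams(
    psiA=0.6, psiBA=0.85, psiBa=0.85, pA=0.03, rA=0.03, pB=0.045, rBA=0.045, rBa=0.045
)

DEFAULT_ACTIVITY = {
    # subordinate: crepuscular bimodal (morning + evening peaks)
    "bobcat": VonMisesMixture((6.0, 20.0), (2.0, 2.0), (0.5, 0.5)),
    # dominant: evening/nocturnal
    "puma": VonMisesMixture((21.0, 2.0), (2.0, 2.0), (0.6, 0.4)),
}


@dataclass
class SimulationConfig:
    n_sites_per_grid: int = 20
    grid_names: tuple[str, str] = ("urbanized", "wildland")
    survey_start: date = date(2010, 10, 1)
    survey_end: date = date(2010, 12, 31)  # 92 daily occasions
    truth: TwoSpeciesParams = DEFAULT_TRUTH
    lag_avoidance: LagAvoidance = field(default_factory=LagAvoidance)
    activity: dict[str, VonMisesMixture] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY)
    )
    # HOP Poisson intensities per km^2: dense residential development on the
    # urbanized grid, nearly none in wildland.
    hop_intensity_per_km2: dict[str, float] = field(
        default_factory=lambda: {"urbanized": 2.0, "wildland": 0.05}
    )
    beta_hd: float = -0.4  # standardized human-development effect on logit(p)
    hd_radius_m: float = 200.0
    # Burst model: extra photographs within the hour after each event.
    burst_prob: float = 0.3
    burst_max_extra: int = 2
    species_a: str = "puma"
    species_b: str = "bobcat"

    @property
    def design(self) -> SurveyDesign:
        return SurveyDesign(self.survey_start, self.survey_end)

    @property
    def n_sites(self) -> int:
        return self.n_sites_per_grid * len(self.grid_names)


@dataclass
class Landscape:
    sites: pd.DataFrame  # site_id, x, y, grid (index: site order)
    hops: np.ndarray  # (n, 2) structure coordinates, metres
    grid_indicator: pd.Series  # 0 = wildland, 1 = urbanized, by site_id


def simulate_landscape(config: SimulationConfig, seed: int) -> Landscape:
    """Lay out one site per 2 x 2 km cell and draw structure points per grid.

    Each grid is a 10 x 4 km rectangle of twenty 2 x 2 km cells (80 km^2),
    the two grids offset by 6 km; cameras sit at jittered cell centres.  HOPs
    follow a homogeneous Poisson process within each grid at the configured
    intensity.
    """
    rng = np.random.default_rng(seed)
    ncols, nrows = 5, 4  # 5 x 4 cells of 2 km = 10 x 8 km per grid... see below
    # 20 cells: 5 columns x 4 rows of 2x2 km -> 10 x 8 km = 80 km^2
    rows = []
    hop_list = []
    for gi, grid in enumerate(config.grid_names):
        x0 = gi * (ncols * 2 * KM + 6 * KM)  # grids ~6 km apart
        for c in range(ncols):
            for r in range(nrows):
                cx = x0 + (c + 0.5) * 2 * KM + rng.uniform(-300, 300)
                cy = (r + 0.5) * 2 * KM + rng.uniform(-300, 300)
                rows.append(
                    {
                        "site_id": f"{grid[:2].upper()}{c * nrows + r + 1:02d}",
                        "x": cx,
                        "y": cy,
                        "grid": grid,
                    }
                )
        area_km2 = ncols * nrows * 4.0
        lam = config.hop_intensity_per_km2.get(grid, 0.0) * area_km2
        n_hops = rng.poisson(lam)
        hx = rng.uniform(x0, x0 + ncols * 2 * KM, size=n_hops)
        hy = rng.uniform(0, nrows * 2 * KM, size=n_hops)
        hop_list.append(np.column_stack([hx, hy]))
    sites = pd.DataFrame(rows).set_index("site_id")
    hops = np.vstack(hop_list) if hop_list else np.empty((0, 2))
    grid_ind = (sites["grid"] == "urbanized").astype(int)
    return Landscape(sites=sites, hops=hops, grid_indicator=grid_ind)


def _standardized_hd(config: SimulationConfig, landscape: Landscape) -> pd.Series:
    from .covariates import StructurePointSet, hop_kernel_density

    pts = StructurePointSet(landscape.hops)
    raw = landscape.sites.apply(
        lambda row: hop_kernel_density(pts, (row["x"], row["y"]), config.hd_radius_m),
        axis=1,
    )
    sd = raw.std(ddof=0)
    return (raw - raw.mean()) / sd if sd > 0 else raw * 0.0


def simulate_detection_data(
    config: SimulationConfig,
    landscape: Landscape,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw latent occupancy, daily detections and photo timestamps.

    Returns ``(photos, deployments, truth)``: a photo-record table in the
    pipeline's CSV schema, a deployment table covering the whole survey at
    every site, and a truth record with latent states, the daily detection
    matrices and independent-event counts per site and species.
    """
    rng = np.random.default_rng(seed)
    tr = config.truth
    design = config.design
    t = design.n_daily_occasions
    sites = landscape.sites
    n = len(sites)
    hd = _standardized_hd(config, landscape)

    zA = rng.random(n) < tr.psiA
    psiB_cond = np.where(zA, tr.psiBA, tr.psiBa)
    zB = rng.random(n) < psiB_cond

    from scipy.special import expit, logit

    pA_daily = expit(logit(tr.pA) + config.beta_hd * hd.to_numpy())
    pB_base = expit(logit(tr.pB) + config.beta_hd * hd.to_numpy())

    detA = np.zeros((n, t), dtype=int)
    detB = np.zeros((n, t), dtype=int)
    lag = config.lag_avoidance
    affected = sites["grid"].isin(lag.grids_affected).to_numpy()

    for i in range(n):
        if zA[i]:
            detA[i] = rng.random(t) < pA_daily[i]
        if zB[i]:
            pB_t = np.full(t, pB_base[i])
            if affected[i] and lag.length_days > 0:
                suppressed = np.zeros(t, dtype=bool)
                for d in np.flatnonzero(detA[i]):
                    suppressed[d : d + lag.length_days] = True
                pB_t = np.where(suppressed, pB_t * lag.suppression, pB_t)
            detB[i] = rng.random(t) < pB_t

    photos = _timestamps_for_detections(config, sites, detA, detB, rng)
    deployments = pd.DataFrame(
        {
            "site_id": sites.index,
            "start": datetime.combine(design.survey_start_date, design.day_boundary),
            "end": datetime.combine(
                design.survey_end_date + timedelta(days=1), design.day_boundary
            ),
        }
    )
    truth = {
        "params": asdict(tr),
        "lag_avoidance": asdict(lag),
        "beta_hd": config.beta_hd,
        "zA": zA.astype(int).tolist(),
        "zB": zB.astype(int).tolist(),
        "detA": detA.tolist(),
        "detB": detB.tolist(),
        "event_counts": {
            config.species_a: dict(zip(sites.index, detA.sum(axis=1).tolist())),
            config.species_b: dict(zip(sites.index, detB.sum(axis=1).tolist())),
        },
        "hd_standardized": dict(zip(sites.index, hd.tolist())),
    }
    return photos, deployments, truth


def _timestamps_for_detections(
    config: SimulationConfig,
    sites: pd.DataFrame,
    detA: np.ndarray,
    detB: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign circadian-mixture timestamps (and bursts) to daily detections.

    A clock time at or after the noon day boundary lands on the occasion's
    first calendar day, an earlier one on the following day, so each
    timestamp falls inside its noon-to-noon occasion.
    """
    design = config.design
    rows: list[dict] = []
    for species, det in ((config.species_a, detA), (config.species_b, detB)):
        mixture = config.activity[species]
        last_ts: dict[int, datetime] = {}
        site_idx, day_idx = np.nonzero(det)
        for (i, d) in zip(site_idx, day_idx):
            # Redraw times that land within the independence window of the
            # previous day's event at this site, so each daily detection maps
            # to exactly one independent event after filtering.
            for _ in range(200):
                theta = float(mixture.rvs(1, rng)[0])
                secs = theta / (2 * np.pi) * 86400.0
                day = design.survey_start_date + timedelta(days=int(d))
                if secs < 12 * 3600:
                    day = day + timedelta(days=1)
                ts = datetime.combine(day, time(0, 0)) + timedelta(seconds=round(secs))
                prev = last_ts.get(i)
                if prev is None or ts - prev > timedelta(minutes=61):
                    break
            last_ts[i] = ts
            rows.append(
                {
                    "site_id": sites.index[i],
                    "species": species,
                    "timestamp": ts,
                    "individual_id": "",
                    "dependent_young": 0,
                }
            )
            if rng.random() < config.burst_prob:
                for _ in range(rng.integers(1, config.burst_max_extra + 1)):
                    offset = timedelta(seconds=round(rng.uniform(30.0, 55 * 60.0)))
                    rows.append(
                        {
                            "site_id": sites.index[i],
                            "species": species,
                            "timestamp": ts + offset,
                            "individual_id": "",
                            "dependent_young": 0,
                        }
                    )
    photos = pd.DataFrame(
        rows, columns=["site_id", "species", "timestamp", "individual_id", "dependent_young"]
    )
    return photos.sort_values(["timestamp", "site_id", "species"]).reset_index(drop=True)


@dataclass
class SimulatedSurvey:
    """One fully processed synthetic survey: events, histories, covariates, truth."""

    config: SimulationConfig
    landscape: Landscape
    photos: pd.DataFrame
    deployments: list[Deployment]
    events: list
    daily_a: "object"  # DetectionHistory of the dominant species
    daily_b: "object"  # DetectionHistory of the subordinate species
    covariates: "object"  # CovariateSet with site table (G, HD, PumaCount) and lags
    truth: dict


def simulate_survey(config: SimulationConfig, seed: int) -> SimulatedSurvey:
    """Simulate and run the full data-engineering chain on one survey.

    Produces photo records, filters them for independence, builds daily
    detection histories for both species, and assembles the standardized site
    covariates (G, HD, PumaCount) plus the lag covariates from the dominant
    species' history — everything the occupancy fitters need.
    """
    from .camera_records import (
        PhotoRecord,
        assign_daily_occasions,
        event_count_by_site,
        filter_independent,
    )
    from .covariates import build_lag_covariates, standardize
    from .occupancy_single import CovariateSet

    landscape = simulate_landscape(config, seed)
    photos, dep_df, truth = simulate_detection_data(config, landscape, seed + 1)
    records = [
        PhotoRecord(
            timestamp=pd.Timestamp(r.timestamp).to_pydatetime(),
            site_id=str(r.site_id),
            species=str(r.species),
        )
        for r in photos.itertuples()
    ]
    events = filter_independent(records)
    deployments = [
        Deployment(str(r.site_id), pd.Timestamp(r.start).to_pydatetime(), pd.Timestamp(r.end).to_pydatetime())
        for r in dep_df.itertuples()
    ]
    design = config.design
    sites = list(landscape.sites.index)
    daily_a = assign_daily_occasions(events, design, deployments, sites=sites, species=config.species_a)
    daily_b = assign_daily_occasions(events, design, deployments, sites=sites, species=config.species_b)
    table = pd.DataFrame(index=landscape.sites.index)
    table["G"] = landscape.grid_indicator
    table["HD"] = pd.Series(truth["hd_standardized"])
    table["PumaCount"] = event_count_by_site(events, config.species_a, sites)
    std, _ = standardize(table, ["PumaCount"])
    cov = CovariateSet(site=std, lags=build_lag_covariates(daily_a, grid=std["G"].to_numpy()))
    return SimulatedSurvey(
        config=config,
        landscape=landscape,
        photos=photos,
        deployments=deployments,
        events=events,
        daily_a=daily_a,
        daily_b=daily_b,
        covariates=cov,
        truth=truth,
    )


def write_fixture(
    photos: pd.DataFrame,
    deployments: pd.DataFrame,
    landscape: Landscape,
    directory: str | Path,
    truth: dict | None = None,
) -> dict[str, Path]:
    """Write the simulated tables in the CSV formats the pipeline consumes."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "photos": directory / "photo_records.csv",
        "deployments": directory / "deployments.csv",
        "sites": directory / "sites.csv",
        "hops": directory / "hops.csv",
    }
    out = photos.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(paths["photos"], index=False)
    dep = deployments.copy()
    for col in ("start", "end"):
        dep[col] = pd.to_datetime(dep[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    dep.to_csv(paths["deployments"], index=False)
    landscape.sites.reset_index().to_csv(paths["sites"], index=False, float_format="%.3f")
    pd.DataFrame(landscape.hops, columns=["x", "y"]).to_csv(
        paths["hops"], index=False, float_format="%.3f"
    )
    if truth is not None:
        paths["truth"] = directory / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
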