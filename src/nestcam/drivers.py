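"""Breeding-success drivers: precipitation events, krill catch, tourism.

Covariate construction
----------------------
* Precipitation: images are scored R1-R3 (rain) / S1-S3 (snow) per causative
  event; the per-site/year covariate is the count of events of magnitude 2
  or more, rain and snow pooled.
* Krill catch: monthly catches reported per management-unit polygon (SSMU,
  WGS84) are combined into a site-level figure by area-weighting each unit
  with the fraction of a 150-km geodesic buffer around the site it covers,
  then summing over the 11 months from March of the year before the season
  ends through January of the ending year.  Buffers and overlay areas are
  computed in a spherical Lambert azimuthal equal-area projection centered
  on the site (a circle about the projection center is exactly the geodesic
  disc, and areas are preserved).
* Tourism: visitors summed over the extrapolated lay date through crèche
  date, both endpoints inclusive.

Regression
----------
Each driver enters its own Bayesian errors-in-variables regression

    bs_obs_i ~ N(bs_true_i, sigma_bs_i)       (sigma_bs_i known)
    bs_true_i ~ N(alpha + beta * x_i, sigma)

fit by Gibbs sampling: the latent true values and (alpha, beta) have
conjugate normal full conditionals; the residual sd sigma (half-Normal
prior) is updated by slice sampling on log sigma.  The krill covariate is
log-transformed; zero catches receive a configurable additive offset
(default: half the smallest positive catch) recorded in the fit metadata.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, Point, shape
from shapely import transform as shp_transform

from .geometry import SEASON_LENGTH, _as_date

logger = logging.getLogger(__name__)

__all__ = [
    "PrecipScore", "SsmuCatch", "count_precip_events", "read_precip_scores",
    "krill_buffer_catch", "buffer_weights", "krill_window_months",
    "tourism_window_count", "build_driver_table",
    "RegressionPriors", "RegressionPosterior", "fit_driver_regression",
    "event_overlay_export", "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

VALID_KINDS = ("rain", "snow")


@dataclass
class PrecipScore:
    """One scored precipitation event."""

    date: dt.date
    kind: str
    magnitude: int

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.magnitude not in (1, 2, 3):
            raise ValueError(
                f"magnitude must be 1, 2 or 3 (R1-R3/S1-S3); got {self.magnitude}")


def count_precip_events(scores: Sequence[PrecipScore] | pd.DataFrame,
                        min_magnitude: int = 2) -> int:
    """Count precipitation events at or above ``min_magnitude`` (default 2:
    R2, R3, S2, S3), rain and snow pooled."""
    if isinstance(scores, pd.DataFrame):
        scores = [
            PrecipScore(date=_as_date(r.date), kind=str(r.kind),
                        magnitude=int(r.magnitude))
            for r in scores.itertuples()
        ]
    else:
        scores = list(scores)
    return sum(1 for s in scores if s.magnitude >= min_magnitude)


def read_precip_scores(path) -> pd.DataFrame:
    """Precipitation CSV: site_id, year_id, date, kind, magnitude."""
    df = pd.read_csv(path)
    for r in df.itertuples():
        PrecipScore(date=_as_date(r.date), kind=str(r.kind), magnitude=int(r.magnitude))
    return df


# ---------------------------------------------------------------------------
# krill catch within a geodesic buffer
# ---------------------------------------------------------------------------


@dataclass
class SsmuCatch:
    """A management-unit polygon with its monthly catch records."""

    ssmu_id: str
    polygon: Polygon             # WGS84 lon/lat
    monthly_catch: Mapping[tuple[int, int], float]  # (year, month) -> tonnes

    def __post_init__(self):
        if not self.polygon.is_valid:
            raise ValueError(f"SSMU {self.ssmu_id}: invalid (self-intersecting?) polygon")
        if any(v < 0 for v in self.monthly_catch.values()):
            raise ValueError(f"SSMU {self.ssmu_id}: negative catch")

    def window_total(self, months: Sequence[tuple[int, int]]) -> float:
        return float(sum(self.monthly_catch.get(m, 0.0) for m in months))


def _laea(lon0: float, lat0: float):
    """Forward spherical Lambert azimuthal equal-area projection centered
    at (lon0, lat0); input/output in degrees/kilometers."""
    lam0 = np.radians(lon0)
    phi0 = np.radians(lat0)

    def fwd(coords: np.ndarray) -> np.ndarray:
        lam = np.radians(coords[:, 0])
        phi = np.radians(coords[:, 1])
        dl = lam - lam0
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dl)
        k = np.sqrt(2.0 / np.maximum(denom, 1e-12))
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dl)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dl))
        return np.c_[x, y]

    return fwd


def buffer_weights(
    site_lonlat: tuple[float, float],
    ssmus: Sequence[SsmuCatch],
    radius_km: float = 150.0,
    quad_segs: int = 256,
) -> dict[str, float]:
    """Fraction of the geodesic buffer around a site covered by each SSMU.

    Weights are proportions of the *total* buffer area, so they sum to at
    most 1 and to exactly 1 when the units tile the buffer.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    fwd = _laea(*site_lonlat)
    disc = Point(0.0, 0.0).buffer(radius_km, quad_segs=quad_segs)
    area = disc.area
    weights = {}
    for s in ssmus:
        proj = shp_transform(s.polygon, fwd)
        weights[s.ssmu_id] = proj.intersection(disc).area / area
    return weights


def krill_window_months(season_end_year: int) -> list[tuple[int, int]]:
    """Calendar months from March of the previous year through January of
    ``season_end_year`` (11 months: catch before and during the season)."""
    return [(season_end_year - 1, m) for m in range(3, 13)] + [(season_end_year, 1)]


def krill_buffer_catch(
    site_lonlat: tuple[float, float],
    ssmus: Sequence[SsmuCatch],
    season_end_year: int,
    radius_km: float = 150.0,
    months: Sequence[tuple[int, int]] | None = None,
) -> float:
    """Buffer-weighted krill catch (tonnes) for one site and season.

    Each month's site-level catch is the weighted average of SSMU catches
    with buffer-area weights; the return value sums those over the window.
    A site whose buffer overlaps no unit returns 0 with a warning (the
    uncovered area implicitly contributes zero catch).
    """
    w = buffer_weights(site_lonlat, ssmus, radius_km=radius_km)
    if months is None:
        months = krill_window_months(season_end_year)
    total = sum(w[s.ssmu_id] * s.window_total(months) for s in ssmus)
    if all(v == 0.0 for v in w.values()):
        warnings.warn(
            f"site at {site_lonlat} has zero SSMU overlap within "
            f"{radius_km} km; krill catch set to 0", stacklevel=2)
    return float(total)


def load_ssmus(geojson: dict, catch: pd.DataFrame) -> list[SsmuCatch]:
    """Build SSMU records from a GeoJSON FeatureCollection (property
    ``ssmu_id``) and a catch table (ssmu_id, year, month, tonnes)."""
    out = []
    for feat in geojson["features"]:
        sid = str(feat["properties"]["ssmu_id"])
        poly = shape(feat["geometry"])
        rows = catch[catch["ssmu_id"].astype(str) == sid]
        monthly = {(int(r.year), int(r.month)): float(r.tonnes)
                   for r in rows.itertuples()}
        out.append(SsmuCatch(ssmu_id=sid, polygon=poly, monthly_catch=monthly))
    return out


# ---------------------------------------------------------------------------
# tourism
# ---------------------------------------------------------------------------


def tourism_window_count(
    visits: pd.DataFrame, lay_date: dt.date, creche_date: dt.date
) -> int:
    """Total visitors between lay date and crèche date, inclusive.

    ``visits`` has columns ``date`` and ``visitors``.
    """
    lay_date = _as_date(lay_date)
    creche_date = _as_date(creche_date)
    if lay_date > creche_date:
        raise ValueError("lay_date must not be after creche_date")
    if len(visits) == 0:
        return 0
    dates = pd.to_datetime(visits["date"]).dt.date
    sel = (dates >= lay_date) & (dates <= creche_date)
    return int(visits.loc[sel, "visitors"].sum())


# ---------------------------------------------------------------------------
# driver table and errors-in-variables regression
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = {
    "precipitation": "precip_events",
    "krill": "log_krill_catch",
    "tourism": "tourists",
}


def build_driver_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble the per-site/year driver table.

    Each row supplies site_id, year_id, bs_obs, sigma_bs, precip_events,
    krill_catch, tourists; the log-krill column is added here with the
    zero-catch offset rule (half the smallest positive catch), recorded in
    ``DataFrame.attrs['krill_log_offset']``.
    """
    df = pd.DataFrame(list(rows))
    if (df["sigma_bs"] <= 0).any():
        raise ValueError("sigma_bs must be positive for every site/year")
    catches = df["krill_catch"].to_numpy(dtype=float)
    if (catches < 0).any():
        raise ValueError("krill_catch must be non-negative")
    offset = 0.0
    if (catches == 0).any():
        positive = catches[catches > 0]
        if positive.size == 0:
            # leave the log column undefined; the krill regression raises
            # the actionable error if it is actually requested
            df["log_krill_catch"] = np.nan
            df.attrs["krill_log_offset"] = None
            return df
        offset = float(positive.min() / 2.0)
        logger.info("zero krill catches present; using log offset %.6g", offset)
    df["log_krill_catch"] = np.log(catches + offset)
    df.attrs["krill_log_offset"] = offset
    return df


@dataclass
class RegressionPriors:
    alpha_sd: float = 10.0
    beta_sd: float = 10.0
    sigma_scale: float = 1.0   # half-Normal prior scale for residual sd


@dataclass
class RegressionPosterior:
    """Posterior draws for the errors-in-variables regression."""

    covariate: str
    draws: dict[str, np.ndarray]    # alpha, beta, sigma: (chains, n); bs_true: (chains, n, n_pts)
    rhat: dict[str, float]
    ess: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    def to_frame(self) -> pd.DataFrame:
        """Tidy draw table: chain, draw, parameter, value."""
        rows = []
        for name in ("alpha", "beta", "sigma"):
            d = self.draws[name]
            for c in range(d.shape[0]):
                rows.append(pd.DataFrame(
                    {"chain": c, "draw": np.arange(d.shape[1]),
                     "parameter": name, "value": d[c]}))
        bt = self.draws["bs_true"]
        for k in range(bt.shape[2]):
            for c in range(bt.shape[0]):
                rows.append(pd.DataFrame(
                    {"chain": c, "draw": np.arange(bt.shape[1]),
                     "parameter": f"bs_true[{k}]", "value": bt[c, :, k]}))
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> dict:
        """Median slope and central 95% credible interval, as reported."""
        beta = self.flat("beta")
        alpha = self.flat("alpha")
        return {
            "covariate": self.covariate,
            "beta_median": float(np.median(beta)),
            "beta_ci95": [float(np.quantile(beta, 0.025)),
                          float(np.quantile(beta, 0.975))],
            "alpha_median": float(np.median(alpha)),
            "max_rhat": max(self.rhat.values()),
            "min_ess": min(self.ess.values()),
            **self.metadata,
        }


def _slice_sample_log_sigma(rng, log_sigma, logpost, w=1.0, max_steps=50):
    """Univariate stepping-out slice sampler on log sigma."""
    y = logpost(log_sigma) + np.log(rng.random())
    lo = log_sigma - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logpost(lo) <= y:
            break
        lo -= w
    for _ in range(max_steps):
        if logpost(hi) <= y:
            break
        hi += w
    for _ in range(max_steps):
        prop = lo + (hi - lo) * rng.random()
        if logpost(prop) > y:
            return prop
        if prop < log_sigma:
            lo = prop
        else:
            hi = prop
    return log_sigma


def fit_driver_regression(
    table: pd.DataFrame,
    covariate: str,
    priors: RegressionPriors | None = None,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_samples: int = 2500,
    rng_seed: int = 0,
    sigma_fixed: float | None = None,
    standardize: bool = False,
) -> RegressionPosterior:
    """Fit one driver's errors-in-variables regression by Gibbs sampling.

    ``covariate`` is ``precipitation``, ``krill`` or ``tourism`` (mapping to
    the raw event count, log catch, and visitor count respectively) or any
    column of ``table``.  ``sigma_fixed`` pins the residual sd instead of
    sampling it (useful for conjugate cross-checks).  Covariates are used on
    their raw scale unless ``standardize`` is set.
    """
    priors = priors or RegressionPriors()
    col = COVARIATE_COLUMNS.get(covariate, covariate)
    if col not in table.columns:
        raise KeyError(f"covariate column {col!r} not in driver table")
    if len(table) < 3:
        raise ValueError("need at least 3 site/years for the regression")
    x = table[col].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError(
            f"covariate {col!r} contains undefined values (all-zero krill "
            "catch under the log transform?); supply positive catches or an "
            "explicit offset")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=0)
    bs_obs = table["bs_obs"].to_numpy(dtype=float)
    sigma_bs = table["sigma_bs"].to_numpy(dtype=float)
    if (sigma_bs < 0).any():
        raise ValueError("sigma_bs must be >= 0")
    n = len(x)
    X = np.c_[np.ones(n), x]
    prior_prec = np.diag([priors.alpha_sd**-2, priors.beta_sd**-2])

    seeds = np.random.SeedSequence(rng_seed).generate_state(n_chains)
    chains = {k: [] for k in ("alpha", "beta", "sigma", "bs_true")}
    for cs in seeds:
        rng = np.random.default_rng(int(cs) % (2**31))
        a, b = rng.normal(0, 1, 2)
        sigma = sigma_fixed if sigma_fixed is not None else abs(rng.normal(0, 0.5)) + 0.05
        bs_true = bs_obs.copy()
        keep = {k: np.empty(n_samples if k != "bs_true" else (n_samples, n))
                for k in chains}
        for it in range(n_warmup + n_samples):
            mu = a + b * x
            # latent true breeding success: conjugate normal; a known error
            # of zero pins the latent value to the observation
            zero = sigma_bs == 0
            nz = ~zero
            m = np.empty(n)
            sd = np.zeros(n)
            m[zero] = bs_obs[zero]
            prec = sigma_bs[nz] ** -2.0 + sigma**-2
            m[nz] = (bs_obs[nz] / sigma_bs[nz] ** 2 + mu[nz] / sigma**2) / prec
            sd[nz] = prec**-0.5
            bs_true = m + sd * rng.standard_normal(n)
            # (alpha, beta): conjugate bivariate normal
            Lam = X.T @ X / sigma**2 + prior_prec
            rhs = X.T @ bs_true / sigma**2
            cov = np.linalg.inv(Lam)
            mean = cov @ rhs
            a, b = rng.multivariate_normal(mean, cov)
            # residual sd: slice sample on log sigma (half-Normal prior)
            if sigma_fixed is None:
                resid2 = ((bs_true - a - b * x) ** 2).sum()

                def logpost(ls):
                    s2 = np.exp(2 * ls)
                    return (-n * ls - resid2 / (2 * s2)
                            - s2 / (2 * priors.sigma_scale**2) + ls)

                sigma = float(np.exp(_slice_sample_log_sigma(
                    rng, np.log(sigma), logpost)))
            if it >= n_warmup:
                j = it - n_warmup
                keep["alpha"][j] = a
                keep["beta"][j] = b
                keep["sigma"][j] = sigma
                keep["bs_true"][j] = bs_true
        for k in chains:
            chains[k].append(keep[k])
    draws = {k: np.stack(v) for k, v in chains.items()}

    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        diag_vars = {k: draws[k] for k in ("alpha", "beta", "sigma")}
        if sigma_fixed is not None:
            del diag_vars["sigma"]
        idata = az.from_dict(diag_vars)
        rhat = {v: float(np.asarray(az.rhat(idata)[v]).max())
                for v in diag_vars}
        ess = {v: float(np.asarray(az.ess(idata)[v]).min()) for v in diag_vars}
    meta = {"n_site_years": n, "standardized": standardize}
    if covariate == "krill" and "krill_log_offset" in table.attrs:
        meta["krill_log_offset"] = table.attrs["krill_log_offset"]
    if sigma_fixed is not None:
        meta["sigma_fixed"] = sigma_fixed
    return RegressionPosterior(covariate=covariate, draws=draws,
                               rhat=rhat, ess=ess, metadata=meta)


# ---------------------------------------------------------------------------
# event overlay export
# ---------------------------------------------------------------------------


def event_overlay_export(
    z_mean, z_sd, precip_scores: pd.DataFrame | None = None,
    lay_date: dt.date | None = None,
) -> pd.DataFrame:
    """Long-format table (day 1..60, Z mean, Z sd, event kind/magnitude)
    for overlaying storm events on the chick-total trajectory.

    ``precip_scores`` may carry a ``day`` column directly, or ``date``
    columns resolved against ``lay_date``.
    """
    z_mean = np.asarray(z_mean, dtype=float)
    z_sd = np.asarray(z_sd, dtype=float)
    if z_mean.shape != (SEASON_LENGTH,) or z_sd.shape != (SEASON_LENGTH,):
        raise ValueError(f"trajectory summaries must have length {SEASON_LENGTH}")
    out = pd.DataFrame({
        "day": np.arange(1, SEASON_LENGTH + 1),
        "z_mean": z_mean,
        "z_sd": z_sd,
        "event_kind": pd.Series([pd.NA] * SEASON_LENGTH, dtype="object"),
        "event_magnitude": pd.Series([pd.NA] * SEASON_LENGTH, dtype="object"),
    })
    if precip_scores is not None and len(precip_scores):
        for r in precip_scores.itertuples():
            if hasattr(r, "day") and not pd.isna(r.day):
                day = int(r.day)
            else:
                if lay_date is None:
                    raise ValueError("lay_date required to resolve event dates")
                day = (_as_date(r.date) - _as_date(lay_date)).days
            if 1 <= day <= SEASON_LENGTH:
                out.loc[day - 1, "event_kind"] = str(r.kind)
                out.loc[day - 1, "event_magnitude"] = int(r.magnitude)
    return out
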