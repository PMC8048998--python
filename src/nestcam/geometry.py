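"""Nest zones, detection assignment, and daily observation series.

A fixed time-lapse camera watches a colony; each annotated nest location
("seed", in image pixel coordinates) owns the Voronoi cell of pixels closer
to it than to any other seed.  Chick detections (pixel points per image)
are assigned to the nest whose zone contains them, hourly counts are
collapsed to a daily maximum, and the daily counts are laid out on the
60-day model timeline anchored at the extrapolated lay date (crèche date
minus 60 days).

Coordinate convention: origin at the image top-left, x rightward,
y downward, units are pixels (floats).  Boundary ties in assignment go to
the lower nest id; this is deterministic and documented here once.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box, mapping

logger = logging.getLogger(__name__)

#: length of the modeled breeding timeline in days (lay date to crèche)
SEASON_LENGTH = 60

#: maximum chicks per nest (two-egg clutch)
CLUTCH_SIZE = 2


@dataclass
class NestMap:
    """Voronoi partition of one camera frame into per-nest zones."""

    site_id: str
    year_id: str
    frame_width: float
    frame_height: float
    seeds: list[tuple[str, float, float]]
    zones: dict[str, Polygon] = field(repr=False)

    @property
    def nest_ids(self) -> list[str]:
        return [nid for nid, _, _ in self.seeds]

    def seed_array(self) -> np.ndarray:
        return np.array([[x, y] for _, x, y in self.seeds], dtype=float)

    def to_geojson(self) -> dict:
        """Zones as a GeoJSON FeatureCollection in pixel coordinates (QC aid)."""
        features = []
        for nid, x, y in self.seeds:
            features.append(
                {
                    "type": "Feature",
                    "properties": {"nest_id": nid, "seed_x": x, "seed_y": y},
                    "geometry": mapping(self.zones[nid]),
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)


@dataclass
class DetectionRecord:
    """Chick locations classified in a single image."""

    timestamp: dt.datetime
    points: list[tuple[float, float]]


def build_nest_zones(
    seeds: Sequence[tuple[str, float, float]],
    frame_width: float,
    frame_height: float,
    site_id: str = "",
    year_id: str = "",
) -> NestMap:
    """Partition the camera frame into Voronoi zones, one per nest seed.

    Every point of the frame rectangle belongs to the zone of its nearest
    seed (Euclidean distance in pixels).  Zones are clipped to the frame, so
    their areas sum to the frame area.

    Parameters
    ----------
    seeds
        ``(nest_id, x, y)`` triples; ids must be unique, points distinct and
        inside the frame.
    frame_width, frame_height
        Frame extent in pixels.

    Raises
    ------
    ValueError
        On duplicate seed coordinates (naming the offending pair), duplicate
        ids, or a seed outside the frame.
    """
    if len(seeds) < 1:
        raise ValueError("at least one nest seed is required")
    ids = [s[0] for s in seeds]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate nest ids: {dup}")
    pts = np.array([[x, y] for _, x, y in seeds], dtype=float)
    for a in range(len(seeds)):
        for b in range(a + 1, len(seeds)):
            if np.allclose(pts[a], pts[b]):
                raise ValueError(
                    f"duplicate seed coordinates for nests "
                    f"{ids[a]!r} and {ids[b]!r} at {tuple(pts[a])}"
                )
    for nid, x, y in seeds:
        if not (0 <= x <= frame_width and 0 <= y <= frame_height):
            raise ValueError(
                f"seed for nest {nid!r} at ({x}, {y}) lies outside the "
                f"{frame_width}x{frame_height} frame"
            )

    frame = box(0.0, 0.0, float(frame_width), float(frame_height))
    zones: dict[str, Polygon] = {}
    if len(seeds) == 1:
        zones[ids[0]] = frame
    else:
        # Ghost points far outside the frame bound every real cell; their
        # bisectors stay well clear of the frame, so clipping is exact.
        cx, cy = frame_width / 2.0, frame_height / 2.0
        radius = 100.0 * max(frame_width, frame_height, 1.0)
        ang = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        ghosts = np.c_[cx + radius * np.cos(ang), cy + radius * np.sin(ang)]
        vor = Voronoi(np.vstack([pts, ghosts]))
        for i, nid in enumerate(ids):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) == 0:  # pragma: no cover - ghosts prevent this
                raise RuntimeError("unbounded Voronoi cell; ghost ring too small")
            cell = Polygon(vor.vertices[region])
            zones[nid] = cell.intersection(frame)
    return NestMap(
        site_id=site_id,
        year_id=year_id,
        frame_width=float(frame_width),
        frame_height=float(frame_height),
        seeds=[(str(n), float(x), float(y)) for n, x, y in seeds],
        zones=zones,
    )


def assign_detections(
    record: DetectionRecord, nest_map: NestMap
) -> dict[str, int]:
    """Count detected chicks per nest zone, capped at the clutch size.

    Assignment is nearest-seed (identical to zone membership); a point
    equidistant from several seeds goes to the lowest nest id.  Counts above
    two chicks in a zone are capped at two with a logged warning, since the
    model assumes a two-egg clutch.
    """
    seeds = nest_map.seed_array()
    ids = nest_map.nest_ids
    counts = {nid: 0 for nid in ids}
    for x, y in record.points:
        if not (0 <= x <= nest_map.frame_width and 0 <= y <= nest_map.frame_height):
            raise ValueError(f"detection at ({x}, {y}) outside frame bounds")
        d2 = (seeds[:, 0] - x) ** 2 + (seeds[:, 1] - y) ** 2
        tied = np.flatnonzero(d2 <= d2.min() * (1 + 1e-12))
        nid = min(ids[i] for i in tied)
        counts[nid] += 1
    for nid, c in counts.items():
        if c > CLUTCH_SIZE:
            logger.warning(
                "capping count %d -> %d for nest %s at %s (clutch size %d)",
                c, CLUTCH_SIZE, nid, record.timestamp, CLUTCH_SIZE,
            )
            counts[nid] = CLUTCH_SIZE
    return counts


def aggregate_daily(hourly_counts: Iterable) -> float:
    """Collapse one nest's hourly counts for one day to the daily maximum.

    The daily value is the highest count seen in any image that day; a day
    with no usable images is missing (``nan``).  Accepts ``None``/``nan``
    for missing hours.
    """
    best = np.nan
    for v in hourly_counts:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        v = float(v)
        if not v.is_integer() or v < 0 or v > CLUTCH_SIZE:
            raise ValueError(f"hourly count {v} outside {{0,1,2}}")
        if np.isnan(best) or v > best:
            best = v
    return best


@dataclass
class ObservationSeries:
    """Daily observed chick counts for every nest of one site/year.

    ``y[t-1, i]`` is the count for model day ``t`` (1..60) and nest ``i``;
    ``nan`` marks missing.  Day ``t`` corresponds to calendar date
    ``lay_date + t`` days, so the crèche date lands exactly at t = 60 and
    the lay date itself (t = 0) is the unobserved two-egg initial state.
    """

    site_id: str
    year_id: str
    creche_date: dt.date
    nest_ids: list[str]
    y: np.ndarray  # (SEASON_LENGTH, n_nests) float, nan = missing

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (SEASON_LENGTH, len(self.nest_ids)):
            raise ValueError(
                f"y must be {SEASON_LENGTH} x n_nests; got {self.y.shape}"
            )
        vals = self.y[~np.isnan(self.y)]
        if vals.size and (
            (vals < 0).any() or (vals > CLUTCH_SIZE).any() or (vals % 1 != 0).any()
        ):
            raise ValueError("observed counts must be integers in {0,1,2}")

    @property
    def lay_date(self) -> dt.date:
        return self.creche_date - dt.timedelta(days=SEASON_LENGTH)

    @property
    def n_nests(self) -> int:
        return len(self.nest_ids)

    def date_of(self, t: int) -> dt.date:
        return self.lay_date + dt.timedelta(days=int(t))

    def n_observed(self) -> int:
        return int((~np.isnan(self.y)).sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: site_id, year_id, nest_id, t, date, count."""
        rows = []
        for j, nid in enumerate(self.nest_ids):
            for t in range(1, SEASON_LENGTH + 1):
                v = self.y[t - 1, j]
                rows.append(
                    {
                        "site_id": self.site_id,
                        "year_id": self.year_id,
                        "nest_id": nid,
                        "t": t,
                        "date": self.date_of(t).isoformat(),
                        "count": "" if np.isnan(v) else int(v),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ObservationSeries":
        site_id = str(frame["site_id"].iloc[0])
        year_id = str(frame["year_id"].iloc[0])
        nest_ids = list(dict.fromkeys(frame["nest_id"].astype(str)))
        dates = pd.to_datetime(frame["date"])
        t = frame["t"].astype(int)
        creche = (dates.iloc[0] - pd.Timedelta(days=int(t.iloc[0]))).date() + dt.timedelta(
            days=SEASON_LENGTH
        )
        y = np.full((SEASON_LENGTH, len(nest_ids)), np.nan)
        col = {nid: j for j, nid in enumerate(nest_ids)}
        cnt = pd.to_numeric(frame["count"], errors="coerce")
        for nid, ti, v in zip(frame["nest_id"].astype(str), t, cnt):
            if not np.isnan(v):
                y[ti - 1, col[nid]] = v
        return cls(site_id=site_id, year_id=year_id, creche_date=creche,
                   nest_ids=nest_ids, y=y)

    @classmethod
    def from_csv(cls, path) -> "ObservationSeries":
        return cls.from_frame(pd.read_csv(path, keep_default_na=True))


def build_observation_series(
    daily_counts: pd.DataFrame | Mapping,
    creche_date: dt.date,
    first_chick_date: dt.date,
    nest_ids: Sequence[str],
    site_id: str = "",
    year_id: str = "",
) -> ObservationSeries:
    """Place assigned daily counts onto the 60-day model timeline.

    ``daily_counts`` is a DataFrame with columns ``date, nest_id, count``
    (or a mapping ``(date, nest_id) -> count``).  Days before the first
    chick sighting are missing by construction (egg contents are not
    scored); any count dated before ``first_chick_date`` is dropped with a
    warning.  Dates outside ``(lay_date, creche_date]`` raise.
    """
    creche_date = _as_date(creche_date)
    first_chick_date = _as_date(first_chick_date)
    if first_chick_date > creche_date:
        raise ValueError("first_chick_date must not be after creche_date")
    lay_date = creche_date - dt.timedelta(days=SEASON_LENGTH)
    if first_chick_date <= lay_date:
        raise ValueError("first_chick_date must be after the extrapolated lay date")

    if isinstance(daily_counts, Mapping):
        items = [(d, n, c) for (d, n), c in daily_counts.items()]
    else:
        items = list(
            zip(daily_counts["date"], daily_counts["nest_id"], daily_counts["count"])
        )
    nest_ids = [str(n) for n in nest_ids]
    col = {nid: j for j, nid in enumerate(nest_ids)}
    y = np.full((SEASON_LENGTH, len(nest_ids)), np.nan)
    for date, nid, count in items:
        date = _as_date(date)
        t = (date - lay_date).days
        if t < 1 or t > SEASON_LENGTH:
            raise ValueError(
                f"count dated {date} falls outside the model window "
                f"({lay_date} .. {creche_date}]"
            )
        if count is None or (isinstance(count, float) and np.isnan(count)):
            continue
        if date < first_chick_date:
            logger.warning(
                "dropping count dated %s before first chick sighting %s",
                date, first_chick_date,
            )
            continue
        nid = str(nid)
        if nid not in col:
            raise ValueError(f"unknown nest id {nid!r}")
        y[t - 1, col[nid]] = float(count)
    return ObservationSeries(
        site_id=site_id, year_id=year_id, creche_date=creche_date,
        nest_ids=nest_ids, y=y,
    )


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.to_datetime(d).date()


def read_annotations(path) -> list[NestMap]:
    """Read nest-annotation CSV (site_id, year_id, nest_id, x_px, y_px,
    frame_w, frame_h) and build one :class:`NestMap` per site/year."""
    df = pd.read_csv(path)
    maps = []
    for (site, year), grp in df.groupby(["site_id", "year_id"], sort=True):
        seeds = [
            (str(r.nest_id), float(r.x_px), float(r.y_px))
            for r in grp.itertuples()
        ]
        fw = float(grp["frame_w"].iloc[0])
        fh = float(grp["frame_h"].iloc[0])
        maps.append(build_nest_zones(seeds, fw, fh, site_id=str(site), year_id=str(year)))
    return maps


def read_detections(path) -> pd.DataFrame:
    """Read detections CSV (site_id, year_id, timestamp, x_px, y_px)."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def detections_to_daily(
    detections: pd.DataFrame, nest_map: NestMap
) -> pd.DataFrame:
    """Assign a site/year's detections to zones and aggregate to daily
    maxima; returns a ``date, nest_id, count`` table."""
    sel = detections[
        (detections["site_id"].astype(str) == nest_map.site_id)
        & (detections["year_id"].astype(str) == nest_map.year_id)
    ]
    per_image: dict[tuple[dt.date, str], list[int]] = {}
    for ts, grp in sel.groupby("timestamp"):
        rec = DetectionRecord(
            timestamp=ts.to_pydatetime(),
            points=[(float(r.x_px), float(r.y_px)) for r in grp.itertuples()],
        )
        counts = assign_detections(rec, nest_map)
        day = ts.date()
        for nid, c in counts.items():
            per_image.setdefault((day, nid), []).append(c)
    rows = [
        {"date": day, "nest_id": nid, "count": aggregate_daily(vals)}
        for (day, nid), vals in sorted(per_image.items())
    ]
    return pd.DataFrame(rows, columns=["date", "nest_id", "count"])
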