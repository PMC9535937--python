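"""Prepare segment-level training data from raw mobile observations.

A mobile-monitoring campaign yields second-resolution point measurements
along a road network.  Before any land-use-regression model can be trained
those points have to be turned into segment-level aggregates:

1. the road network is divided into short (default 50 m) segments,
2. raw observations are temporally corrected against a fixed background
   reference site, removing day-to-day and hour-to-hour meteorology,
3. each observation is snapped to the nearest road segment,
4. per-segment means, observation counts and drive-pass counts are formed,
5. long-term monitoring sites are matched to the segments within a radius
   (default 30 m) so that segment predictions can later be compared with
   long-term observations.

All coordinates are planar meters in a projected CRS; distances are
Euclidean.  Observations and reference series travel as pandas DataFrames,
geometry as shapely objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, shape
from shapely.ops import substring
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

#: Fraction of the target length below which a trailing remainder piece is
#: merged into its predecessor instead of forming a sliver segment.
MIN_REMAINDER_FRACTION = 0.2

#: Columns every mobile-observation table must carry.
OBS_COLUMNS = ("timestamp", "x", "y", "pollutant", "value")

POLLUTANTS = ("NO2", "UFP")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoadSegment:
    """A piece of road of roughly the target length.

    Attributes
    ----------
    segment_id : str
        Unique id, ``"<polyline id>.<piece index>"``.
    geometry : LineString
        Vertices in planar meters.
    """

    segment_id: str
    geometry: LineString

    @property
    def length(self) -> float:
        return self.geometry.length

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.geometry.centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class ReferenceSeries:
    """Concentrations at the single fixed background reference site."""

    timestamps: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self):
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")

    @property
    def campaign_mean(self) -> float:
        return float(np.mean(self.values))

    def window_means(self, freq: str = "h") -> pd.Series:
        """Mean reference value per calendar window (default: hour)."""
        s = pd.Series(np.asarray(self.values, dtype=float), index=self.timestamps)
        return s.groupby(s.index.floor(freq)).mean()


@dataclass(frozen=True)
class LongTermSite:
    """A stationary long-term monitor near the road network."""

    site_id: str
    x: float
    y: float
    pollutant: str
    value: float
    matched_segment_ids: tuple[str, ...] = field(default=())


# ---------------------------------------------------------------------------
# 1. segmentation
# ---------------------------------------------------------------------------

def segment_road_network(
    polylines: dict[str, LineString] | list[tuple[str, LineString]],
    target_length: float = 50.0,
) -> list[RoadSegment]:
    """Divide each road polyline into consecutive pieces of ``target_length``.

    The final remainder piece of a polyline is kept as its own (shorter)
    segment unless it is shorter than ``MIN_REMAINDER_FRACTION`` of the
    target length, in which case it is merged into the preceding piece.
    Total length is conserved per polyline.

    Parameters
    ----------
    polylines
        Mapping (or list of pairs) of polyline id -> LineString in meters.
    target_length
        Segment length in meters, > 0.

    Returns
    -------
    list of RoadSegment with unique ids ``"<line id>.<k>"``.
    """
    if target_length <= 0:
        raise ValueError("target_length must be > 0")
    items = polylines.items() if isinstance(polylines, dict) else polylines
    segments: list[RoadSegment] = []
    for line_id, line in items:
        if not isinstance(line, LineString):
            line = LineString(line)
        total = line.length
        if total <= 0:
            raise ValueError(f"degenerate zero-length polyline: {line_id!r}")
        # breakpoints along the line
        n_full = int(np.floor(total / target_length + 1e-9))
        remainder = total - n_full * target_length
        cuts = [i * target_length for i in range(n_full + 1)]
        if remainder > 1e-9:
            if remainder < MIN_REMAINDER_FRACTION * target_length and n_full >= 1:
                cuts[-1] = total  # merge sliver into predecessor
                logger.debug(
                    "polyline %s: %.2f m remainder merged into last segment",
                    line_id, remainder,
                )
            else:
                cuts.append(total)
        for k in range(len(cuts) - 1):
            piece = substring(line, cuts[k], cuts[k + 1])
            segments.append(RoadSegment(f"{line_id}.{k}", piece))
    ids = [s.segment_id for s in segments]
    if len(set(ids)) != len(ids):
        raise ValueError("segment ids are not unique; polyline ids must be unique")
    return segments


# ---------------------------------------------------------------------------
# 2. temporal correction
# ---------------------------------------------------------------------------

def temporal_correct(
    observations: pd.DataFrame,
    reference: ReferenceSeries,
    mode: str = "additive",
    window: str = "h",
) -> pd.DataFrame:
    """Correct raw observations for temporal variation via the reference site.

    For each observation the reference mean over its calendar window
    (default: the hour containing the timestamp) is compared with the
    campaign-wide reference mean:

    * ``additive``:        value - (ref_window_mean - campaign_mean)
    * ``multiplicative``:  value * campaign_mean / ref_window_mean

    An additive correction is conventional for gas concentrations; the
    multiplicative (ratio) form for particle counts.  Observations whose
    window is not covered by the reference series are dropped (count logged).
    """
    if mode not in ("additive", "multiplicative"):
        raise ValueError(f"unknown correction mode: {mode!r}")
    obs = observations.copy()
    ts = pd.to_datetime(obs["timestamp"])
    keys = ts.dt.floor(window)
    ref_means = reference.window_means(window)
    matched = keys.map(ref_means)
    missing = matched.isna()
    if missing.any():
        logger.warning(
            "temporal_correct: %d observations without reference coverage dropped",
            int(missing.sum()),
        )
        obs = obs.loc[~missing.values].copy()
        matched = matched.loc[~missing.values]
    cm = reference.campaign_mean
    if mode == "additive":
        obs["value"] = obs["value"].to_numpy(float) - (matched.to_numpy(float) - cm)
    else:
        rw = matched.to_numpy(float)
        if np.any(rw <= 0):
            raise ValueError(
                "multiplicative correction undefined: reference window mean <= 0"
            )
        obs["value"] = obs["value"].to_numpy(float) * cm / rw
    return obs


# ---------------------------------------------------------------------------
# 3. snapping
# ---------------------------------------------------------------------------

def snap_to_segments(
    observations: pd.DataFrame,
    segments: list[RoadSegment],
    max_snap_distance: float = 25.0,
) -> pd.DataFrame:
    """Assign each observation the nearest road segment.

    Distances are point-to-polyline Euclidean.  Observations farther than
    ``max_snap_distance`` from every segment stay unassigned
    (``segment_id`` is NaN; their count is logged).  Exact distance ties
    resolve to the lexicographically smallest segment_id so the result is
    independent of segment order.
    """
    if not segments:
        raise ValueError("segments must be nonempty")
    obs = observations.copy()
    geoms = np.array([s.geometry for s in segments], dtype=object)
    seg_ids = np.array([s.segment_id for s in segments], dtype=object)
    tree = STRtree(geoms)
    points = [Point(xy) for xy in obs[["x", "y"]].to_numpy(float)]
    assigned = np.full(len(points), None, dtype=object)
    pairs = tree.query_nearest(
        points, max_distance=max_snap_distance, all_matches=True
    )
    # pairs: 2 x m array of (point index, geometry index); ties give
    # multiple rows per point -> keep the smallest segment_id.
    for pt_i, geom_i in zip(*pairs):
        sid = seg_ids[geom_i]
        if assigned[pt_i] is None or sid < assigned[pt_i]:
            assigned[pt_i] = sid
    n_miss = int(sum(a is None for a in assigned))
    if n_miss:
        logger.info(
            "snap_to_segments: %d/%d observations beyond %.1f m left unassigned",
            n_miss, len(points), max_snap_distance,
        )
    obs["segment_id"] = [a if a is not None else np.nan for a in assigned]
    return obs


# ---------------------------------------------------------------------------
# 4. aggregation
# ---------------------------------------------------------------------------

def aggregate_segments(snapped: pd.DataFrame) -> pd.DataFrame:
    """Aggregate snapped observations to per-(segment, pollutant) records.

    Returns a DataFrame with columns ``segment_id, pollutant, mean_conc,
    n_obs, n_drive_passes``; a drive-pass is a distinct calendar date with
    at least one observation on the segment.
    """
    if snapped["segment_id"].isna().any():
        raise ValueError("all observations must carry a segment_id; snap first")
    df = snapped.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    out = (
        df.groupby(["segment_id", "pollutant"], sort=True)
        .agg(
            mean_conc=("value", "mean"),
            n_obs=("value", "size"),
            n_drive_passes=("date", "nunique"),
        )
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# 5. site matching
# ---------------------------------------------------------------------------

def match_sites_to_segments(
    sites: list[LongTermSite],
    segments: list[RoadSegment],
    radius: float = 30.0,
) -> list[LongTermSite]:
    """Match each long-term site to all segments within ``radius`` meters.

    Sites with no segment inside the radius get an empty match list and are
    logged; they are excluded later from site-level validation.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    geoms = np.array([s.geometry for s in segments], dtype=object)
    seg_ids = [s.segment_id for s in segments]
    tree = STRtree(geoms)
    matched: list[LongTermSite] = []
    for site in sites:
        p = Point(site.x, site.y)
        idx = tree.query(p, predicate="dwithin", distance=radius)
        ids = tuple(sorted(seg_ids[i] for i in idx))
        if not ids:
            logger.warning(
                "site %s has no road segment within %.1f m", site.site_id, radius
            )
        matched.append(
            LongTermSite(site.site_id, site.x, site.y, site.pollutant, site.value, ids)
        )
    return matched


# ---------------------------------------------------------------------------
# I/O: CSV observation tables, GeoJSON roads and sites
# ---------------------------------------------------------------------------

def read_observations_csv(path) -> pd.DataFrame:
    """Read a mobile-observation CSV (timestamp ISO-8601, x, y, pollutant, value)."""
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = ~np.isfinite(df["value"].to_numpy(float)) | (df["value"].to_numpy(float) < 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: row {row}: non-finite or negative value")
    return df


def read_reference_csv(path) -> ReferenceSeries:
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    return ReferenceSeries(
        pd.DatetimeIndex(df["timestamp"]), df["value"].to_numpy(float)
    )


def read_roads_geojson(path) -> dict[str, LineString]:
    """Read a road network GeoJSON of LineString features keyed by ``id``."""
    with open(path) as fh:
        gj = json.load(fh)
    roads: dict[str, LineString] = {}
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"{path}: feature is not a LineString")
        fid = str(feat.get("id", feat.get("properties", {}).get("id")))
        if fid in roads:
            raise ValueError(f"{path}: duplicate polyline id {fid!r}")
        roads[fid] = geom
    return roads


def read_sites_geojson(path) -> list[LongTermSite]:
    """Read long-term sites from GeoJSON Point features."""
    with open(path) as fh:
        gj = json.load(fh)
    sites = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        sites.append(
            LongTermSite(
                str(props["site_id"]), geom.x, geom.y,
                str(props["pollutant"]), float(props["value"]),
            )
        )
    return sites


def write_roads_geojson(path, polylines: dict[str, LineString]) -> None:
    feats = [
        {
            "type": "Feature",
            "id": lid,
            "properties": {"id": lid},
            "geometry": {"type": "LineString", "coordinates": list(line.coords)},
        }
        for lid, line in polylines.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_sites_geojson(path, sites: list[LongTermSite]) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {
                "site_id": s.site_id, "pollutant": s.pollutant, "value": s.value,
            },
            "geometry": {"type": "Point", "coordinates": [s.x, s.y]},
        }
        for s in sites
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
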