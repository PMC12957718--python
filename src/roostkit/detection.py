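"""Communal-roost detection from nightly GPS fixes.

The processing chain: project WGS84 fixes to planar metres; reduce each
bird-night to the component-wise median of its dusk-to-dawn fixes; block
the Nov 1 -- Jan 31 season into consecutive five-night intervals; flag a
bird as attending a communal roost in a block when at least ``min_others``
other tagged birds have a nightly median within ``radius`` metres of one
of its nightly medians inside the block; cluster nightly medians into
roost sites by single linkage; and weight each bird-block unit by its mean
distance outside the study-area polygon (inside = weight 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta
from itertools import product

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .geo import CIVIL_TWILIGHT_ELEVATION, TransverseMercator, twilight_times

log = logging.getLogger("roostkit")


@dataclass
class DetectionConfig:
    """Spatio-temporal thresholds of the communal-roost definition."""

    radius: float = 300.0          # metres; closed ball (ties count as inside)
    window: int = 5                # nights per block
    min_others: int = 2            # other tagged birds required within radius
    matching: str = "cross_night"  # or "same_night"
    twilight_elevation: float = CIVIL_TWILIGHT_ELEVATION
    duty_window: tuple = (7, 21)   # local clock hours
    tz_offset_hours: float = 1.0   # CET

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_others < 1:
            raise ValueError("min_others must be >= 1")
        if self.matching not in ("cross_night", "same_night"):
            raise ValueError("matching must be 'cross_night' or 'same_night'")


def project_coordinates(fixes: pd.DataFrame,
                        projection: TransverseMercator) -> pd.DataFrame:
    """Add planar ``x``/``y`` (metres) to a WGS84 fixes frame.

    Raises :class:`roostkit.geo.ProjectionError` for coordinates outside
    the projection's validity region.
    """
    out = fixes.copy()
    if len(out):
        x, y = projection.forward(out.lon.to_numpy(), out.lat.to_numpy())
    else:
        x = y = np.zeros(0)
    out["x"], out["y"] = x, y
    out.attrs["projection"] = projection.spec
    return out


def extract_night_locations(fixes: pd.DataFrame,
                            config: DetectionConfig | None = None) -> pd.DataFrame:
    """Reduce projected fixes to one median location per bird-night.

    A night ``d`` collects fixes between civil dusk of ``d`` and the duty
    end, plus fixes of day ``d+1`` from the duty start until civil dawn.
    Nights without qualifying fixes are absent from the output.
    """
    config = config or DetectionConfig()
    cols = ["bird_id", "night_date", "x", "y", "n_fixes"]
    if not len(fixes):
        return pd.DataFrame(columns=cols)
    df = fixes.copy()
    ts = pd.DatetimeIndex(df.timestamp)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    ts_utc = ts.tz_convert("UTC")
    local = ts_utc + pd.Timedelta(hours=config.tz_offset_hours)

    # candidate night: evening fixes belong to their own date, morning fixes
    # (before local noon) to the previous date
    local_naive = local.tz_localize(None)
    is_morning = local_naive.hour < 12
    night = local_naive.normalize() - pd.to_timedelta(is_morning.astype(int), unit="D")

    # twilight per fix (vectorised per unique date for speed)
    dusk = np.empty(len(df), dtype="datetime64[s]")
    dawn = np.empty(len(df), dtype="datetime64[s]")
    lon = df.lon.to_numpy()
    lat = df.lat.to_numpy()
    night_arr = np.asarray(night.values, dtype="datetime64[D]")
    for d in np.unique(night_arr):
        mask = night_arr == d
        pydate = pd.Timestamp(d).date()
        _, dusk_d = twilight_times(pydate, lon[mask], lat[mask],
                                   config.twilight_elevation)
        dawn_d, _ = twilight_times(pydate + timedelta(days=1), lon[mask],
                                   lat[mask], config.twilight_elevation)
        dusk[mask] = dusk_d
        dawn[mask] = dawn_d

    t64 = np.asarray(ts_utc.tz_localize(None).values, dtype="datetime64[s]")
    keep = np.where(np.asarray(is_morning), t64 <= dawn, t64 >= dusk)
    duty_end_local = config.duty_window[1]
    keep &= np.where(np.asarray(is_morning), True,
                     np.asarray(local_naive.hour
                                + local_naive.minute / 60.0) <= duty_end_local + 1e-9)

    df = df.loc[keep, ["bird_id", "x", "y"]].copy()
    df["night_date"] = night_arr[keep]
    if not len(df):
        return pd.DataFrame(columns=cols)
    out = df.groupby(["bird_id", "night_date"], as_index=False).agg(
        x=("x", "median"), y=("y", "median"), n_fixes=("x", "size"))
    return out[cols]


def assign_intervals(nights: pd.DataFrame, window: int | None = None,
                     config: DetectionConfig | None = None) -> pd.DataFrame:
    """Annotate night locations with winter id and five-night block index.

    Winters run Nov 1 -- Jan 31 and are labelled by the year of their
    Nov 1; blocks are consecutive, non-overlapping and anchored at Nov 1
    (the last block of a 5-night scheme has 2 nights).  Nights outside
    the seasonal window are dropped (count logged).
    """
    window = window if window is not None else (config.window if config else 5)
    out = nights.copy()
    nd = pd.DatetimeIndex(out.night_date)
    winter = np.where(nd.month >= 11, nd.year, nd.year - 1)
    anchor = pd.to_datetime({"year": winter, "month": 11, "day": 1})
    days = (nd.tz_localize(None) - pd.DatetimeIndex(anchor)).days
    in_window = (days >= 0) & (days < 92) & nd.month.isin([11, 12, 1])
    n_dropped = int((~in_window).sum())
    if n_dropped:
        log.info("assign_intervals: dropped %d nights outside Nov 1 - Jan 31",
                 n_dropped)
    out = out.loc[in_window].copy()
    out["winter_id"] = winter[in_window]
    out["interval_index"] = (days[np.asarray(in_window)] // window + 1).astype(int)
    return out


def intervals_per_winter(window: int = 5, season_nights: int = 92) -> int:
    """Number of blocks per winter (19 for the 5-night scheme)."""
    return int(np.ceil(season_nights / window))


def detect_attendance(nights: pd.DataFrame,
                      config: DetectionConfig | None = None):
    """Flag communal-roost attendance per bird x winter x block.

    Returns ``(night_counts, units)``:

    ``night_counts``
        per bird-night, the number of distinct other birds whose median
        location that same night lies within the radius;
    ``units``
        one row per bird x winter x block with ``neighbour_count`` (the
        number of distinct other birds within the radius under the
        configured matching rule), ``attendance`` (count >= min_others)
        and ``n_nights_observed``.

    Under ``cross_night`` matching a neighbour counts if any of its nightly
    medians in the block is within the radius of any of the focal bird's
    nightly medians; ``same_night`` requires the proximity on a shared
    night.  Distances are closed-ball (ties at the radius count).
    """
    config = config or DetectionConfig()
    req = {"bird_id", "night_date", "x", "y", "winter_id", "interval_index"}
    missing = req - set(nights.columns)
    if missing:
        raise ValueError(f"nights frame lacks columns: {sorted(missing)}")

    nc_parts = []
    unit_rows = []
    for (winter, block), g in nights.groupby(["winter_id", "interval_index"]):
        xy = g[["x", "y"]].to_numpy()
        birds, bird_codes = np.unique(g.bird_id.to_numpy(), return_inverse=True)
        tree = cKDTree(xy)
        pairs = tree.query_pairs(config.radius, output_type="ndarray")
        same_night = np.zeros(len(pairs), dtype=bool)
        if len(pairs):
            nd = np.asarray(pd.DatetimeIndex(g.night_date).values)
            same_night = nd[pairs[:, 0]] == nd[pairs[:, 1]]

        # per-night neighbour counts (distinct other birds, same night)
        neigh_sets_night: dict = {}
        for (i, j), sn in zip(pairs, same_night):
            if not sn or bird_codes[i] == bird_codes[j]:
                continue
            neigh_sets_night.setdefault(i, set()).add(bird_codes[j])
            neigh_sets_night.setdefault(j, set()).add(bird_codes[i])
        counts = np.array([len(neigh_sets_night.get(i, ())) for i in range(len(g))])
        part = g[["bird_id", "night_date", "winter_id", "interval_index"]].copy()
        part["n_neighbours"] = counts
        nc_parts.append(part)

        # block-level neighbour sets
        neigh: dict = {b: set() for b in range(len(birds))}
        use = pairs if config.matching == "cross_night" else pairs[same_night]
        for i, j in use:
            bi, bj = bird_codes[i], bird_codes[j]
            if bi != bj:
                neigh[bi].add(bj)
                neigh[bj].add(bi)
        n_nights = pd.Series(g.bird_id.to_numpy()).groupby(
            pd.Series(bird_codes)).size()
        for b, bird in enumerate(birds):
            cnt = len(neigh[b])
            unit_rows.append((bird, winter, block, cnt,
                              int(cnt >= config.min_others),
                              int(n_nights.loc[b])))

    night_counts = (pd.concat(nc_parts, ignore_index=True) if nc_parts
                    else pd.DataFrame(columns=["bird_id", "night_date",
                                               "winter_id", "interval_index",
                                               "n_neighbours"]))
    units = pd.DataFrame(unit_rows, columns=[
        "bird_id", "winter_id", "interval_index", "neighbour_count",
        "attendance", "n_nights_observed"])
    return night_counts, units


def cluster_roost_sites(nights: pd.DataFrame,
                        linkage_radius: float = 300.0) -> pd.DataFrame:
    """Single-linkage clusters of nightly medians, one night at a time.

    Members of a site are pairwise connected under the linkage radius;
    the centroid is the mean of member locations.
    """
    rows = []
    for night, g in nights.groupby("night_date"):
        xy = g[["x", "y"]].to_numpy()
        tree = cKDTree(xy)
        pairs = tree.query_pairs(linkage_radius, output_type="ndarray")
        n = len(g)
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        for c in range(n_comp):
            m = labels == c
            rows.append(dict(
                site_id=f"{pd.Timestamp(night).date()}-{c:03d}",
                night_date=night,
                member_ids=";".join(sorted(g.bird_id.to_numpy()[m])),
                centroid_x=float(xy[m, 0].mean()),
                centroid_y=float(xy[m, 1].mean()),
                n_tagged=int(m.sum()),
            ))
    return pd.DataFrame(rows, columns=["site_id", "night_date", "member_ids",
                                       "centroid_x", "centroid_y", "n_tagged"])


def compute_weights(units: pd.DataFrame, nights: pd.DataFrame,
                    study_area: Polygon) -> pd.DataFrame:
    """Observation weights from mean distance outside the study area.

    Per unit: ``d`` = mean over its nights of the Euclidean distance to
    the area boundary (0 inside); scaled by the global maximum ``d``;
    weight = 1 - scaled.  All-inside data gets weight 1 everywhere.
    """
    if study_area.is_empty or study_area.area <= 0:
        raise ValueError("degenerate study-area polygon")
    nl = nights.copy()
    pts = [Point(x, y) for x, y in zip(nl.x, nl.y)]
    nl["dist_out"] = [0.0 if study_area.covers(p) else p.distance(study_area)
                      for p in pts]
    mean_d = nl.groupby(["bird_id", "winter_id", "interval_index"])["dist_out"].mean()
    out = units.copy()
    key = pd.MultiIndex.from_frame(out[["bird_id", "winter_id", "interval_index"]])
    d = mean_d.reindex(key).to_numpy()
    d = np.nan_to_num(d, nan=0.0)
    dmax = d.max() if len(d) else 0.0
    out["weight"] = 1.0 - (d / dmax if dmax > 0 else 0.0)
    return out


def attach_covariates(units: pd.DataFrame,
                      individuals: pd.DataFrame) -> pd.DataFrame:
    """Merge sex, tag class, winter-season age and breeding status onto units.

    Age counts winter seasons (a bird fledged in spring of year ``y`` has
    age 1 throughout winter ``y``); it is defined for juvenile-tagged
    birds only.  Breeding status is 1 from the first breeding year on.
    """
    ind = individuals.set_index("bird_id")
    out = units.copy()
    out["sex"] = ind.sex.reindex(out.bird_id).to_numpy()
    out["tag_class"] = ind.tag_class.reindex(out.bird_id).to_numpy()
    by = pd.to_numeric(ind.birth_year.reindex(out.bird_id), errors="coerce").to_numpy(dtype=float)
    out["age"] = np.where(out.tag_class == "juvenile",
                          out.winter_id.to_numpy() - by + 1, np.nan)
    fb = pd.to_numeric(ind.first_breeding_year.reindex(out.bird_id),
                       errors="coerce").to_numpy(dtype=float)
    out["breeding_status"] = (np.nan_to_num(fb, nan=np.inf)
                              <= out.winter_id.to_numpy()).astype(int)
    return out


def sensitivity_sweep(nights: pd.DataFrame, radii, windows, min_others_grid,
                      matching: str = "cross_night") -> pd.DataFrame:
    """Attendance rates over a grid of detection thresholds.

    Re-runs block assignment and attendance detection for every
    combination; returns one row per combination with the number of units
    and the attendance rate.
    """
    radii = list(radii)
    windows = list(windows)
    min_others_grid = list(min_others_grid)
    if not radii or not windows or not min_others_grid:
        raise ValueError("sensitivity grid must be non-empty")
    rows = []
    base = nights.drop(columns=[c for c in ("winter_id", "interval_index")
                                if c in nights.columns])
    for w in windows:
        blocked = assign_intervals(base, window=w)
        for r, m in product(radii, min_others_grid):
            cfg = DetectionConfig(radius=r, window=w, min_others=m,
                                  matching=matching)
            _, units = detect_attendance(blocked, cfg)
            rows.append(dict(radius=r, window=w, min_others=m,
                             matching=matching, n_units=len(units),
                             attendance_rate=float(units.attendance.mean())
                             if len(units) else np.nan,
                             n_attending=int(units.attendance.sum())))
    return pd.DataFrame(rows)
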