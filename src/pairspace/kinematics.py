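"""Per-bin movement metrics from position fixes and depth series.

The behavioral-state analysis works on six metrics per 10-min bin: swimming
speed, speed south (net southerly displacement rate), course deviation
between consecutive bins, energetic-surface-behavior count, proportion of
time at the surface and number of deep dives initiated. Deep dives are
excursions strictly deeper than 10 m lasting strictly longer than 75 s; all
remaining time is "surface" (a series of shallow dives and breaths), so
dives and surface intervals partition the depth record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RunConfig, TagDataset

logger = logging.getLogger("pairspace")

__all__ = [
    "DiveEvent",
    "SurfaceInterval",
    "segment_dives",
    "interpolate_bin_positions",
    "compute_bin_kinematics",
    "compute_bin_dive_metrics",
    "build_metric_table",
    "METRIC_COLUMNS",
]

#: the six clustering variables, in canonical order
METRIC_COLUMNS = [
    "speed_kmh",
    "speed_south_kmh",
    "course_dev_deg",
    "esb_count",
    "surface_prop",
    "dive_count",
]


@dataclass(frozen=True)
class DiveEvent:
    """One deep dive: depth > threshold for longer than the duration rule."""

    t_start: float
    t_end: float
    max_depth: float
    mean_depth: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SurfaceInterval:
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _cross_time(t0: float, d0: float, t1: float, d1: float, thr: float) -> float:
    # linear interpolation of the instant depth crosses thr between samples
    return t0 + (thr - d0) / (d1 - d0) * (t1 - t0)


def segment_dives(
    t: np.ndarray, depth: np.ndarray, config: RunConfig | None = None
) -> tuple[list[DiveEvent], list[SurfaceInterval]]:
    """Segment a depth series into deep dives and surface intervals.

    Dive boundaries are placed where the linearly-interpolated depth trace
    crosses the depth threshold; excursions qualify as dives only if their
    duration strictly exceeds the duration threshold and their maximum depth
    strictly exceeds the depth threshold. The returned dives and surface
    intervals tile [t[0], t[-1]] exactly.
    """
    config = config or RunConfig()
    thr = config.deep_dive_depth_m
    min_dur = config.deep_dive_duration_s
    t = np.asarray(t, float)
    depth = np.asarray(depth, float)
    if t.size == 0:
        return [], []
    if t.size == 1:
        return [], [SurfaceInterval(float(t[0]), float(t[0]))]

    below = depth > thr
    dives: list[DiveEvent] = []
    # maximal runs of below-threshold samples
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = [0] if below[0] else []
    starts += [int(i) + 1 for i in edges if not below[i] and below[i + 1]]
    ends = [int(i) for i in edges if below[i] and not below[i + 1]]
    if below[-1]:
        ends.append(len(t) - 1)

    for i, j in zip(starts, ends):
        if i > 0:
            t0 = _cross_time(t[i - 1], depth[i - 1], t[i], depth[i], thr)
            d_edge0 = thr
        else:
            t0, d_edge0 = float(t[0]), float(depth[0])
        if j < len(t) - 1:
            t1 = _cross_time(t[j], depth[j], t[j + 1], depth[j + 1], thr)
            d_edge1 = thr
        else:
            t1, d_edge1 = float(t[-1]), float(depth[-1])
        duration = t1 - t0
        max_depth = float(depth[i : j + 1].max())
        if duration > min_dur and max_depth > thr:
            tt = np.concatenate(([t0], t[i : j + 1], [t1]))
            dd = np.concatenate(([d_edge0], depth[i : j + 1], [d_edge1]))
            mean_depth = float(np.trapezoid(dd, tt) / duration) if duration > 0 else max_depth
            dives.append(DiveEvent(float(t0), float(t1), max_depth, mean_depth))

    surfaces: list[SurfaceInterval] = []
    cursor = float(t[0])
    for dv in dives:
        if dv.t_start > cursor:
            surfaces.append(SurfaceInterval(cursor, dv.t_start))
        cursor = dv.t_end
    if cursor < float(t[-1]):
        surfaces.append(SurfaceInterval(cursor, float(t[-1])))
    return dives, surfaces


def interpolate_bin_positions(
    fixes: pd.DataFrame, bin_edges: np.ndarray
) -> pd.DataFrame:
    """Interpolate group positions at bin boundaries from position fixes.

    Assumes straight-line, constant-speed movement between consecutive
    fixes. Boundaries outside the fix record are marked missing; the
    downstream metric table excludes the affected bins.
    """
    if len(fixes) < 2:
        raise ValueError("need at least 2 position fixes to interpolate")
    tf = fixes["t_s"].to_numpy(float)
    xf = fixes["x_km"].to_numpy(float)
    yf = fixes["y_km"].to_numpy(float)
    edges = np.asarray(bin_edges, float)
    inside = (edges >= tf[0]) & (edges <= tf[-1])
    x = np.where(inside, np.interp(edges, tf, xf), np.nan)
    y = np.where(inside, np.interp(edges, tf, yf), np.nan)
    return pd.DataFrame({"t_s": edges, "x_km": x, "y_km": y, "missing": ~inside})


def compute_bin_kinematics(
    start_pos: tuple[float, float],
    end_pos: tuple[float, float],
    dt_s: float,
    prev_course: float | None,
) -> tuple[float, float, float | None, float | None]:
    """Speed, speed south, course and course deviation for one bin.

    Course is the bearing of net displacement, degrees clockwise from north.
    Speed south is the net southerly displacement rate (negative when the
    net movement is northward); it can never exceed speed in magnitude.
    Course deviation is the absolute circular difference from the previous
    bin's course, in [0, 180]; ``None`` when there is no previous course.
    With zero net displacement the course is undefined: the previous course
    is carried and the deviation is 0 (logged, not fatal).
    """
    dx = end_pos[0] - start_pos[0]
    dy = end_pos[1] - start_pos[1]
    dt_h = dt_s / 3600.0
    dist = math.hypot(dx, dy)
    speed = dist / dt_h
    speed_south = -dy / dt_h
    if dist < 1e-12:
        logger.debug("zero displacement in bin; carrying previous course")
        course = prev_course
        deviation = 0.0 if prev_course is not None else None
        return 0.0, 0.0, course, deviation
    course = math.degrees(math.atan2(dx, dy)) % 360.0
    if prev_course is None:
        deviation = None
    else:
        raw = abs(course - prev_course) % 360.0
        deviation = min(raw, 360.0 - raw)
    return speed, speed_south, course, deviation


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def compute_bin_dive_metrics(
    dives: list[DiveEvent],
    record_span: tuple[float, float],
    bin_start: float,
    bin_end: float,
) -> tuple[float | None, int | None]:
    """Surface proportion and number of dives initiated within one bin.

    A dive belongs to the bin containing its start (half-open bins) but its
    time is allocated pro rata to every bin it overlaps when computing the
    surface proportion. Returns ``(None, None)`` if the depth record does
    not cover the bin.
    """
    r0, r1 = record_span
    if bin_start < r0 - 1e-9 or bin_end > r1 + 1e-9:
        return None, None
    bin_len = bin_end - bin_start
    dive_time = sum(_overlap(d.t_start, d.t_end, bin_start, bin_end) for d in dives)
    surface_prop = (bin_len - dive_time) / bin_len
    dive_count = sum(1 for d in dives if bin_start <= d.t_start < bin_end)
    return surface_prop, dive_count


def build_metric_table(dataset: TagDataset, config: RunConfig | None = None) -> pd.DataFrame:
    """Compute the six per-bin movement metrics for one tag.

    Bins are half-open ``[start, start + bin_length)`` indexed from the
    follow start; only complete bins are emitted. Rows with any missing
    metric (notably the first bin, whose course deviation cannot be
    computed) carry ``excluded = 1`` and are dropped from clustering.
    """
    config = config or RunConfig()
    bl = config.bin_length_s
    n_bins = int(math.floor((dataset.follow_end - dataset.follow_start) / bl))
    edges = dataset.follow_start + bl * np.arange(n_bins + 1)
    if n_bins < 1:
        return pd.DataFrame(
            columns=["tag_id", "bin_index", "t_start_s", "speed_kmh", "speed_south_kmh",
                     "course_deg", "course_dev_deg", "esb_count", "surface_prop",
                     "dive_count", "excluded"]
        )
    pos = interpolate_bin_positions(dataset.fixes, edges)

    t_depth = dataset.depth["t_s"].to_numpy(float)
    d_depth = dataset.depth["depth_m"].to_numpy(float)
    dives, _ = segment_dives(t_depth, d_depth, config)
    span = (float(t_depth[0]), float(t_depth[-1])) if t_depth.size else (np.nan, np.nan)

    esb_t = dataset.esb["t_s"].to_numpy(float)
    esb_n = dataset.esb["count"].to_numpy(float)

    rows = []
    prev_course: float | None = None
    for b in range(n_bins):
        b0, b1 = float(edges[b]), float(edges[b + 1])
        row: dict = {"tag_id": dataset.tag_id, "bin_index": b, "t_start_s": b0}
        missing = False
        if pos["missing"].iloc[b] or pos["missing"].iloc[b + 1]:
            missing = True
            speed = speed_south = course = deviation = None
        else:
            start = (pos["x_km"].iloc[b], pos["y_km"].iloc[b])
            end = (pos["x_km"].iloc[b + 1], pos["y_km"].iloc[b + 1])
            speed, speed_south, course, deviation = compute_bin_kinematics(
                start, end, bl, prev_course
            )
            prev_course = course
            if deviation is None:
                missing = True
        if t_depth.size:
            surface_prop, dive_count = compute_bin_dive_metrics(dives, span, b0, b1)
        else:
            surface_prop = dive_count = None
        if surface_prop is None:
            missing = True
        esb = float(esb_n[(esb_t >= b0) & (esb_t < b1)].sum())
        row.update(
            speed_kmh=speed,
            speed_south_kmh=speed_south,
            course_deg=course,
            course_dev_deg=deviation,
            esb_count=esb,
            surface_prop=surface_prop,
            dive_count=dive_count,
            excluded=int(missing),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def build_metric_tables(
    datasets: dict[str, TagDataset], config: RunConfig | None = None
) -> pd.DataFrame:
    """Concatenate per-tag metric tables over a collection of follows."""
    parts = [build_metric_table(ds, config) for ds in datasets.values()]
    parts = [p for p in parts if len(p)]
    if not parts:
        return build_metric_table(next(iter(datasets.values())), config)
    return pd.concat(parts, ignore_index=True)
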