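"""Surface-offset correction, dive detection, and phase segmentation.

A dive is any excursion beyond 3 m depth. Descent ends where the vertical
rate of a continuous descent first drops below 0.4 m/s other than during a
brief transit step (< 8 s and before 60 % of maximum dive depth); ascent
start is found symmetrically scanning backward from the dive's end. "Rate"
is the plain 1-s first difference of depth — the sampling resolution defines
the rate resolution and no smoothing is applied before differencing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .config import SegmentationConfig
from .series import DepthSeries

#: per-dive metric columns produced by :func:`segment_dives`
DIVE_COLUMNS = [
    "dive_id", "start_s", "end_s", "max_depth", "descent_duration",
    "bottom_duration", "ascent_duration", "dive_duration",
    "post_dive_interval", "descent_rate", "ascent_rate",
    "depth_bottom_start", "depth_bottom_end", "descent_end_s",
    "ascent_start_s", "deep", "degenerate",
]


class NoSurfaceRecordsError(ValueError):
    """No inter-dive surface records found; review the dive threshold."""


def correct_surface_offset(series: DepthSeries,
                           cfg: SegmentationConfig | None = None) -> DepthSeries:
    """Remove the pressure-transducer surface offset.

    Surface records are the minimum depths between successive dives (plus
    the pre-first and post-last surface segments). A trend fitted through
    them — robust linear for few records, smoothing spline otherwise — is
    subtracted from the whole series. Negative residual depths are kept for
    inspection, not clipped.
    """
    cfg = cfg or SegmentationConfig()
    depth = series.depth
    runs = _threshold_runs(depth, cfg.dive_threshold_m)
    if not runs:
        raise NoSurfaceRecordsError(
            "no dives found, so no inter-dive surface records; "
            "review the dive threshold")
    # surface segments: before first dive, between dives, after last dive
    seg_edges = [(0, runs[0][0])]
    for (s0, e0), (s1, _) in zip(runs[:-1], runs[1:]):
        seg_edges.append((e0, s1))
    seg_edges.append((runs[-1][1], len(depth)))
    ts, ms = [], []
    for a, b in seg_edges:
        if b - a < 1:
            continue
        i = a + int(np.argmin(depth[a:b]))
        ts.append(series.time[i])
        ms.append(depth[i])
    ts, ms = np.asarray(ts), np.asarray(ms)
    if len(ts) == 0:
        raise NoSurfaceRecordsError("no surface records between dives")

    if len(ts) < cfg.min_surface_records:
        trend = _robust_line(ts, ms)(series.time)
    else:
        # smoothing scale from the local roughness of the surface minima
        resid = np.diff(ms)
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid))) / np.sqrt(2)
        scale = max(scale, 1e-3)
        spl = UnivariateSpline(ts, ms, k=3, s=len(ts) * scale ** 2)
        tt = np.clip(series.time, ts[0], ts[-1])  # no extrapolation past anchors
        trend = spl(tt)
    return DepthSeries(series.individual_id, series.time, depth - trend)


def _robust_line(t, y):
    """Least-absolute-ish line via two iterations of reweighted least squares."""
    w = np.ones_like(y)
    for _ in range(3):
        coef = np.polyfit(t, y, 1, w=w)
        r = y - np.polyval(coef, t)
        s = 1.4826 * np.median(np.abs(r)) + 1e-9
        w = 1.0 / np.sqrt(1.0 + (r / s) ** 2)
    return lambda x: np.polyval(coef, x)


def _threshold_runs(depth: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Half-open index runs where depth > thr."""
    above = depth > thr
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(depth))
    return list(zip(starts, ends))


def detect_dives(series: DepthSeries, dive_threshold_m: float = 3.0,
                 surface_eps_m: float = 0.5) -> list[tuple[int, int]]:
    """Find dives as maximal runs with depth > threshold, extended outward
    to the adjacent surface crossings (depth <= ``surface_eps_m``).

    Returns half-open ``(start, end)`` index pairs. Idempotent: re-running
    on the same series returns the same pairs.
    """
    depth = series.depth
    runs = _threshold_runs(depth, dive_threshold_m)
    out = []
    prev_end = 0
    for s, e in runs:
        while s > prev_end and depth[s - 1] > surface_eps_m:
            s -= 1
        while e < len(depth) and depth[e] > surface_eps_m:
            e += 1
        if e < len(depth):
            e += 1  # include the first surface sample as the dive's end point
        if out and s < out[-1][1]:
            # extension met the previous dive: split at the shallowest point
            s = out[-1][1]
        out.append((s, e))
        prev_end = e
    return out


def segment_phases(depth: np.ndarray, cfg: SegmentationConfig | None = None
                   ) -> tuple[int, int]:
    """Locate descent end and ascent start inside one dive's depth samples.

    Scanning forward, descent continues while the 1-s increment is >= the
    rate threshold; a slow run is tolerated as a transit step when it lasts
    < 8 s and its mean depth is < 60 % of max depth; the first disqualifying
    slow run ends the descent. The ascent is segmented symmetrically
    scanning backward. Returns ``(descent_end_idx, ascent_start_idx)``.
    """
    cfg = cfg or SegmentationConfig()
    i_desc = _descent_end(depth, cfg)
    i_asc_rev = _descent_end(depth[::-1], cfg)
    i_asc = (len(depth) - 1) - i_asc_rev
    if i_asc < i_desc:  # V-shaped dive: vertex region, zero-length bottom
        i_asc = i_desc
    return i_desc, i_asc


def _descent_end(depth: np.ndarray, cfg: SegmentationConfig) -> int:
    r = np.diff(depth)
    max_depth = depth.max()
    slow = r < cfg.rate_threshold_ms
    pos = 0
    n = len(r)
    while pos < n:
        if not slow[pos]:
            pos += 1
            continue
        j = pos
        while j < n and slow[j]:
            j += 1
        run_len = j - pos
        mean_depth = depth[pos:j + 1].mean()
        if run_len < cfg.step_max_s and mean_depth < cfg.step_depth_fraction * max_depth:
            pos = j  # tolerated transit step; descent continues
        else:
            return pos
    return n  # never disqualified: degenerate (no bottom/ascent)


def segment_dives(series: DepthSeries, cfg: SegmentationConfig | None = None
                  ) -> pd.DataFrame:
    """Detect and segment every dive of an offset-corrected series.

    Produces one row per dive with the standard per-dive metrics. Dives not
    exceeding the 15-m deep threshold are detected and timed but carry no
    phase metrics (marked ``deep=False``); dives too short to segment are
    flagged ``degenerate`` and excluded downstream.
    """
    cfg = cfg or SegmentationConfig()
    pairs = detect_dives(series, cfg.dive_threshold_m, cfg.surface_eps_m)
    rows = []
    for k, (s, e) in enumerate(pairs):
        d = series.depth[s:e]
        t0 = series.time[s]
        t1 = series.time[e - 1]
        max_depth = float(d.max())
        deep = max_depth > cfg.deep_threshold_m
        row = {
            "dive_id": k, "start_s": t0, "end_s": t1, "max_depth": max_depth,
            "dive_duration": t1 - t0, "deep": deep, "degenerate": False,
            "descent_duration": np.nan, "bottom_duration": np.nan,
            "ascent_duration": np.nan, "descent_rate": np.nan,
            "ascent_rate": np.nan, "depth_bottom_start": np.nan,
            "depth_bottom_end": np.nan, "descent_end_s": np.nan,
            "ascent_start_s": np.nan,
        }
        if deep:
            if len(d) < 4:
                row["degenerate"] = True
            else:
                i_desc, i_asc = segment_phases(d, cfg)
                if i_desc == 0 or i_desc >= len(d) - 1:
                    row["degenerate"] = True
                else:
                    row.update({
                        "descent_end_s": t0 + i_desc,
                        "ascent_start_s": t0 + i_asc,
                        "descent_duration": float(i_desc),
                        "bottom_duration": float(i_asc - i_desc),
                        "ascent_duration": float((len(d) - 1) - i_asc),
                        "depth_bottom_start": float(d[i_desc]),
                        "depth_bottom_end": float(d[i_asc]),
                    })
                    row["descent_rate"] = row["depth_bottom_start"] / row["descent_duration"]
                    asc_dur = row["ascent_duration"]
                    row["ascent_rate"] = (row["depth_bottom_end"] / asc_dur
                                          if asc_dur > 0 else np.nan)
        rows.append(row)
    df = pd.DataFrame(rows, columns=DIVE_COLUMNS if rows else DIVE_COLUMNS)
    if len(df):
        nxt = df["start_s"].shift(-1)
        df["post_dive_interval"] = nxt - df["end_s"]
    return df
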