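"""Step, wiggle, and bottom depth-variation detection inside segmented dives.

All detectors work on maximal runs of the 1-s depth first difference.
Depth is positive downward: a *descending* step gets deeper, an *ascending*
step gets shallower. Runs are strictly maximal with no gap tolerance — a
single discordant sample splits a run.

* transit step (descent or ascent): |rate| < 0.4 m/s for 1-7 s, run mean
  depth before 60 % of maximum dive depth;
* bottom step: |rate| > 0.4 m/s for 1-7 s within the bottom phase, labelled
  by sign;
* wiggle: an ascending bottom step whose end is followed within < 3 s by
  the start of a descending bottom step (each step pairs at most once,
  greedily in time order);
* bottom depth variation: maximum dive depth minus depth at bottom start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FeatureConfig, SegmentationConfig

FEATURE_COLUMNS = ["steps_descent", "steps_ascent", "steps_descending_bottom",
                   "steps_ascending_bottom", "wiggles", "depth_variation_bottom"]


@dataclass
class Interval:
    """A detected run: [start, end] in seconds relative to the subseries."""

    start: float
    end: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) over rate indices."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def detect_transit_steps(depth: np.ndarray, max_depth: float,
                         cfg: SegmentationConfig | None = None) -> list[Interval]:
    """Steps in a descent or ascent subseries (rate-magnitude slowdowns)."""
    cfg = cfg or SegmentationConfig()
    if len(depth) < 2:
        return []
    r = np.diff(depth)
    slow = np.abs(r) < cfg.rate_threshold_ms
    out = []
    for s, e in _runs(slow):
        length = e - s
        if 1 <= length < cfg.step_max_s and \
                depth[s:e + 1].mean() < cfg.step_depth_fraction * max_depth:
            out.append(Interval(float(s), float(e)))
    return out


def detect_bottom_steps(depth: np.ndarray, cfg: SegmentationConfig | None = None
                        ) -> tuple[list[Interval], list[Interval]]:
    """(descending, ascending) fast runs of 1-7 s within the bottom phase."""
    cfg = cfg or SegmentationConfig()
    if len(depth) < 2:
        return [], []
    r = np.diff(depth)
    desc, asc = [], []
    for sign, sink in ((1, desc), (-1, asc)):
        mask = sign * r > cfg.rate_threshold_ms
        for s, e in _runs(mask):
            if 1 <= e - s < cfg.step_max_s:
                sink.append(Interval(float(s), float(e)))
    return desc, asc


def detect_wiggles(ascending: list[Interval], descending: list[Interval],
                   cfg: FeatureConfig | None = None) -> int:
    """Count ascending-then-descending step pairs separated by < 3 s.

    Pairs form greedily in time order; each step joins at most one wiggle.
    With ``wiggle_either_order`` the symmetric reading (a pair in either
    order) is counted instead.
    """
    cfg = cfg or FeatureConfig()
    if cfg.wiggle_either_order:
        events = sorted([(iv, "A") for iv in ascending] +
                        [(iv, "D") for iv in descending], key=lambda x: x[0].start)
        count, prev = 0, None
        for iv, kind in events:
            if prev is not None and kind != prev[1] and \
                    iv.start - prev[0].end < cfg.wiggle_gap_s:
                count += 1
                prev = None
            else:
                prev = (iv, kind)
        return count
    descending = sorted(descending, key=lambda iv: iv.start)
    used = [False] * len(descending)
    count = 0
    for a in sorted(ascending, key=lambda iv: iv.start):
        for i, d in enumerate(descending):
            if used[i] or d.start < a.end:
                continue
            if d.start - a.end < cfg.wiggle_gap_s:
                used[i] = True
                count += 1
            break  # only the next descending step can pair with this ascent
    return count


def bottom_depth_variation(max_depth: float, depth_bottom_start: float) -> float:
    """Maximum dive depth minus depth at the start of the bottom phase.

    Negative only when max depth occurs before the bottom starts (flagged
    upstream, never dropped)."""
    return max_depth - depth_bottom_start


def extract_features(series_depth: np.ndarray, dive_row: pd.Series,
                     seg_cfg: SegmentationConfig | None = None,
                     feat_cfg: FeatureConfig | None = None) -> dict:
    """All feature counts for one segmented deep dive.

    ``series_depth`` is the trip's full 1-Hz depth; boundaries come from the
    dive row produced by segmentation.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    s = int(dive_row["start_s"])
    e = int(dive_row["end_s"])
    i_desc = int(dive_row["descent_end_s"])
    i_asc = int(dive_row["ascent_start_s"])
    max_depth = float(dive_row["max_depth"])
    descent = series_depth[s:i_desc + 1]
    bottom = series_depth[i_desc:i_asc + 1]
    ascent = series_depth[i_asc:e + 1]
    steps_d = detect_transit_steps(descent, max_depth, seg_cfg)
    steps_a = detect_transit_steps(ascent, max_depth, seg_cfg)
    sdb, sab = detect_bottom_steps(bottom, seg_cfg)
    return {
        "steps_descent": len(steps_d),
        "steps_ascent": len(steps_a),
        "steps_descending_bottom": len(sdb),
        "steps_ascending_bottom": len(sab),
        "wiggles": detect_wiggles(sab, sdb, feat_cfg),
        "depth_variation_bottom": bottom_depth_variation(
            max_depth, float(dive_row["depth_bottom_start"])),
    }


def add_features(dives: pd.DataFrame, series, seg_cfg=None, feat_cfg=None
                 ) -> pd.DataFrame:
    """Extend a per-dive table with feature columns (NaN for non-deep or
    degenerate dives)."""
    out = dives.copy()
    for col in FEATURE_COLUMNS:
        out[col] = np.nan
    for idx, row in out.iterrows():
        if not row["deep"] or row["degenerate"]:
            continue
        feats = extract_features(series.depth, row, seg_cfg, feat_cfg)
        for k, v in feats.items():
            out.loc[idx, k] = v
    return out
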