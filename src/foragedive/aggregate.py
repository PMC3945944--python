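"""Response/predictor tables at each temporal scale.

Scales: individual dives, dive bouts, fixed 30-min / 1-h / 2-h windows tiled
inside bouts, and whole nights. Only dives deeper than 15 m, lying in bouts
of >= 3 dives and not terminating their bout, enter the tables. Bout and
window rows are kept only when deep-dive cycles (dive duration + post-dive
surface interval) cover more than 85 % of the row's span; that coverage
percentage itself joins the predictors (``pct_time_deep``), as does the
number of dives (``n_dives``), at every super-dive scale.

Windows are anchored at each bout's start and tile without overlap; partial
trailing windows are dropped. Because 30-min windows nest exactly inside
1-h and 2-h windows from the same origin, responses are consistent across
window scales whenever all constituents are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AggregateConfig, WINDOW_SECONDS
from .synthetic import DIVE_PREDICTORS

SUPER_PREDICTORS = tuple(DIVE_PREDICTORS) + ("n_dives", "pct_time_deep")


class EmptyTableError(ValueError):
    pass


@dataclass
class ScaleTable:
    """Aggregated predictor/response table at one temporal scale."""

    scale: str
    df: pd.DataFrame
    predictors: tuple
    response: str = "pca_count"
    stats: dict | None = None          # per-column (mean, sd) once standardized

    @property
    def standardized(self) -> bool:
        return self.stats is not None


def attach_context(dives: pd.DataFrame, night_windows: dict) -> pd.DataFrame:
    """Add the modelling context columns to a segmented dive table:
    ``surface_duration`` (the post-dive surface interval, the recovery-time
    predictor) and ``night`` (index of the night window containing the dive
    start; -1 outside every window)."""
    out = dives.copy()
    out["surface_duration"] = out["post_dive_interval"].astype(float)
    nights = np.full(len(out), -1, dtype=int)
    for i, (_, row) in enumerate(out.iterrows()):
        for k, (ns, ne) in enumerate(night_windows.get(row["individual_id"], [])):
            if ns <= row["start_s"] < ne:
                nights[i] = k
                break
    out["night"] = nights
    return out


def _analysis_dives(dives: pd.DataFrame) -> pd.DataFrame:
    mask = (dives["deep"] & ~dives["degenerate"] & dives["included"]
            & (dives["max_depth"] > 15.0))
    return dives.loc[mask]


def build_dive_table(dives: pd.DataFrame) -> ScaleTable:
    """One row per included deep dive; predictors are the per-dive metrics
    verbatim (pre-standardization)."""
    sub = _analysis_dives(dives)
    if len(sub) == 0:
        n_deep = int(dives["deep"].sum()) if len(dives) else 0
        raise EmptyTableError(
            "no dives left at the dive scale "
            f"(total={len(dives)}, deep={n_deep}, "
            f"in qualifying bouts={int(dives.get('included', pd.Series(dtype=bool)).sum())})")
    cols = ["individual_id", "bout_id", "night", "start_s", "end_s",
            "dive_duration", "post_dive_interval", "pca_count"] + list(DIVE_PREDICTORS)
    df = sub[cols].reset_index(drop=True).copy()
    df["pca_count"] = df["pca_count"].astype(int)
    return ScaleTable("dive", df, tuple(DIVE_PREDICTORS))


def _cycle_bounds(dives: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """[start, end] of each dive cycle (dive + following surface interval);
    a dive with no recorded following interval contributes the dive only."""
    start = dives["start_s"].to_numpy(dtype=float)
    iv = dives["post_dive_interval"].to_numpy(dtype=float)
    end = dives["end_s"].to_numpy(dtype=float) + np.where(np.isfinite(iv), iv, 0.0)
    return start, end


def _aggregate_rows(sub: pd.DataFrame) -> dict:
    row = {p: float(sub[p].mean()) for p in DIVE_PREDICTORS}
    row["pca_count"] = int(sub["pca_count"].sum())
    row["n_dives"] = int(len(sub))
    return row


def build_bout_table(dives: pd.DataFrame,
                     cfg: AggregateConfig | None = None) -> ScaleTable:
    """Per qualifying bout: summed response, mean dive predictors, number of
    dives, and deep-dive-cycle coverage (rows under 85 % coverage drop)."""
    cfg = cfg or AggregateConfig()
    rows = []
    for (ind, bout), grp in dives.groupby(["individual_id", "bout_id"]):
        ana = _analysis_dives(grp)
        if len(ana) == 0:
            continue
        span0 = float(grp["start_s"].min())
        span1 = float(grp["end_s"].max())
        span = span1 - span0
        if span <= 0:
            continue
        cs, ce = _cycle_bounds(grp.loc[grp["deep"]])
        cover = float(np.sum(np.clip(np.minimum(ce, span1) - np.maximum(cs, span0),
                                     0.0, None))) / span
        if cover <= cfg.coverage_min:
            continue
        row = _aggregate_rows(ana)
        row.update({"individual_id": ind, "bout_id": bout,
                    "start_s": span0, "end_s": span1,
                    "pct_time_deep": 100.0 * cover,
                    "night": int(grp["night"].iloc[0])})
        rows.append(row)
    if not rows:
        raise EmptyTableError("no bouts pass the >=3-dive and coverage rules")
    return ScaleTable("bout", pd.DataFrame(rows), SUPER_PREDICTORS)


def build_window_table(dives: pd.DataFrame, window_s: int,
                       cfg: AggregateConfig | None = None,
                       scale_name: str | None = None) -> ScaleTable:
    """Non-overlapping windows of ``window_s`` tiled from each bout's start.

    A window is kept iff deep-dive cycles overlap more than ``coverage_min``
    of it; dives are assigned to the window containing their start.
    """
    cfg = cfg or AggregateConfig()
    if scale_name is None:
        scale_name = {v: k for k, v in WINDOW_SECONDS.items()}.get(window_s,
                                                                   f"win{window_s}s")
    rows = []
    for (ind, bout), grp in dives.groupby(["individual_id", "bout_id"]):
        t0 = float(grp["start_s"].min())
        t1 = float(grp["end_s"].max())
        n_win = int((t1 - t0) // window_s)      # partial trailing window dropped
        if n_win == 0:
            continue
        deep = grp.loc[grp["deep"]]
        cs, ce = _cycle_bounds(deep)
        ana = _analysis_dives(grp)
        for j in range(n_win):
            w0, w1 = t0 + j * window_s, t0 + (j + 1) * window_s
            cover = float(np.sum(np.clip(np.minimum(ce, w1) - np.maximum(cs, w0),
                                         0.0, None))) / window_s
            if cover <= cfg.coverage_min:
                continue
            sub = ana.loc[(ana["start_s"] >= w0) & (ana["start_s"] < w1)]
            if len(sub) == 0:
                continue
            row = _aggregate_rows(sub)
            row.update({"individual_id": ind, "bout_id": bout,
                        "start_s": w0, "end_s": w1,
                        "pct_time_deep": 100.0 * cover,
                        "night": int(grp["night"].iloc[0])})
            rows.append(row)
    if not rows:
        raise EmptyTableError(
            f"no {window_s}-s windows pass the {cfg.coverage_min:.0%} "
            "deep-dive-cycle coverage rule")
    return ScaleTable(scale_name, pd.DataFrame(rows), SUPER_PREDICTORS)


def build_night_table(dives: pd.DataFrame, night_windows: dict,
                      recording_spans: dict | None = None,
                      cfg: AggregateConfig | None = None) -> ScaleTable:
    """One row per complete night per individual.

    ``night_windows`` maps individual id -> list of (start, end) seconds;
    ``recording_spans`` maps individual id -> (first, last) recorded second.
    Nights not fully covered by the recording are excluded.
    """
    cfg = cfg or AggregateConfig()
    rows = []
    for ind, grp in dives.groupby("individual_id"):
        windows = night_windows[ind]
        span = recording_spans.get(ind) if recording_spans else None
        for k, (ns, ne) in enumerate(windows):
            if span is not None and not (span[0] <= ns and span[1] >= ne):
                continue  # logger stopped during this night
            night_dives = grp.loc[grp["night"] == k]
            ana = _analysis_dives(night_dives)
            if len(ana) == 0:
                continue
            cs, ce = _cycle_bounds(night_dives.loc[night_dives["deep"]])
            cover = float(np.sum(np.clip(np.minimum(ce, ne) - np.maximum(cs, ns),
                                         0.0, None))) / (ne - ns)
            row = _aggregate_rows(ana)
            row.update({"individual_id": ind, "night": k,
                        "start_s": float(ns), "end_s": float(ne),
                        "pct_time_deep": 100.0 * cover})
            rows.append(row)
    if not rows:
        raise EmptyTableError("no complete nights with analysable dives")
    return ScaleTable("night", pd.DataFrame(rows), SUPER_PREDICTORS)


def standardize(table: ScaleTable, stats: dict | None = None) -> ScaleTable:
    """Centre and scale predictors; with ``stats`` given (e.g. training-set
    statistics during cross-validation), apply those instead of refitting."""
    df = table.df.copy()
    out_stats = {}
    for col in table.predictors:
        if stats is not None:
            mean, sd = stats[col]
        else:
            mean, sd = float(df[col].mean()), float(df[col].std(ddof=0))
        if sd < 1e-12:
            raise ValueError(f"zero-variance predictor column: {col}")
        df[col] = (df[col] - mean) / sd
        out_stats[col] = (mean, sd)
    return ScaleTable(table.scale, df, table.predictors, table.response, out_stats)


def destandardize(table: ScaleTable) -> ScaleTable:
    """Invert :func:`standardize` (round-trip support)."""
    if table.stats is None:
        return table
    df = table.df.copy()
    for col, (mean, sd) in table.stats.items():
        df[col] = df[col] * sd + mean
    return ScaleTable(table.scale, df, table.predictors, table.response, None)


def build_all_tables(dives: pd.DataFrame, night_windows: dict,
                     recording_spans: dict | None = None,
                     cfg: AggregateConfig | None = None,
                     scales: tuple = ("dive", "bout", "win30", "win60",
                                      "win120", "night")) -> dict:
    """All requested scale tables (raw, unstandardized); scales whose
    filters remove every row are skipped with a note."""
    cfg = cfg or AggregateConfig()
    if "surface_duration" not in dives.columns or "night" not in dives.columns:
        dives = attach_context(dives, night_windows)
    out, skipped = {}, {}
    for scale in scales:
        try:
            if scale == "dive":
                out[scale] = build_dive_table(dives)
            elif scale == "bout":
                out[scale] = build_bout_table(dives, cfg)
            elif scale in WINDOW_SECONDS:
                out[scale] = build_window_table(dives, WINDOW_SECONDS[scale], cfg, scale)
            elif scale == "night":
                out[scale] = build_night_table(dives, night_windows,
                                               recording_spans, cfg)
            else:
                raise ValueError(f"unknown scale {scale}")
        except EmptyTableError as err:
            skipped[scale] = str(err)
    return {"tables": out, "skipped": skipped}
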