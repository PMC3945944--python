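"""Mouth-opening (prey capture attempt) detection from the jaw sensor.

Accelerometer pipeline: 3-Hz zero-phase high-pass on the horizontal channel
(removes head and body motion), centred 1.5-s moving-window variance, then
a threshold on the variance series; contiguous super-threshold runs merge
into single events. The Hall-sensor variant runs the same pipeline with a
5-s window and no high-pass (the sensor needs longer to return to baseline
and carries no body-motion component to remove).

The threshold is per-individual and robust by default — median + k * MADn of
the variance series (MADn = 1.4826 * median absolute deviation, the
normal-consistent scale), k = 6 — because what counts as "extreme" must not
be dragged by the events themselves. A moment rule (mean + k * sd) and an
absolute threshold are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .config import PcaConfig
from .series import AccelSeries


def highpass_filter(x: np.ndarray, rate_hz: float, cutoff_hz: float = 3.0,
                    order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth high-pass."""
    if cutoff_hz >= rate_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {rate_hz / 2} Hz")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def moving_variance(x: np.ndarray, rate_hz: float, window_s: float) -> np.ndarray:
    """Centred sliding-window sample variance, same length as input.

    Edges use truncated windows. Window must span >= 3 samples.
    """
    w = int(round(window_s * rate_hz))
    if w < 3:
        raise ValueError("variance window must span at least 3 samples")
    v = (pd.Series(np.asarray(x, dtype=float))
         .rolling(w, center=True, min_periods=2).var(ddof=1)
         .to_numpy())
    # fill the single-sample edge positions with the nearest defined value
    if np.isnan(v[0]):
        v[0] = v[1]
    if np.isnan(v[-1]):
        v[-1] = v[-2]
    return v


def variance_threshold(v: np.ndarray, cfg: PcaConfig | None = None) -> float:
    cfg = cfg or PcaConfig()
    if cfg.threshold_rule == "absolute":
        if cfg.threshold_abs is None:
            raise ValueError("absolute threshold rule needs threshold_abs")
        return float(cfg.threshold_abs)
    if cfg.threshold_rule == "moment":
        return float(np.mean(v) + cfg.threshold_k * np.std(v))
    med = np.median(v)
    madn = 1.4826 * np.median(np.abs(v - med))
    return float(med + cfg.threshold_k * madn)


def threshold_events(v: np.ndarray, times: np.ndarray,
                     cfg: PcaConfig | None = None,
                     threshold: float | None = None,
                     refine: np.ndarray | None = None) -> np.ndarray:
    """Event times from a variance series.

    Contiguous super-threshold runs (merged across gaps shorter than
    ``merge_gap_s``) become events; without a refinement series each run
    yields one event at its threshold-excess-weighted centroid, so two
    bursts closer than the variance window collapse into a single event.

    The moving window puts a flat ~(window + burst)-long top on every
    burst, so run maxima localize poorly and adjacent bursts share runs.
    ``refine`` — a short-window variance of the same filtered signal —
    restores sharp per-burst peaks: within each run, events are placed at
    its super-threshold peaks (>= 0.75 s apart), which both splits touching
    bursts and pins each event to well under half a second. A run in which
    the refinement series never exceeds its own robust threshold carries no
    burst-like spike and is rejected, suppressing the slow accumulation of
    chance variance excursions over multi-day records.
    """
    cfg = cfg or PcaConfig()
    v = np.asarray(v, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("variance series contains non-finite values")
    thr = variance_threshold(v, cfg) if threshold is None else threshold
    above = v > thr
    if not above.any():
        return np.array([], dtype=float)
    d = np.diff(above.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(v))
    runs = list(zip(starts, ends))
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    gap = max(1, int(round(cfg.merge_gap_s / dt)))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    def _centroid(a: int, b: int, series: np.ndarray, base: float) -> float:
        excess = np.clip(series[a:b] - base, 1e-12, None)
        return float(np.sum(times[a:b] * excess) / np.sum(excess))

    out = []
    if refine is None:
        for s, e in merged:
            out.append(_centroid(s, e, v, thr))
        return np.asarray(sorted(out), dtype=float)

    # localize within runs using the sharply peaked refinement series
    refine = np.asarray(refine, dtype=float)
    r_med = np.median(refine)
    r_thr = r_med + cfg.threshold_k * 1.4826 * np.median(np.abs(refine - r_med))
    min_sep = max(2, int(round(0.75 / dt)))
    for s, e in merged:
        seg = refine[s:e]
        peaks, _ = signal.find_peaks(seg, height=r_thr, distance=min_sep)
        if len(peaks) == 0:
            if seg.max() > r_thr:      # spike at the run edge: still a burst
                peaks = [int(np.argmax(seg))]
            else:
                continue               # no burst-like spike: reject the run
        for p in peaks:
            a = max(s, s + p - 3)
            b = min(e, s + p + 4)
            out.append(_centroid(a, b, refine, r_med))
    return np.asarray(sorted(out), dtype=float)


def detect_events(series: AccelSeries, cfg: PcaConfig | None = None) -> np.ndarray:
    """Full detection pipeline on one individual's jaw-sensor stream."""
    cfg = cfg or PcaConfig()
    x = series.ax
    if cfg.sensor_kind == "hall" or series.sensor_kind == "hall":
        v = moving_variance(x, series.rate_hz, cfg.hall_window_s)
        refine = None   # Hall signals relax slowly; no sharp peak to refine on
    else:
        x = highpass_filter(x, series.rate_hz, cfg.highpass_cutoff_hz)
        v = moving_variance(x, series.rate_hz, cfg.variance_window_s)
        refine = moving_variance(x, series.rate_hz, 5.0 / series.rate_hz)
    return threshold_events(v, series.time, cfg, refine=refine)


def assign_events_to_dives(event_times: np.ndarray, dives: pd.DataFrame
                           ) -> tuple[pd.DataFrame, np.ndarray]:
    """Map each event to the dive whose [start, end] contains it.

    Returns the dive table with a ``pca_count`` column and the times of
    surface events (outside every dive, excluded from modelling).
    """
    out = dives.copy()
    counts = np.zeros(len(out), dtype=int)
    surface = []
    starts = out["start_s"].to_numpy(dtype=float)
    ends = out["end_s"].to_numpy(dtype=float)
    order = np.argsort(starts)
    for t in np.asarray(event_times, dtype=float):
        i = np.searchsorted(starts[order], t, side="right") - 1
        if i >= 0 and t <= ends[order][i]:
            counts[order[i]] += 1
        else:
            surface.append(t)
    out["pca_count"] = counts
    return out, np.asarray(surface, dtype=float)
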