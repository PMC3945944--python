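"""Ground-truthed synthetic biologging data.

Emulates a multi-day foraging trip of a night-foraging diving predator:
1-Hz depth with trapezoidal dives organised in bouts inside explicit night
windows, brief step plateaus in transit, staircase excursions and wiggles in
the bottom phase, pressure-transducer surface-offset drift, and a 16-Hz
jaw-acceleration channel carrying one short high-amplitude transient per
true prey-capture attempt (PCA). Per-dive PCA counts follow a Poisson
log-link model on the dive's (within-trip standardized) predictors with an
individual random intercept, so the downstream mixed-model machinery is
exercised against a known generative truth.

Everything injected is recorded in :class:`SimTruth`; a fixed seed fixes the
full output bit-for-bit.

Profiles are built on the integer-second grid from per-second depth
increments, so on noise-free data phase boundaries and feature counts are
recovered exactly by the segmentation and feature detectors.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import AccelSeries, DepthSeries

#: dive-scale predictors of the PCA count model, in canonical order
DIVE_PREDICTORS = (
    "max_depth", "surface_duration", "descent_rate", "ascent_rate",
    "bottom_duration", "depth_variation_bottom", "steps_descent",
    "steps_ascent", "steps_descending_bottom", "steps_ascending_bottom",
    "wiggles",
)


@dataclass
class GlmmTruth:
    """True Poisson log-link model: log E[count] = intercept + z.beta + b_ind."""

    intercept: float = 0.058
    beta: dict = field(default_factory=lambda: {
        # defaults follow the magnitudes reported for Antarctic fur seals
        # at the dive scale (standardized predictors)
        "descent_rate": 0.240, "ascent_rate": 0.194, "surface_duration": 0.162,
        "steps_descending_bottom": 0.143, "max_depth": 0.091,
        "steps_descent": 0.075, "depth_variation_bottom": 0.074,
        "steps_ascent": 0.065, "bottom_duration": 0.025,
        "steps_ascending_bottom": 0.004, "wiggles": 0.004,
    })
    re_sd: float = 0.3


@dataclass
class SimConfig:
    """Study conditions for one simulated deployment."""

    n_individuals: int = 11
    n_nights: int = 9                      # trips last ~9.5 days
    night_window: tuple = ("21:00", "05:00")
    # (mean dives per bout, within-bout surface-interval mean s, between-bout gap mean s)
    bout_structure: tuple = (40, 40.0, 1800.0)
    # max-depth lognormal (median m, log-sd), descent/ascent speed ranges m/s,
    # bottom-duration lognormal (median s, log-sd)
    depth_median_m: float = 40.0
    depth_log_sd: float = 0.4
    descent_speed_range: tuple = (0.9, 1.4)
    ascent_speed_range: tuple = (0.8, 1.3)
    bottom_median_s: float = 45.0
    bottom_log_sd: float = 0.5
    shallow_fraction: float = 0.10         # dives below the 15-m modelling threshold
    # expected feature counts per deep dive
    feature_rates: dict = field(default_factory=lambda: {
        "steps_descent": 0.7, "steps_ascent": 0.5,
        "steps_descending_bottom": 0.8, "steps_ascending_bottom": 0.4,
        "wiggles": 0.5,
    })
    drift_amplitude_m: float = 1.0         # linear surface-offset trend over the trip
    depth_noise_sd: float = 0.1            # sensor resolution scale
    # (sample rate Hz, baseline noise sd, event amplitude multiple, event duration s)
    accel: tuple = (16.0, 1.0, 10.0, 0.3)
    body_sway_amp: float = 3.0             # low-frequency body acceleration, x baseline sd
    body_sway_hz: float = 0.35
    glmm_truth: GlmmTruth = field(default_factory=GlmmTruth)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.glmm_truth, dict):
            self.glmm_truth = GlmmTruth(**self.glmm_truth)
        if self.night_duration_s() <= 0:
            raise ValueError("night window has zero length")
        if self.accel[2] <= 1:
            raise ValueError("event amplitude multiple must exceed 1")
        for k, v in self.feature_rates.items():
            if v < 0:
                raise ValueError(f"negative feature rate {k}")
        if self.depth_noise_sd < 0 or self.drift_amplitude_m < 0:
            raise ValueError("noise and drift scales must be non-negative")
        if min(self.descent_speed_range) <= 0.4 or min(self.ascent_speed_range) <= 0.4:
            raise ValueError("transit speeds must exceed the 0.4 m/s phase threshold")

    # -- timeline --------------------------------------------------------
    def night_duration_s(self) -> int:
        start = _clock_to_s(self.night_window[0])
        end = _clock_to_s(self.night_window[1])
        return int((end - start) % 86400)

    def night_windows(self) -> list[tuple[int, int]]:
        """Night k occupies [k*86400, k*86400 + duration); t=0 is first dusk."""
        dur = self.night_duration_s()
        return [(k * 86400, k * 86400 + dur) for k in range(self.n_nights)]

    def trip_duration_s(self) -> int:
        return (self.n_nights - 1) * 86400 + self.night_duration_s() + 600


def _clock_to_s(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 3600 + int(m) * 60


@dataclass
class SimTruth:
    """Everything injected into one simulated trip."""

    individual_id: str
    b_individual: float
    dives: pd.DataFrame            # one row per dive with true boundaries/features/counts
    event_times: np.ndarray        # true mouth-opening times, s
    night_windows: list
    drift_amplitude_m: float

    def write_json(self, path: str | Path) -> None:
        payload = {
            "individual_id": self.individual_id,
            "b_individual": self.b_individual,
            "night_windows": [list(w) for w in self.night_windows],
            "drift_amplitude_m": self.drift_amplitude_m,
            "event_times": [round(float(t), 4) for t in self.event_times],
            "dives": json.loads(self.dives.to_json(orient="records", double_precision=6)),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["individual_id"], d["b_individual"], pd.DataFrame(d["dives"]),
                   np.asarray(d["event_times"], dtype=float),
                   [tuple(w) for w in d["night_windows"]], d["drift_amplitude_m"])


# ---------------------------------------------------------------------------
# dive profile construction (per-second increments -> exact grid alignment)
# ---------------------------------------------------------------------------

def _build_descent(rng, depth0: float, speed_range, n_steps: int, ascending=False):
    """Per-second increments from surface to depth0 with `n_steps` plateaus.

    Plateaus (1-s rate 0 < 0.4 m/s, duration 2-5 s) are placed between 20 %
    and 50 % of the transit depth so they always qualify as transit steps.
    Returns (deltas, n_steps_actually_inserted).
    """
    v = rng.uniform(*speed_range)
    n = max(2, int(round(depth0 / v)))
    inc = depth0 / n
    deltas = [inc] * n
    placed = []
    for _ in range(n_steps):
        idx = int(round(rng.uniform(0.2, 0.5) * n))
        if all(abs(idx - p) >= 3 for p in placed) and 1 <= idx < n - 1:
            placed.append(idx)
    for idx in sorted(placed, reverse=True):
        length = int(rng.integers(2, 6))
        deltas[idx:idx] = [0.0] * length
    if ascending:
        deltas = [-d for d in reversed(deltas)]
    return deltas, len(placed)


def _build_bottom(rng, depth0: float, target_dur: float, n_wig: int,
                  n_sdb: int, n_sab: int):
    """Bottom-phase increments starting and ending at flat water.

    Components: standalone descending steps (staircase deeper), standalone
    ascending steps, and wiggles (ascending step then descending step with a
    gap < 3 s). Flat gaps >= 4 s separate components so runs never merge and
    no spurious wiggle pairs arise. Total staircase drop is capped at half
    the entry depth so the bottom always sits below 60 % of max dive depth
    (which keeps phase segmentation unambiguous).
    """
    comps = []  # (deltas, kind)
    drop_budget = 0.5 * depth0
    rise_budget = 0.3 * depth0
    for _ in range(n_sdb):
        r = rng.uniform(0.55, 1.0)
        length = int(rng.integers(2, 4))
        if r * length <= drop_budget:
            drop_budget -= r * length
            comps.append(([r] * length, "sdb"))
    for _ in range(n_sab):
        r = rng.uniform(0.55, 1.0)
        length = int(rng.integers(2, 4))
        if r * length <= rise_budget:
            rise_budget -= r * length
            comps.append(([-r] * length, "sab"))
    for _ in range(n_wig):
        r = rng.uniform(0.55, 1.0)
        length = int(rng.integers(2, 4))
        gap = int(rng.integers(0, 3))
        comps.append(([-r] * length + [0.0] * gap + [r] * length, "wig"))
    rng.shuffle(comps)

    counts = {"sdb": 0, "sab": 0, "wig": 0}
    for _, kind in comps:
        counts[kind] += 1

    n_flats = len(comps) + 1
    flats = [4] * n_flats
    flats[0] = 3   # lead-in after descent terminates
    flats[-1] = 3  # trail before ascent begins
    needed = sum(flats) + sum(len(c) for c, _ in comps)
    extra = max(0, int(round(target_dur)) - needed)
    if extra > 0:
        add = rng.multinomial(extra, [1.0 / n_flats] * n_flats)
        flats = [f + int(a) for f, a in zip(flats, add)]

    deltas = []
    for i, (c, _) in enumerate(comps):
        deltas.extend([0.0] * flats[i])
        deltas.extend(c)
    deltas.extend([0.0] * flats[-1])
    return deltas, counts


def _build_deep_dive(rng, cfg: SimConfig):
    depth0 = float(np.clip(rng.lognormal(math.log(cfg.depth_median_m), cfg.depth_log_sd),
                           18.0, 150.0))
    fr = cfg.feature_rates
    desc, n_sd = _build_descent(rng, depth0, cfg.descent_speed_range,
                                rng.poisson(fr["steps_descent"]))
    bottom, bcounts = _build_bottom(
        rng, depth0,
        np.clip(rng.lognormal(math.log(cfg.bottom_median_s), cfg.bottom_log_sd), 10, 240),
        rng.poisson(fr["wiggles"]), rng.poisson(fr["steps_descending_bottom"]),
        rng.poisson(fr["steps_ascending_bottom"]))
    final_level = depth0 + sum(bottom)
    asc, n_sa = _build_descent(rng, final_level, cfg.ascent_speed_range,
                               rng.poisson(fr["steps_ascent"]), ascending=True)
    deltas = desc + bottom + asc
    profile = np.concatenate([[0.0], np.cumsum(deltas)])
    profile[-1] = 0.0  # kill float residue at the final surface sample
    i_bs = len(desc)
    i_as = len(desc) + len(bottom)
    truth = {
        "deep": True,
        "descent_end_idx": i_bs, "ascent_start_idx": i_as,
        "max_depth": float(profile.max()),
        "depth_bottom_start": float(profile[i_bs]),
        "depth_bottom_end": float(profile[i_as]),
        "steps_descent": n_sd, "steps_ascent": n_sa,
        "steps_descending_bottom": bcounts["sdb"] + bcounts["wig"],
        "steps_ascending_bottom": bcounts["sab"] + bcounts["wig"],
        "wiggles": bcounts["wig"],
    }
    return profile, truth


def _build_shallow_dive(rng):
    depth0 = rng.uniform(4.0, 12.0)
    desc, _ = _build_descent(rng, depth0, (0.6, 0.9), 0)
    flat = [0.0] * int(rng.integers(4, 13))
    asc, _ = _build_descent(rng, depth0, (0.6, 0.9), 0, ascending=True)
    deltas = desc + flat + asc
    profile = np.concatenate([[0.0], np.cumsum(deltas)])
    profile[-1] = 0.0
    i_bs, i_as = len(desc), len(desc) + len(flat)
    truth = {
        "deep": False, "descent_end_idx": i_bs, "ascent_start_idx": i_as,
        "max_depth": float(profile.max()),
        "depth_bottom_start": float(profile[i_bs]),
        "depth_bottom_end": float(profile[i_as]),
        "steps_descent": 0, "steps_ascent": 0,
        "steps_descending_bottom": 0, "steps_ascending_bottom": 0, "wiggles": 0,
    }
    return profile, truth


# ---------------------------------------------------------------------------
# trip assembly
# ---------------------------------------------------------------------------

def _individual_stream(seed: int, individual_id: str) -> np.random.Generator:
    digest = hashlib.sha256(individual_id.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2 ** 31)
    return np.random.default_rng([seed, sub])


def simulate_trip(config: SimConfig, individual_id: str):
    """Generate one individual's trip.

    Returns ``(DepthSeries, AccelSeries, SimTruth)``. The random stream is
    keyed by ``(config.seed, individual_id)`` so per-individual output is
    reproducible independent of generation order.
    """
    rng = _individual_stream(config.seed, individual_id)
    T = config.trip_duration_s()
    mean_dives, within_mean, between_mean = config.bout_structure

    rows = []
    profiles = []
    bout_label = 0
    for night_idx, (ns, ne) in enumerate(config.night_windows()):
        cursor = ns + int(round(rng.exponential(300.0))) + 5
        while cursor < ne - 600:
            bout_label += 1
            n_dives = int(rng.geometric(1.0 / mean_dives))
            for _ in range(n_dives):
                deep = rng.uniform() >= config.shallow_fraction
                profile, tr = (_build_deep_dive(rng, config) if deep
                               else _build_shallow_dive(rng))
                n = len(profile)
                if cursor + n > ne - 60:
                    break
                interval = 8 + int(round(rng.exponential(max(within_mean - 8, 1.0))))
                tr.update({
                    "start_s": cursor, "end_s": cursor + n - 1,
                    "descent_end_s": cursor + tr.pop("descent_end_idx"),
                    "ascent_start_s": cursor + tr.pop("ascent_start_idx"),
                    "post_dive_interval": interval,
                    "bout": bout_label, "night": night_idx,
                })
                rows.append(tr)
                profiles.append((cursor, profile))
                cursor += (n - 1) + interval
            cursor += int(round(rng.exponential(between_mean)))

    dives = pd.DataFrame(rows)
    if len(dives):
        dives["dive_duration"] = dives["end_s"] - dives["start_s"]
        dives["descent_duration"] = dives["descent_end_s"] - dives["start_s"]
        dives["bottom_duration"] = dives["ascent_start_s"] - dives["descent_end_s"]
        dives["ascent_duration"] = dives["end_s"] - dives["ascent_start_s"]
        dives["descent_rate"] = dives["depth_bottom_start"] / dives["descent_duration"]
        dives["ascent_rate"] = dives["depth_bottom_end"] / dives["ascent_duration"]
        dives["surface_duration"] = dives["post_dive_interval"].astype(float)
        dives["depth_variation_bottom"] = dives["max_depth"] - dives["depth_bottom_start"]

    # --- true PCA counts: Poisson log-link on within-trip standardized predictors
    b_ind = rng.normal(0.0, config.glmm_truth.re_sd)
    counts = np.zeros(len(dives), dtype=int)
    if len(dives):
        deep_mask = dives["deep"].to_numpy()
        eta = np.full(len(dives), -1.5)  # shallow dives: sparse background captures
        if deep_mask.any():
            z = np.zeros(deep_mask.sum())
            eta_deep = np.full(deep_mask.sum(), config.glmm_truth.intercept)
            sub = dives.loc[deep_mask]
            for name, beta in config.glmm_truth.beta.items():
                col = sub[name].to_numpy(dtype=float)
                sd = col.std()
                z = (col - col.mean()) / sd if sd > 1e-12 else np.zeros_like(col)
                eta_deep += beta * z
            eta[deep_mask] = eta_deep
        lam = np.exp(np.clip(eta + b_ind, -30, 6))
        counts = rng.poisson(lam)

    # --- event placement inside each dive
    event_times = []
    per_dive_placed = []
    for (t0, profile), (_, row), c in zip(profiles, dives.iterrows(), counts):
        placed = _place_events(rng, row, c)
        per_dive_placed.append(len(placed))
        event_times.extend(placed)
    if len(dives):
        dives["pca_count"] = per_dive_placed
    event_times = np.asarray(sorted(event_times), dtype=float)

    # --- depth series: profiles + linear surface-offset drift + noise
    depth = np.zeros(T)
    for t0, profile in profiles:
        depth[t0:t0 + len(profile)] = profile
    t = np.arange(T, dtype=float)
    depth += config.drift_amplitude_m * (t / max(T - 1, 1))
    if config.depth_noise_sd > 0:
        depth += rng.normal(0.0, config.depth_noise_sd, T)
    depth_series = DepthSeries(individual_id, t, depth)

    # --- acceleration series: baseline noise + body sway + event bursts
    fs, base_sd, amp_mult, ev_dur = config.accel
    n16 = int(round(T * fs))
    t16 = np.arange(n16) / fs
    ax = rng.normal(0.0, base_sd, n16)
    ay = rng.normal(0.0, base_sd, n16)
    phase = rng.uniform(0, 2 * np.pi)
    sway = config.body_sway_amp * base_sd * np.sin(2 * np.pi * config.body_sway_hz * t16 + phase)
    ax += sway
    ay += 0.5 * sway
    L = max(3, int(round(ev_dur * fs)))
    tau = np.arange(L) / fs
    burst = (amp_mult * base_sd * np.hanning(L) * np.sin(2 * np.pi * 6.0 * tau + 0.7))
    for te in event_times:
        i0 = int(round(te * fs)) - L // 2
        if 0 <= i0 and i0 + L <= n16:
            ax[i0:i0 + L] += burst
    accel_series = AccelSeries(individual_id, t16, ax, ay, rate_hz=fs)

    truth = SimTruth(individual_id, float(b_ind), dives, event_times,
                     config.night_windows(), config.drift_amplitude_m)
    return depth_series, accel_series, truth


def _place_events(rng, row, count: int) -> list[float]:
    """Place `count` event times inside one dive, >=2 s apart (bottom first)."""
    if count <= 0:
        return []
    lo, hi = row["descent_end_s"] + 1.0, row["ascent_start_s"] - 1.0
    if hi - lo < 2.0 * count:
        lo, hi = row["start_s"] + 2.0, row["end_s"] - 2.0
    grid = np.arange(lo, hi, 2.0)
    if len(grid) == 0:
        return []
    k = min(count, len(grid))
    chosen = rng.choice(grid, size=k, replace=False)
    return sorted(float(c + rng.uniform(-0.25, 0.25)) for c in chosen)


def simulate_study(config: SimConfig):
    """Yield ``(individual_id, DepthSeries, AccelSeries, SimTruth)`` per animal."""
    for i in range(config.n_individuals):
        ind = f"ID{i + 1:03d}"
        yield (ind, *simulate_trip(config, ind))


# ---------------------------------------------------------------------------
# standalone generative pieces for model-layer testing
# ---------------------------------------------------------------------------

def simulate_pca_counts(table: pd.DataFrame, truth: GlmmTruth, seed: int,
                        group_col: str = "individual_id") -> np.ndarray:
    """Draw counts ~ Poisson(exp(intercept + z.beta + b_group)) for a table
    of standardized predictors. b ~ Normal(0, re_sd^2) per group."""
    rng = np.random.default_rng(seed)
    eta = np.full(len(table), float(truth.intercept))
    for name, beta in truth.beta.items():
        eta += beta * table[name].to_numpy(dtype=float)
    groups = table[group_col].to_numpy()
    uniq = pd.unique(groups)
    b = dict(zip(uniq, rng.normal(0.0, truth.re_sd, len(uniq))))
    eta += np.array([b[g] for g in groups])
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    return rng.poisson(np.exp(np.clip(eta, -700, 30)))


def simulate_model_table(n_rows: int, n_individuals: int, truth: GlmmTruth,
                         seed: int, extra_predictors: tuple = ()) -> pd.DataFrame:
    """i.i.d. standard-normal predictor table with Poisson GLMM counts.

    Predictors are the keys of ``truth.beta`` plus any ``extra_predictors``
    (which get true coefficient 0). Rows are split evenly across individuals.
    """
    rng = np.random.default_rng(seed)
    names = list(truth.beta) + [p for p in extra_predictors if p not in truth.beta]
    df = pd.DataFrame(rng.standard_normal((n_rows, len(names))), columns=names)
    df["individual_id"] = [f"ID{i % n_individuals + 1:03d}" for i in range(n_rows)]
    df["pca_count"] = simulate_pca_counts(df, truth, seed=seed + 1)
    return df
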