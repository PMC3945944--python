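"""Dive-bout allocation via a maximum-likelihood bout-ending criterion (BEC).

Sequential dives cluster into bouts. Following the classical two-process
view, the criterion variable (by default the absolute successive differences
of post-dive surface intervals) is modelled as a mixture of two exponential
processes — a fast within-bout process and a slow between-bout one:

    f(x) = p * lam_f * exp(-lam_f x) + (1 - p) * lam_s * exp(-lam_s x)

fitted by direct numerical maximisation of the log-likelihood from three
moment-based starting points. The BEC is the abscissa where the two weighted
component densities intersect:

    x* = log((p * lam_f) / ((1 - p) * lam_s)) / (lam_f - lam_s)

Bout assignment then applies the BEC as a threshold on the raw post-dive
intervals (a difference threshold cannot delimit bouts directly); dives in
bouts of fewer than 3 dives are excluded, as is the terminal dive of each
bout (its post-dive interval reflects behaviours other than recovery).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .config import BoutConfig


class BoutFitError(RuntimeError):
    """Mixture fit failed; inspect the interval data."""


@dataclass
class BoutCriterion:
    bec_s: float
    lambda_fast: float        # rate of the within-bout process (1/s)
    lambda_slow: float        # rate of the between-bout process (1/s)
    p_fast: float             # mixing proportion of the fast process
    loglik: float
    n: int
    criterion_variable: str = "diffs"

    @property
    def mean_fast(self) -> float:
        return 1.0 / self.lambda_fast

    @property
    def mean_slow(self) -> float:
        return 1.0 / self.lambda_slow

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def bec_intersection(p: float, lam_f: float, lam_s: float) -> float:
    """Closed-form crossing point of the two weighted exponential densities."""
    return float(np.log((p * lam_f) / ((1.0 - p) * lam_s)) / (lam_f - lam_s))


def _nll(theta: np.ndarray, x: np.ndarray) -> float:
    p = expit(theta[0])
    lf, ls = np.exp(theta[1]), np.exp(theta[2])
    a = np.log(p) + np.log(lf) - lf * x
    b = np.log1p(-p) + np.log(ls) - ls * x
    return -float(np.sum(np.logaddexp(a, b)))


def fit_bout_criterion(intervals: np.ndarray,
                       cfg: BoutConfig | None = None) -> BoutCriterion:
    """Fit the two-exponential mixture and return the BEC.

    ``intervals`` are non-negative durations (seconds) of whichever
    criterion variable the caller uses (absolute successive differences of
    post-dive intervals in the standard pipeline). Requires >= 20 values.
    """
    cfg = cfg or BoutConfig()
    x = np.asarray(intervals, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < cfg.min_intervals:
        raise BoutFitError(f"need >= {cfg.min_intervals} intervals, got {len(x)}")
    if (x < 0).any():
        raise BoutFitError("negative interval durations")
    if np.ptp(x) < 1e-9:
        raise BoutFitError("all intervals identical; no mixture identifiable")
    x = np.maximum(x, 1e-6)

    m = x.mean()
    med = np.median(x)
    # three moment-based starts: split around the median / mean / upper quartile
    q75 = np.quantile(x, 0.75)
    starts = []
    for split in (med, m, q75):
        fast = x[x <= split]
        slow = x[x > split]
        if len(fast) < 2 or len(slow) < 2:
            continue
        starts.append([np.log(len(fast) / len(slow)),
                       -np.log(max(fast.mean(), 1e-6)),
                       -np.log(max(slow.mean(), 1e-6))])
    if not starts:
        starts = [[0.0, -np.log(med + 1e-6), -np.log(m * 2 + 1e-6)]]

    best = None
    for s0 in starts:
        res = minimize(_nll, np.asarray(s0), args=(x,), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise BoutFitError("mixture optimisation did not converge")

    p = float(expit(best.x[0]))
    lf, ls = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    if lf < ls:  # keep "fast" = short intervals = large rate
        lf, ls, p = ls, lf, 1.0 - p
    if lf <= ls or not (0.0 < p < 1.0):
        raise BoutFitError(
            "degenerate mixture at optimum (fast rate <= slow rate); "
            "inspect the interval distribution")
    return BoutCriterion(bec_intersection(p, lf, ls), lf, ls, p,
                         -float(best.fun), len(x),
                         cfg.criterion_variable if cfg else "diffs")


def criterion_variable(post_dive_intervals: np.ndarray,
                       cfg: BoutConfig | None = None) -> np.ndarray:
    """The quantity the mixture is fitted to."""
    cfg = cfg or BoutConfig()
    iv = np.asarray(post_dive_intervals, dtype=float)
    iv = iv[np.isfinite(iv)]
    if cfg.criterion_variable == "raw_intervals":
        return iv
    return np.abs(np.diff(iv))


def assign_bouts(dives: pd.DataFrame, bec_s: float) -> pd.DataFrame:
    """Label time-ordered dives with contiguous bout ids.

    A new bout starts after any post-dive surface interval exceeding the
    BEC. Invariant to uniform time translation (only intervals matter).
    """
    out = dives.sort_values("start_s").copy()
    iv = out["post_dive_interval"].to_numpy(dtype=float)
    breaks = np.zeros(len(out), dtype=bool)
    if len(out) > 1:
        prev = iv[:-1]
        breaks[1:] = ~np.isfinite(prev) | (prev > bec_s)
    out["bout_id"] = np.cumsum(breaks) + 1
    return out


def apply_inclusion_rules(dives: pd.DataFrame,
                          cfg: BoutConfig | None = None) -> pd.DataFrame:
    """Flag dives entering the models: bouts need >= 3 dives, and the
    terminal dive of each bout is excluded."""
    cfg = cfg or BoutConfig()
    out = dives.copy()
    sizes = out.groupby("bout_id")["bout_id"].transform("size")
    last_in_bout = ~out.duplicated("bout_id", keep="last") if len(out) else \
        pd.Series(dtype=bool)
    included = (sizes >= cfg.min_bout_dives) & ~last_in_bout
    out["included"] = included
    return out


def allocate_bouts(dives: pd.DataFrame, cfg: BoutConfig | None = None
                   ) -> tuple[pd.DataFrame, BoutCriterion]:
    """Full bout stage: fit the BEC on this individual's intervals, assign
    bout ids, and apply the inclusion rules."""
    cfg = cfg or BoutConfig()
    x = criterion_variable(dives["post_dive_interval"].to_numpy(), cfg)
    crit = fit_bout_criterion(x, cfg)
    out = apply_inclusion_rules(assign_bouts(dives, crit.bec_s), cfg)
    return out, crit
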