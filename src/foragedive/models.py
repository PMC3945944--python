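"""Poisson regression with individual random intercepts, all-subsets AICc
ranking, and Akaike-weight model averaging.

The mixed model is

    count_ij ~ Poisson(mu_ij),  log mu_ij = x_ij . beta + b_i,
    b_i ~ Normal(0, sigma_b^2)

with the marginal likelihood integrated over b by adaptive Gauss-Hermite
quadrature (default 15 nodes): per individual the integrand is proportional
to exp(S_i b - E_i e^b) with S_i the summed counts and E_i the summed
exp(linear predictor), so the mode and curvature are found by a scalar
Newton iteration and the quadrature grid is centred and scaled there.
Without a random intercept the model reduces to a plain Poisson GLM fitted
by Newton iteration (the night-scale path).

Model selection fits every predictor subset up to a per-scale cap (chosen
so that each tested variable has at least 10 rows), ranks by AICc

    AICc = -2 l + 2k + 2k(k+1)/(n - k - 1)

and averages the smallest weight-ordered candidate set whose cumulative
Akaike weight exceeds 0.95 (re-normalised). Averaging is full
(zero-substitution): a predictor absent from a candidate model contributes
a zero coefficient, and its importance weight is the summed weight of the
candidate models containing it. Unconditional standard errors combine
within-model variance and between-model coefficient spread
(Burnham-Anderson).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import gammaln

from .aggregate import ScaleTable
from .config import ModelConfig


class ModelError(RuntimeError):
    pass


@dataclass
class ModelFit:
    """One fitted candidate model (coefficients on the link scale,
    standardized predictors)."""

    predictors: tuple
    coef: np.ndarray               # intercept first, then predictors in order
    se: np.ndarray | None          # computed lazily for mixed models
    re_sd: float | None            # None for plain GLM
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    _se_fn: object = None          # deferred observed-information computation

    def ensure_se(self) -> np.ndarray:
        if self.se is None:
            self.se = self._se_fn()
        return self.se

    def coef_dict(self) -> dict:
        d = {"intercept": float(self.coef[0])}
        d.update({p: float(c) for p, c in zip(self.predictors, self.coef[1:])})
        return d

    def se_dict(self) -> dict:
        self.ensure_se()
        d = {"intercept": float(self.se[0])}
        d.update({p: float(s) for p, s in zip(self.predictors, self.se[1:])})
        return d


@dataclass
class AveragedModel:
    """Model-averaged coefficients with importance weights."""

    scale: str
    intercept: float
    intercept_se: float
    coef: dict                     # predictor -> averaged coefficient
    se: dict                       # predictor -> unconditional SE
    importance: dict               # predictor -> summed candidate weight
    candidates: list               # (predictors, renormalised weight)
    re_sd: float | None
    use_random_intercept: bool
    cumulative_weight: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"predictor": "intercept", "w": 1.0,
                 "coef": self.intercept, "se": self.intercept_se}]
        for p in self.coef:
            rows.append({"predictor": p, "w": self.importance[p],
                         "coef": self.coef[p], "se": self.se[p]})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain Poisson GLM (Newton / IRLS)
# ---------------------------------------------------------------------------

def _fit_glm(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-8))
    converged = False
    for _ in range(60):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:
            raise ModelError(f"degenerate design matrix: {err}") from err
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    ll = float(y @ eta - mu.sum() - gammaln(y + 1).sum())
    H = (X * mu[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    return beta, se, ll, converged


# ---------------------------------------------------------------------------
# Poisson GLMM via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

class _GlmmProblem:
    """Precomputed structures for one response/design/grouping triple."""

    def __init__(self, y, X, groups, n_quad=15):
        order = np.argsort(groups, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.X = np.asarray(X, dtype=float)[order]
        g = np.asarray(groups)[order]
        _, starts, inverse = np.unique(g, return_index=True, return_inverse=True)
        # np.unique sorts; with pre-sorted g the starts are increasing
        self.starts = np.sort(starts)
        self.row_group = inverse
        self.G = len(self.starts)
        self.S = np.add.reduceat(self.y, self.starts)
        self.const = float(gammaln(self.y + 1).sum())
        self.Xty = self.X.T @ self.y
        xq, wq = hermgauss(n_quad)
        self.xq = xq
        self.xq2_logw = xq ** 2 + np.log(wq)
        self.modes = np.zeros(self.G)   # warm-started across evaluations

    def subproblem(self, cols: list) -> "_GlmmProblem":
        """A column-sliced view sharing the precomputed group structures
        (used by the all-subsets enumeration)."""
        sub = object.__new__(_GlmmProblem)
        sub.y = self.y
        sub.X = self.X[:, cols]
        sub.starts = self.starts
        sub.row_group = self.row_group
        sub.G = self.G
        sub.S = self.S
        sub.const = self.const
        sub.Xty = self.Xty[cols]
        sub.xq = self.xq
        sub.xq2_logw = self.xq2_logw
        sub.modes = self.modes.copy()
        return sub

    def objective(self, theta):
        """(negative marginal loglik, gradient) at theta = [beta, log sigma]."""
        beta, log_sigma = theta[:-1], theta[-1]
        inv_s2 = np.exp(-2.0 * log_sigma)
        eta = self.X @ beta
        np.clip(eta, -30, 30, out=eta)
        e = np.exp(eta)
        E = np.add.reduceat(e, self.starts)
        # inner Newton for the per-group posterior mode of b (warm-started;
        # steps are damped, so |m| stays within exp() range)
        m = self.modes
        for _ in range(40):
            Eem = E * np.exp(m)
            step = (self.S - Eem - m * inv_s2) / (Eem + inv_s2)
            np.clip(step, -3.0, 3.0, out=step)
            m = m + step
            if np.abs(step).max() < 1e-9:
                break
        self.modes = m
        h = E * np.exp(m) + inv_s2
        # adapted nodes and log integrand (G x Q, both small)
        b = m[:, None] + np.sqrt(2.0 / h)[:, None] * self.xq
        eb = np.exp(np.clip(b, -60, 30))
        a = (self.S[:, None] * b - E[:, None] * eb
             - (0.5 * inv_s2) * b * b + self.xq2_logw)
        amax = a.max(axis=1)
        expa = np.exp(a - amax[:, None])
        sumexp = expa.sum(axis=1)
        ll = float((amax + np.log(sumexp) + 0.5 * np.log(2.0 / h)).sum()
                   + self.y @ eta - self.const
                   - self.G * (log_sigma + 0.5 * np.log(2 * np.pi)))

        # gradient with the adapted grid held fixed (quadrature is near-exact
        # at >= 10 nodes, so the adaptation terms are negligible)
        omega = expa / sumexp[:, None]
        wE = (omega * eb).sum(axis=1)                     # E_q[e^b] per group
        grad_beta = self.Xty - self.X.T @ (e * wE[self.row_group])
        wb2 = (omega * b * b).sum(axis=1)
        grad_ls = float((wb2 * inv_s2).sum() - self.G)
        grad = np.append(grad_beta, grad_ls)
        return -ll, -grad


def _glmm_se(prob, theta):
    """Standard errors from the observed information (central differences of
    the analytic gradient)."""
    q = len(theta)
    p = q - 1
    H = np.zeros((q, q))
    eps = 1e-5 * (1.0 + np.abs(theta))
    for j in range(q):
        tp = theta.copy()
        tp[j] += eps[j]
        tm = theta.copy()
        tm[j] -= eps[j]
        _, gp = prob.objective(tp)
        _, gm = prob.objective(tm)
        H[:, j] = (gp - gm) / (2 * eps[j])
    H = 0.5 * (H + H.T)
    try:
        diag = np.diag(np.linalg.inv(H))
        if (diag[:p] <= 0).any():
            return np.full(p, np.nan)
        return np.sqrt(diag[:p])
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _fit_glmm(prob: _GlmmProblem, p: int, start=None):
    """Maximize the adaptive-quadrature marginal likelihood for a problem
    whose design has ``p`` columns. Returns (beta, se_fn, sd, ll, conv, theta)."""
    if start is None:
        beta0, _, _, _ = _fit_glm(prob.y, prob.X)
        start = np.append(beta0, np.log(0.3))
    bounds = [(None, None)] * p + [(np.log(1e-3), np.log(5.0))]
    res = minimize(prob.objective, np.asarray(start, dtype=float), jac=True,
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-6})
    theta = res.x
    ll = -float(res.fun)
    converged = bool(res.success) or np.max(np.abs(res.jac)) < 1e-3
    se_fn = lambda: _glmm_se(prob, theta)  # noqa: E731  deferred: only candidates need SEs
    return theta[:p], se_fn, float(np.exp(theta[-1])), ll, converged, theta


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise ModelError(f"model too rich for the sample: k={k}, n={n}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_poisson_glmm(table: ScaleTable, subset: tuple,
                     use_random_intercept: bool = True,
                     cfg: ModelConfig | None = None,
                     start=None) -> ModelFit:
    """Fit one candidate model on a standardized scale table.

    ``subset`` is a tuple of predictor names; the intercept is always
    included. With ``use_random_intercept`` the individual identity enters
    as a Normal random intercept (one extra parameter, the sd).
    """
    cfg = cfg or ModelConfig()
    df = table.df
    y = df[table.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df))] +
                        [df[p].to_numpy(dtype=float) for p in subset])
    if not np.isfinite(X).all():
        raise ModelError("non-finite values in the design matrix")
    for j, p in enumerate(subset, start=1):
        if X[:, j].std() < 1e-12:
            raise ModelError(f"degenerate (zero-variance) column: {p}")
    n = len(y)
    if use_random_intercept:
        groups = df["individual_id"].to_numpy()
        prob = _GlmmProblem(y, X, groups, cfg.n_quad)
        beta, se_fn, sd, ll, conv, theta = _fit_glmm(prob, X.shape[1], start)
        k = len(subset) + 2            # intercept + slopes + random-intercept sd
        return ModelFit(tuple(subset), beta, None, sd, ll, k, n,
                        aicc(ll, k, n), conv, _se_fn=se_fn)
    beta, se, ll, conv = _fit_glm(y, X)
    k = len(subset) + 1
    return ModelFit(tuple(subset), beta, se, None, ll, k, n,
                    aicc(ll, k, n), conv)


def enumerate_and_rank(table: ScaleTable, candidates: tuple, max_vars: int,
                       use_random_intercept: bool = True,
                       cfg: ModelConfig | None = None) -> list[ModelFit]:
    """Fit every predictor subset of size 0..max_vars and rank by AICc."""
    cfg = cfg or ModelConfig()
    n = len(table.df)
    max_vars = min(max_vars, len(candidates))
    if max_vars * cfg.rows_per_variable > n:
        raise ModelError(
            f"cap of {max_vars} variables violates the "
            f"{cfg.rows_per_variable}-rows-per-variable rule at n={n}")
    fits = []
    if use_random_intercept:
        df = table.df
        y = df[table.response].to_numpy(dtype=float)
        X = np.column_stack([np.ones(n)] +
                            [df[p].to_numpy(dtype=float) for p in candidates])
        if not np.isfinite(X).all():
            raise ModelError("non-finite values in the design matrix")
        master = _GlmmProblem(y, X, df["individual_id"].to_numpy(), cfg.n_quad)
        # warm start every subset from the richest admissible model
        full_beta, full_sd = None, 0.3
        if n > 3 * (len(candidates) + 2):
            try:
                fb, _, fsd, _, fconv, _ = _fit_glmm(master, X.shape[1])
                if fconv:
                    full_beta = dict(zip(("intercept",) + tuple(candidates), fb))
                    full_sd = fsd
            except (ModelError, np.linalg.LinAlgError):
                pass
        col_of = {p: j + 1 for j, p in enumerate(candidates)}
        for size in range(0, max_vars + 1):
            for subset in itertools.combinations(candidates, size):
                cols = [0] + [col_of[p] for p in subset]
                prob = master.subproblem(cols)
                start = None
                if full_beta is not None:
                    start = np.array([full_beta["intercept"]] +
                                     [full_beta[p] for p in subset] +
                                     [np.log(max(full_sd, 1e-3))])
                try:
                    beta, se_fn, sd, ll, conv, _ = _fit_glmm(prob, len(cols), start)
                except (ModelError, np.linalg.LinAlgError) as err:
                    warnings.warn(f"skipping subset {subset}: {err}")
                    continue
                if not conv:
                    warnings.warn(f"non-converged fit dropped: {subset}")
                    continue
                k = len(subset) + 2
                fits.append(ModelFit(subset, beta, None, sd, ll, k, n,
                                     aicc(ll, k, n), True, _se_fn=se_fn))
    else:
        for size in range(0, max_vars + 1):
            for subset in itertools.combinations(candidates, size):
                try:
                    fit = fit_poisson_glmm(table, subset, False, cfg)
                except ModelError as err:
                    warnings.warn(f"skipping subset {subset}: {err}")
                    continue
                if not fit.converged:
                    warnings.warn(f"non-converged fit dropped: {subset}")
                    continue
                fits.append(fit)
    if not fits:
        raise ModelError("no candidate model converged")
    fits.sort(key=lambda f: (f.aicc, f.predictors))
    return fits


def aicc_weights(fits: list[ModelFit]) -> np.ndarray:
    """Akaike weights over the full enumeration (sum to 1)."""
    a = np.array([f.aicc for f in fits])
    if not np.isfinite(a).all():
        raise ModelError("non-finite AICc in ranking")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def model_average(fits: list[ModelFit], weights: np.ndarray,
                  threshold: float = 0.95, scale: str = "",
                  use_random_intercept: bool = True) -> AveragedModel:
    """Average the minimal weight-ordered candidate prefix exceeding the
    cumulative-weight threshold (re-normalised)."""
    order = np.argsort(-weights, kind="stable")
    cum = 0.0
    idx = []
    for i in order:
        idx.append(i)
        cum += weights[i]
        if cum > threshold:
            break
    cand = [fits[i] for i in idx]
    for f in cand:
        f.ensure_se()
    w = np.array([weights[i] for i in idx])
    w_norm = w / w.sum()

    all_predictors = sorted({p for f in fits for p in f.predictors})
    coef, se, importance = {}, {}, {}
    # intercept first
    b0 = np.array([f.coef[0] for f in cand])
    s0 = np.array([f.se[0] for f in cand])
    b0_bar = float(w_norm @ b0)
    s0_bar = float(w_norm @ np.sqrt(s0 ** 2 + (b0 - b0_bar) ** 2))
    for p in all_predictors:
        bj = np.zeros(len(cand))
        sj = np.zeros(len(cand))
        imp = 0.0
        for i, f in enumerate(cand):
            if p in f.predictors:
                j = f.predictors.index(p) + 1
                bj[i] = f.coef[j]
                sj[i] = f.se[j]
                imp += w_norm[i]
        bbar = float(w_norm @ bj)
        coef[p] = bbar
        se[p] = float(w_norm @ np.sqrt(sj ** 2 + (bj - bbar) ** 2))
        importance[p] = float(imp)
    re_sd = None
    if use_random_intercept:
        sds = np.array([f.re_sd if f.re_sd is not None else 0.0 for f in cand])
        re_sd = float(w_norm @ sds)
    return AveragedModel(scale, b0_bar, s0_bar, coef, se, importance,
                         [(f.predictors, float(wn)) for f, wn in zip(cand, w_norm)],
                         re_sd, use_random_intercept, float(cum))


def predict(model: AveragedModel | ModelFit, table: ScaleTable,
            population_level: bool = True) -> np.ndarray:
    """Expected counts for new rows (standardized with the training stats).

    The random intercept is set to zero for unseen individuals
    (population-level prediction)."""
    df = table.df
    if isinstance(model, ModelFit):
        coef = model.coef_dict()
        intercept = coef.pop("intercept")
    else:
        intercept = model.intercept
        coef = model.coef
    eta = np.full(len(df), intercept)
    for p, b in coef.items():
        if p not in df.columns:
            raise ModelError(f"missing predictor column: {p}")
        eta += b * df[p].to_numpy(dtype=float)
    return np.exp(np.clip(eta, -700, 30))


def ranked_model_frame(fits: list[ModelFit], weights: np.ndarray) -> pd.DataFrame:
    """Ranked-model table: subset, logLik, k, AICc, delta, weight, cum weight."""
    a = np.array([f.aicc for f in fits])
    rows = []
    for f, wgt, d in zip(fits, weights, a - a.min()):
        rows.append({"predictors": "+".join(f.predictors) or "(null)",
                     "logLik": f.loglik, "k": f.k, "AICc": f.aicc,
                     "delta": d, "weight": wgt})
    df = pd.DataFrame(rows)
    df["cum_weight"] = df["weight"].cumsum()
    return df
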