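"""Linear mixed model for the crossover design, with covariance selection.

The model is the marginal Gaussian repeated-measures model used for
within-subject crossover analyses: for subject *i* with the four nightly
observations stacked in night order,

    y_i = X_i beta + e_i,     e_i ~ N(0, Sigma(theta)),

with fixed effects order (crossover arm), place (HSL/MSL), timepoint
(first/second night at a place) and the place x timepoint interaction, and a
4x4 residual covariance shared across subjects.  Candidate structures are
compound symmetry (CS), first-order autoregressive over nights (AR1), and
unstructured (UN).  Each candidate is fit by REML; fits that fail to
converge or whose objective Hessian is not positive definite are discarded,
and the minimum-AIC fit among the survivors is selected (AIC = -2*restricted
log-likelihood + 2 x number of covariance parameters, the REML convention).

Degrees of freedom for the per-effect Wald F tests use the Satterthwaite
approximation (delta method on the covariance parameters with the observed
information); results carry ``df_method='satterthwaite'`` and a flag noting
that Kenward-Roger is not implemented in this backend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

FIXED_EFFECTS = ("intercept", "order", "place", "timepoint", "place_x_timepoint")
STRUCTURES = ("un", "ar1", "cs")

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class EffectTest:
    effect: str
    estimate: float
    se: float
    f: float
    df1: int
    df2: float
    p: float


@dataclass
class MixedModelFit:
    structure: str
    beta: np.ndarray
    sigma: np.ndarray
    neg2_reml: float
    aic: float
    converged: bool
    hessian_pd: bool
    theta: np.ndarray = field(default_factory=lambda: np.array([]))
    hessian: np.ndarray | None = None


@dataclass
class MixedModelResult:
    selected: MixedModelFit | None
    candidates: dict[str, MixedModelFit]
    effects: list[EffectTest]
    df_method: str = "satterthwaite"
    kenward_roger_available: bool = False
    n_subjects: int = 0

    @property
    def converged(self) -> bool:
        return self.selected is not None

    def effect(self, name: str) -> EffectTest:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _build_design(data: pd.DataFrame, variable: str):
    """Per-subject response vectors and design matrices in night order.

    Subjects with incomplete nights are dropped (logged): the repeated-
    measures covariance is defined over the full 4-night profile.
    Coding: order = 1 for the MSL-first arm, place = 1 for MSL,
    timepoint = 1 for the second night at a place, interaction = product.
    """
    ys, xs = [], []
    dropped = 0
    for _, grp in data.sort_values("night").groupby("subject"):
        if grp["night"].tolist() != [1, 2, 3, 4] or grp[variable].isna().any():
            dropped += 1
            continue
        y = grp[variable].to_numpy(float)
        place = (grp["place"] == "MSL").to_numpy(float)
        tp = (grp["timepoint"] == 2).to_numpy(float)
        order = float(grp["order"].iloc[0] == "MSL_first")
        x = np.column_stack([
            np.ones(4), np.full(4, order), place, tp, place * tp,
        ])
        ys.append(y)
        xs.append(x)
    if dropped:
        logger.info("mixed model: dropped %d subjects with incomplete nights",
                    dropped)
    if len(ys) < 3:
        raise InsufficientDataError(
            f"mixed model needs >= 3 complete subjects, got {len(ys)}"
        )
    return ys, xs


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _suff_stats(ys, xs):
    """Group subjects by design pattern for fast likelihood evaluation."""
    groups = {}
    for y, x in zip(ys, xs):
        key = x.tobytes()
        g = groups.setdefault(key, {"x": x, "m": 0, "syy": np.zeros((4, 4)),
                                    "sy": np.zeros(4)})
        g["m"] += 1
        g["syy"] += np.outer(y, y)
        g["sy"] += y
    return list(groups.values())


def _neg2_reml(sigma: np.ndarray, groups, n_total: int, p: int) -> tuple[float, np.ndarray, np.ndarray]:
    """-2 restricted log-likelihood; returns (value, beta_hat, C=cov(beta))."""
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    siginv = np.linalg.inv(sigma)

    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    yty = 0.0
    m_total = 0
    for g in groups:
        x, m = g["x"], g["m"]
        xs_inv = x.T @ siginv
        xtx += m * (xs_inv @ x)
        xty += xs_inv @ g["sy"]
        yty += float(np.trace(siginv @ g["syy"]))
        m_total += m
    try:
        c_inv = xtx
        beta = np.linalg.solve(c_inv, xty)
        c = np.linalg.inv(c_inv)
    except np.linalg.LinAlgError:
        return np.inf, np.full(p, np.nan), np.full((p, p), np.nan)
    quad = yty - float(beta @ xty)
    sign, logdet_xtx = np.linalg.slogdet(c_inv)
    if sign <= 0 or quad < 0:
        return np.inf, beta, c
    val = (m_total * logdet + logdet_xtx + quad
           + (n_total - p) * _LOG2PI)
    return val, beta, c


def _sigma_cs(theta: np.ndarray) -> np.ndarray:
    log_s2, z = theta
    rho = -1.0 / 3.0 + (1.0 + 1.0 / 3.0) / (1.0 + math.exp(-z))  # (-1/3, 1)
    s2 = math.exp(log_s2)
    return s2 * ((1 - rho) * np.eye(4) + rho * np.ones((4, 4)))


def _sigma_ar1(theta: np.ndarray) -> np.ndarray:
    log_s2, z = theta
    rho = math.tanh(z)
    s2 = math.exp(log_s2)
    idx = np.arange(4)
    return s2 * rho ** np.abs(idx[:, None] - idx[None, :])


def _sigma_un(theta: np.ndarray) -> np.ndarray:
    L = np.zeros((4, 4))
    tril = np.tril_indices(4)
    vals = np.array(theta, float).copy()
    diag_pos = [i for i, (r, c) in enumerate(zip(*tril)) if r == c]
    vals[diag_pos] = np.exp(vals[diag_pos])
    L[tril] = vals
    return L @ L.T


_STRUCTURE_MAP = {"cs": (_sigma_cs, 2), "ar1": (_sigma_ar1, 2),
                  "un": (_sigma_un, 10)}


def _initial_theta(structure: str, ys, xs) -> np.ndarray:
    """Start values from OLS residual moments."""
    x_all = np.vstack(xs)
    y_all = np.concatenate(ys)
    beta0, *_ = np.linalg.lstsq(x_all, y_all, rcond=None)
    resid = [y - x @ beta0 for y, x in zip(ys, xs)]
    emp = sum(np.outer(r, r) for r in resid) / len(resid)
    emp += 1e-8 * np.trace(emp) / 4.0 * np.eye(4) + 1e-12 * np.eye(4)
    s2 = float(np.trace(emp)) / 4.0
    off = emp[np.triu_indices(4, 1)].mean() / s2
    if structure == "cs":
        rho = float(np.clip(off, -0.32, 0.98))
        z = -math.log((1 + 1 / 3) / (rho + 1 / 3) - 1.0)
        return np.array([math.log(s2), z])
    if structure == "ar1":
        lag1 = np.mean([emp[i, i + 1] for i in range(3)]) / s2
        rho = float(np.clip(lag1, -0.98, 0.98))
        return np.array([math.log(s2), math.atanh(rho)])
    L = np.linalg.cholesky(emp)
    tril = np.tril_indices(4)
    vals = L[tril].copy()
    diag_pos = [i for i, (r, c) in enumerate(zip(*tril)) if r == c]
    vals[diag_pos] = np.log(np.maximum(vals[diag_pos], 1e-8))
    return vals


def _numeric_hessian(fun, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    k = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    hess = np.zeros((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / h[i] ** 2
            else:
                val = (
                    fun(theta + ei + ej) - fun(theta + ei - ej)
                    - fun(theta - ei + ej) + fun(theta - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def _numeric_grad(fun, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    k = theta.size
    h = rel_step * np.maximum(1.0, np.abs(theta))
    g = np.zeros(k)
    for i in range(k):
        e = np.zeros(k); e[i] = h[i]
        g[i] = (fun(theta + e) - fun(theta - e)) / (2 * h[i])
    return g


def _fit_structure(structure: str, ys, xs) -> MixedModelFit:
    groups = _suff_stats(ys, xs)
    n_total = 4 * len(ys)
    p = len(FIXED_EFFECTS)
    sigma_fun, q = _STRUCTURE_MAP[structure]

    def objective(theta):
        val, _, _ = _neg2_reml(sigma_fun(theta), groups, n_total, p)
        return val if np.isfinite(val) else 1e12

    theta0 = _initial_theta(structure, ys, xs)
    if q > 2:
        res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                                options={"maxiter": 300})
        if not res.success:
            res = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                    options={"xatol": 1e-7, "fatol": 1e-9,
                                             "maxiter": 4000})
    else:
        res = optimize.minimize(objective, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9,
                                         "maxiter": 4000})
    theta = res.x
    sigma = sigma_fun(theta)
    neg2, beta, _ = _neg2_reml(sigma, groups, n_total, p)
    converged = bool(res.success) and np.isfinite(neg2)

    hessian_pd = False
    hess = None
    if converged:
        try:
            hess = _numeric_hessian(objective, theta)
            hessian_pd = bool(np.all(np.linalg.eigvalsh(hess) >
                                     -1e-6 * max(1.0, abs(neg2))))
        except np.linalg.LinAlgError:
            hessian_pd = False

    return MixedModelFit(
        structure=structure, beta=beta, sigma=sigma, neg2_reml=neg2,
        aic=neg2 + 2 * q, converged=converged, hessian_pd=hessian_pd,
        theta=theta, hessian=hess,
    )


def _satterthwaite_df(fit: MixedModelFit, groups, n_total: int, p: int,
                      j: int) -> float:
    """Satterthwaite df for the j-th fixed-effect contrast.

    df = 2 (C_jj)^2 / (g' A g) with g the gradient of C_jj(theta) and A the
    asymptotic covariance of theta (2 x inverse Hessian of -2*REML).
    """
    sigma_fun, _ = _STRUCTURE_MAP[fit.structure]

    def objective(theta):
        val, _, _ = _neg2_reml(sigma_fun(theta), groups, n_total, p)
        return val if np.isfinite(val) else 1e12

    def cjj(theta):
        _, _, c = _neg2_reml(sigma_fun(theta), groups, n_total, p)
        return float(c[j, j])

    try:
        hess = fit.hessian if fit.hessian is not None else _numeric_hessian(
            objective, fit.theta)
        a = 2.0 * np.linalg.inv(hess)
        g = _numeric_grad(cjj, fit.theta)
        denom = float(g @ a @ g)
        c0 = cjj(fit.theta)
        if denom <= 0 or c0 <= 0:
            raise np.linalg.LinAlgError
        df = 2.0 * c0 ** 2 / denom
    except np.linalg.LinAlgError:
        logger.warning("Satterthwaite df fell back to residual df")
        return float(n_total - p)
    # guard against pathological tiny/huge df
    return float(np.clip(df, 1.0, n_total - p))


def fit_place_time_model(
    data: pd.DataFrame,
    variable: str,
    structures: tuple[str, ...] = STRUCTURES,
) -> MixedModelResult:
    """Fit the order + place + timepoint + place:timepoint model to one variable.

    ``data`` is the long study table (columns subject, night 1-4, place,
    timepoint, order, and the variable).  All candidate covariance
    structures are fit by REML; converged fits with positive-definite
    Hessians compete on AIC and the winner supplies the per-effect Wald F
    tests with Satterthwaite denominator df.  If no candidate survives, the
    result carries ``selected=None`` and per-candidate diagnostics.
    """
    ys, xs = _build_design(data, variable)
    groups = _suff_stats(ys, xs)
    n_total = 4 * len(ys)
    p = len(FIXED_EFFECTS)

    candidates: dict[str, MixedModelFit] = {}
    for structure in structures:
        try:
            candidates[structure] = _fit_structure(structure, ys, xs)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("structure %s failed: %s", structure, exc)

    valid = {s: f for s, f in candidates.items()
             if f.converged and f.hessian_pd}
    if not valid:
        logger.warning("no covariance structure converged for %s", variable)
        return MixedModelResult(selected=None, candidates=candidates,
                                effects=[], n_subjects=len(ys))

    selected = min(valid.values(), key=lambda f: f.aic)
    _, beta, c = _neg2_reml(selected.sigma, groups, n_total, p)

    effects = []
    for j, name in enumerate(FIXED_EFFECTS):
        if name == "intercept":
            continue
        se = math.sqrt(max(c[j, j], 0.0))
        f_stat = (beta[j] / se) ** 2 if se > 0 else math.inf
        df2 = _satterthwaite_df(selected, groups, n_total, p, j)
        p_val = float(stats.f.sf(f_stat, 1, df2)) if math.isfinite(f_stat) else 0.0
        effects.append(EffectTest(effect=name, estimate=float(beta[j]),
                                  se=se, f=float(f_stat), df1=1, df2=df2,
                                  p=p_val))

    return MixedModelResult(selected=selected, candidates=candidates,
                            effects=effects, n_subjects=len(ys))
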