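"""Mixed-effect autoregressive ordinal logistic regression.

The model for one AD sign: the score of patient k on day t+1 follows an
ordered-logistic distribution whose location is

    eta = alpha_k + sum_{i=0..3} beta_i * 1{s_k(t) = i} + gamma . x(t)

with ``alpha_k ~ Normal(0, sigma_alpha^2)`` a patient random intercept,
``beta_i`` coefficients of previous-score indicators (score 4 is the
reference category and contributes 0), ``gamma`` optional covariate effects
and ``c`` a vector of four strictly increasing cut-offs defining the five
category probabilities.

Estimation is maximum marginal likelihood: the random intercept is
integrated out per patient by adaptive Gauss-Hermite quadrature centered at
each patient's conditional mode.  Optimization alternates between freezing
the per-patient quadrature nodes and maximizing the resulting smooth
objective with L-BFGS-B using an exact analytic gradient, then re-adapting
the nodes; the alternation converges to a joint fixed point equivalent to
the adaptive-quadrature MLE up to quadrature-level error.  A small ridge
penalty on (beta, gamma) keeps estimates finite under separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .panel import (
    COVARIATES,
    SIGNS,
    CovariateStats,
    TransitionPair,
    standardize_covariates,
)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_PMF_FLOOR = 1e-300

K_CATEGORIES = 5


@dataclass(frozen=True)
class OrderedLogisticParams:
    """Cut-offs c1 < c2 < c3 < c4 of a 5-category ordered logistic."""

    cutpoints: tuple

    def __post_init__(self):
        c = np.asarray(self.cutpoints, dtype=float)
        if c.shape != (4,):
            raise ValueError("exactly 4 cutpoints required for 5 categories")
        if not np.all(np.diff(c) > 0):
            raise ValueError(f"cutpoints must be strictly increasing, got {c}")
        object.__setattr__(self, "cutpoints", tuple(float(v) for v in c))


@dataclass(frozen=True)
class ModelSpec:
    """Which sign to model and which covariates enter the linear predictor."""

    sign: str
    covariate_set: tuple = ()

    def __post_init__(self):
        if self.sign not in SIGNS:
            raise ValueError(f"unknown sign {self.sign!r}")
        object.__setattr__(self, "covariate_set", tuple(self.covariate_set))
        for cov in self.covariate_set:
            if cov not in COVARIATES:
                raise ValueError(f"unknown covariate {cov!r}")

    @property
    def variant(self) -> str:
        """Human-readable variant label used in score tables."""
        if not self.covariate_set:
            return "no-covariate"
        if len(self.covariate_set) == 1:
            return f"single:{self.covariate_set[0]}"
        return "all-covariates"


@dataclass
class FitOptions:
    quad_order: int = 9
    ridge: float = 1e-4
    max_outer: int = 60
    inner_maxiter: int = 200
    tol: float = 1e-9
    compute_se: bool = False
    standardize: bool = True


@dataclass
class FittedSignModel:
    """Estimated parameters of one sign's model plus prediction state."""

    spec: ModelSpec
    beta: np.ndarray                       # 4 previous-score coefficients
    gamma: np.ndarray                      # per-covariate effects
    gamma_se: np.ndarray | None
    cutpoints: OrderedLogisticParams
    sigma_alpha: float
    alpha_hat: dict                        # patient -> empirical-Bayes mode
    covariate_stats: CovariateStats | None
    fit_meta: dict


def encode_previous_score(s_t: int) -> np.ndarray:
    """Indicator vector (length 4) for the previous score; score 4 -> zeros."""
    s = int(s_t)
    if not 0 <= s <= 4:
        raise ValueError(f"score must be in 0..4, got {s_t}")
    out = np.zeros(4)
    if s <= 3:
        out[s] = 1.0
    return out


def ordered_logistic_pmf(eta: float, params: OrderedLogisticParams) -> np.ndarray:
    """Category probabilities P(s = 0..4) at location ``eta``.

    P(s <= k) = logistic(c_{k+1} - eta); probabilities are adjacent CDF
    differences, floored at 1e-300 so downstream logs stay finite.
    """
    c = np.asarray(params.cutpoints)
    cdf = expit(c - eta)
    pmf = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    return np.clip(pmf, _PMF_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# vectorized internals: all heavy work happens on flat pair arrays
# ---------------------------------------------------------------------------


@dataclass
class _PairData:
    """Pairs flattened to arrays, rows sorted by patient (contiguous blocks)."""

    patients: list               # distinct patient ids, block order
    pat_idx: np.ndarray          # int code per pair
    row_starts: np.ndarray       # block start offsets for reduceat
    s_t: np.ndarray
    s_next: np.ndarray
    X: np.ndarray                # (n, p) covariates (already standardized)
    Z: np.ndarray = field(init=False)   # (n, 4+p) design for (beta, gamma)
    cl_idx: np.ndarray = field(init=False)
    cu_idx: np.ndarray = field(init=False)

    def __post_init__(self):
        n = len(self.s_t)
        ind = np.zeros((n, 4))
        low = self.s_t <= 3
        ind[np.flatnonzero(low), self.s_t[low]] = 1.0
        self.Z = np.hstack([ind, self.X]) if self.X.size else ind
        if self.X.size == 0 and self.X.shape[1:] == (0,):
            self.Z = ind
        # extended cutpoint indices: c_ext = [-inf, c1..c4, +inf]
        self.cl_idx = self.s_next          # lower bound index into c_ext
        self.cu_idx = self.s_next + 1

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


def _pairs_to_arrays(pairs: Sequence[TransitionPair]) -> _PairData:
    if not pairs:
        raise ValueError("no transition pairs supplied")
    order = sorted(range(len(pairs)), key=lambda i: (str(pairs[i].patient), pairs[i].day))
    patients, codes = [], {}
    pat_idx = np.empty(len(pairs), dtype=np.intp)
    for j, i in enumerate(order):
        p = pairs[i].patient
        if p not in codes:
            codes[p] = len(patients)
            patients.append(p)
        pat_idx[j] = codes[p]
    s_t = np.array([pairs[i].s_t for i in order], dtype=np.intp)
    s_next = np.array([pairs[i].s_next for i in order], dtype=np.intp)
    X = np.array([pairs[i].covariates for i in order], dtype=float)
    if X.ndim == 1:
        X = X.reshape(len(pairs), 0)
    row_starts = np.flatnonzero(np.r_[True, pat_idx[1:] != pat_idx[:-1]])
    return _PairData(patients, pat_idx, row_starts, s_t, s_next, X)


def _cut_ext(c: np.ndarray) -> np.ndarray:
    return np.concatenate(([-np.inf], c, [np.inf]))


def _logpmf_terms(eta, cext, cl_idx, cu_idx, want_d2=False):
    """log pmf and eta-derivatives at locations ``eta`` (any shape).

    Returns (logpmf, dlog, extras) where extras carries (pmf, fu, fl[, d2log]).
    fu/fl are logistic densities at the upper/lower cut minus eta.
    """
    au = cext[cu_idx] - eta
    al = cext[cl_idx] - eta
    Fu = np.where(np.isinf(au), 1.0, expit(au))
    Fl = np.where(np.isinf(al), 0.0, expit(al))
    pmf = np.clip(Fu - Fl, _PMF_FLOOR, 1.0)
    fu = np.where(np.isinf(au), 0.0, Fu * (1.0 - Fu))
    fl = np.where(np.isinf(al), 0.0, Fl * (1.0 - Fl))
    logpmf = np.log(pmf)
    dlog = (fl - fu) / pmf
    if not want_d2:
        return logpmf, dlog, (pmf, fu, fl)
    dfu = fu * (1.0 - 2.0 * Fu)          # d f(au)/d au
    dfl = fl * (1.0 - 2.0 * Fl)
    d2 = (dfu - dfl) / pmf - dlog * dlog
    return logpmf, dlog, (pmf, fu, fl, d2)


def _conditional_modes(data: _PairData, eta0, cext, sigma, alpha0=None, tol=1e-10, max_iter=60):
    """Per-patient mode and curvature of the alpha-conditional log-density.

    Newton iteration, vectorized across patients; the ordered-logistic
    log-pmf is concave in eta so the 1-D problems are well behaved.
    """
    K = data.n_patients
    alpha = np.zeros(K) if alpha0 is None else alpha0.copy()
    inv_var = 1.0 / (sigma * sigma)
    h = np.full(K, -inv_var)
    for _ in range(max_iter):
        eta = eta0 + alpha[data.pat_idx]
        _, dlog, extras = _logpmf_terms(eta, cext, data.cl_idx, data.cu_idx, want_d2=True)
        d2 = extras[3]
        g = np.bincount(data.pat_idx, weights=dlog, minlength=K) - alpha * inv_var
        h = np.bincount(data.pat_idx, weights=d2, minlength=K) - inv_var
        step = g / (-h)
        np.clip(step, -5.0, 5.0, out=step)
        alpha += step
        if np.max(np.abs(g)) < tol and np.max(np.abs(step)) < 1e-8:
            break
    return alpha, h


def _adaptive_nodes(alpha_mode, curvature, quad_order):
    """Node locations and constant log-weights for mode-centered quadrature."""
    z, w = hermgauss(quad_order)
    tau = 1.0 / np.sqrt(-curvature)
    A = alpha_mode[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
    logw_const = (np.log(w) + z * z)[None, :] + (0.5 * np.log(2.0) + np.log(tau))[:, None]
    return A, logw_const


def _patient_log_integrands(data: _PairData, eta0, cext, sigma, A):
    """(K, Q) matrix of per-node joint log-density sums."""
    eta = eta0[:, None] + A[data.pat_idx, :]
    logpmf, _, _ = _logpmf_terms(eta, cext, data.cl_idx[:, None], data.cu_idx[:, None])
    per_patient = np.add.reduceat(logpmf, data.row_starts, axis=0)
    prior = -0.5 * (A / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
    return per_patient + prior


def _adaptive_loglik(data: _PairData, eta0, cext, sigma, quad_order, alpha0=None):
    """Full adaptive-quadrature log marginal likelihood (and the modes)."""
    if sigma <= 0:
        logpmf, _, _ = _logpmf_terms(eta0, cext, data.cl_idx, data.cu_idx)
        return float(np.sum(logpmf)), np.zeros(data.n_patients)
    alpha, h = _conditional_modes(data, eta0, cext, sigma, alpha0)
    A, logw = _adaptive_nodes(alpha, h, quad_order)
    L = _patient_log_integrands(data, eta0, cext, sigma, A) + logw
    return float(np.sum(logsumexp(L, axis=1))), alpha


# -- parameter vector <-> natural parameters --------------------------------


def _unpack(theta, p):
    beta = theta[:4]
    gamma = theta[4:4 + p]
    c1 = theta[4 + p]
    u = theta[5 + p:8 + p]
    logsig = theta[8 + p]
    c = c1 + np.concatenate(([0.0], np.cumsum(np.exp(u))))
    return beta, gamma, c, u, np.exp(logsig)


def _frozen_objective(theta, data: _PairData, A, logw, ridge):
    """Penalized negative log-likelihood with frozen quadrature nodes, + grad."""
    p = data.n_covariates
    beta, gamma, c, u, sigma = _unpack(theta, p)
    coef = theta[:4 + p]
    cext = _cut_ext(c)
    eta0 = data.Z @ coef
    eta = eta0[:, None] + A[data.pat_idx, :]
    logpmf, dlog, (pmf, fu, fl) = _logpmf_terms(
        eta, cext, data.cl_idx[:, None], data.cu_idx[:, None]
    )
    per_patient = np.add.reduceat(logpmf, data.row_starts, axis=0)
    prior = -0.5 * (A / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
    L = per_patient + prior + logw
    ll_k = logsumexp(L, axis=1)
    ll = float(np.sum(ll_k))
    r = np.exp(L - ll_k[:, None])                     # (K, Q) posterior node weights
    W = r[data.pat_idx, :]                            # (n, Q) pair-level weights

    v = np.sum(W * dlog, axis=1)                      # d ll / d eta0 per pair
    grad_coef = data.Z.T @ v

    term_u = np.sum(W * (fu / pmf), axis=1)
    term_l = np.sum(W * (fl / pmf), axis=1)
    grad_c = np.zeros(4)
    up = data.s_next <= 3                             # finite upper cut c_{s+1}
    np.add.at(grad_c, data.s_next[up], term_u[up])
    lo = data.s_next >= 1                             # finite lower cut c_s
    np.subtract.at(grad_c, data.s_next[lo] - 1, term_l[lo])
    grad_c1 = grad_c.sum()
    grad_u = np.exp(u) * np.array([grad_c[m + 1:].sum() for m in range(3)])

    grad_logsig = float(np.sum(r * ((A / sigma) ** 2 - 1.0)))

    nll = -ll + ridge * float(coef @ coef)
    grad = np.concatenate([-grad_coef, [-grad_c1], -grad_u, [-grad_logsig]])
    grad[:4 + p] += 2.0 * ridge * coef
    return nll, grad


def _initial_theta(data: _PairData):
    p = data.n_covariates
    counts = np.bincount(data.s_next, minlength=5).astype(float)
    cum = np.clip(np.cumsum(counts)[:4] / counts.sum(), 1e-3, 1 - 1e-3)
    cum = np.maximum.accumulate(cum + 1e-6 * np.arange(4))
    c = np.log(cum / (1 - cum))
    d = np.maximum(np.diff(c), 1e-3)
    theta = np.zeros(9 + p)
    theta[4 + p] = c[0]
    theta[5 + p:8 + p] = np.log(d)
    theta[8 + p] = 0.0
    return theta


def _fit_arrays(data: _PairData, opts: FitOptions, theta0=None):
    """Inner-outer maximum marginal likelihood on flattened pair arrays."""
    p = data.n_covariates
    theta = _initial_theta(data) if theta0 is None else np.asarray(theta0, dtype=float).copy()
    bounds = (
        [(None, None)] * (4 + p)
        + [(None, None)]
        + [(-10.0, 5.0)] * 3
        + [(-6.0, 3.0)]
    )
    beta, gamma, c, u, sigma = _unpack(theta, p)
    cext = _cut_ext(c)
    eta0 = data.Z @ theta[:4 + p]
    alpha, h = _conditional_modes(data, eta0, cext, sigma, None)
    ll, _ = _adaptive_loglik(data, eta0, cext, sigma, opts.quad_order, alpha)
    trace = [ll]
    converged = False
    for outer in range(opts.max_outer):
        A, logw = _adaptive_nodes(alpha, h, opts.quad_order)
        res = minimize(
            _frozen_objective,
            theta,
            args=(data, A, logw, opts.ridge),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.inner_maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x
        beta, gamma, c, u, sigma = _unpack(theta, p)
        cext = _cut_ext(c)
        eta0 = data.Z @ theta[:4 + p]
        alpha, h = _conditional_modes(data, eta0, cext, sigma, alpha)
        ll_new, _ = _adaptive_loglik(data, eta0, cext, sigma, opts.quad_order, alpha)
        trace.append(ll_new)
        if abs(ll_new - ll) < opts.tol * (1.0 + abs(ll_new)):
            converged = True
            ll = ll_new
            break
        ll = ll_new
    return theta, alpha, ll, trace, converged


def _frozen_hessian(theta, data: _PairData, A, logw, ridge):
    """Central finite-difference Hessian of the frozen-node objective."""
    m = len(theta)
    H = np.zeros((m, m))
    for j in range(m):
        step = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        _, gp = _frozen_objective(tp, data, A, logw, ridge)
        _, gm = _frozen_objective(tm, data, A, logw, ridge)
        H[j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def log_marginal_likelihood(
    beta: Sequence[float],
    gamma: Sequence[float],
    cutpoints: OrderedLogisticParams,
    sigma_alpha: float,
    pairs_by_patient: Mapping[object, Sequence[TransitionPair]],
    quad_order: int = 9,
) -> float:
    """Log marginal likelihood of the mixed model at the given parameters.

    The patient random intercept is integrated out by adaptive Gauss-Hermite
    quadrature (``quad_order`` nodes) centered at each patient's conditional
    mode; deterministic and exact up to quadrature error.  ``sigma_alpha = 0``
    degenerates to the plain ordinal log-likelihood at alpha = 0.
    """
    if sigma_alpha < 0:
        raise ValueError("sigma_alpha must be >= 0")
    if quad_order < 1:
        raise ValueError("quad_order must be >= 1")
    pairs = [p for plist in pairs_by_patient.values() for p in plist]
    if any(len(plist) == 0 for plist in pairs_by_patient.values()):
        raise ValueError("every patient must contribute at least one pair")
    data = _pairs_to_arrays(pairs)
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    coef = np.concatenate([beta, gamma])
    eta0 = data.Z @ coef
    cext = _cut_ext(np.asarray(cutpoints.cutpoints))
    ll, _ = _adaptive_loglik(data, eta0, cext, float(sigma_alpha), quad_order)
    return ll


def fit_sign_model(
    pairs: Sequence[TransitionPair],
    spec: ModelSpec,
    opts: FitOptions | None = None,
    stats: CovariateStats | None = None,
) -> FittedSignModel:
    """Fit one sign's mixed autoregressive ordinal model to transition pairs.

    Continuous covariates are z-scored on the supplied pairs (or with
    pre-fitted ``stats``); the returned model carries the statistics so that
    prediction-time covariates are scaled identically.  Raises when the
    outcome has fewer than two observed categories.
    """
    opts = opts or FitOptions()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs to fit")
    if len(set(p.s_next for p in pairs)) < 2:
        raise ValueError("need at least 2 outcome categories to fit")
    if spec.covariate_set and opts.standardize:
        pairs, stats = standardize_covariates(pairs, spec.covariate_set, stats)
    data = _pairs_to_arrays(pairs)
    theta, alpha, ll, trace, converged = _fit_arrays(data, opts)
    p = data.n_covariates
    beta, gamma, c, u, sigma = _unpack(theta, p)

    gamma_se = None
    if opts.compute_se:
        cext = _cut_ext(c)
        eta0 = data.Z @ theta[:4 + p]
        mode, h = _conditional_modes(data, eta0, cext, sigma, alpha)
        A, logw = _adaptive_nodes(mode, h, opts.quad_order)
        H = _frozen_hessian(theta, data, A, logw, opts.ridge)
        cov = np.linalg.pinv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        gamma_se = se_all[4:4 + p]

    warnings = []
    if data.n_patients < 3:
        warnings.append("sigma_alpha weakly identified: fewer than 3 patients")
    if not converged:
        warnings.append("outer loop hit max iterations without meeting tolerance")
    meta = {
        "loglik": ll,
        "converged": converged,
        "quad_order": opts.quad_order,
        "ll_trace": trace,
        "n_pairs": len(pairs),
        "n_patients": data.n_patients,
        "warnings": warnings,
        "theta": theta.tolist(),
    }
    return FittedSignModel(
        spec=spec,
        beta=beta.copy(),
        gamma=gamma.copy(),
        gamma_se=gamma_se,
        cutpoints=OrderedLogisticParams(tuple(c)),
        sigma_alpha=float(sigma),
        alpha_hat={pat: float(a) for pat, a in zip(data.patients, alpha)},
        covariate_stats=stats,
        fit_meta=meta,
    )


def eb_alpha(model: FittedSignModel, patient_pairs: Sequence[TransitionPair]) -> float:
    """Empirical-Bayes random-intercept estimate for one patient.

    Mode of the conditional density of alpha given the patient's pairs under
    the fitted population parameters.  No pairs, or a degenerate prior
    (sigma_alpha = 0), give the prior mean 0.
    """
    patient_pairs = list(patient_pairs)
    if not patient_pairs or model.sigma_alpha <= 0:
        return 0.0
    if model.spec.covariate_set and model.covariate_stats is not None:
        patient_pairs, _ = standardize_covariates(
            patient_pairs, model.spec.covariate_set, model.covariate_stats
        )
    data = _pairs_to_arrays(patient_pairs)
    coef = np.concatenate([model.beta, model.gamma])
    eta0 = data.Z @ coef
    cext = _cut_ext(np.asarray(model.cutpoints.cutpoints))
    alpha, _ = _conditional_modes(data, eta0, cext, model.sigma_alpha)
    return float(alpha[0])


def predict_forecast(
    model: FittedSignModel,
    patient,
    s_t: int,
    covariates: Sequence[float] = (),
) -> np.ndarray:
    """One-step-ahead forecast pmf over scores 0..4 for one patient-day.

    ``covariates`` are raw values in the order of the model's covariate set;
    they are scaled with the training-window statistics stored in the model.
    An unknown patient gets the population forecast (alpha = 0).
    """
    x = np.asarray(covariates, dtype=float)
    if len(x) != len(model.spec.covariate_set):
        raise ValueError(
            f"expected {len(model.spec.covariate_set)} covariates, got {len(x)}"
        )
    if np.isnan(x).any():
        raise ValueError("missing covariate value in forecast input")
    if model.covariate_stats is not None and len(x):
        x = model.covariate_stats.transform(x)
    alpha = model.alpha_hat.get(patient, 0.0)
    eta = alpha + float(model.beta @ encode_previous_score(s_t))
    if len(x):
        eta += float(model.gamma @ x)
    return ordered_logistic_pmf(eta, model.cutpoints)


# -- serialization ----------------------------------------------------------


def save_model(model: FittedSignModel, path) -> None:
    """Write all fitted parameters to a flat JSON file (exact round-trip)."""
    payload = {
        "sign": model.spec.sign,
        "covariate_set": list(model.spec.covariate_set),
        "beta": model.beta.tolist(),
        "gamma": model.gamma.tolist(),
        "gamma_se": None if model.gamma_se is None else model.gamma_se.tolist(),
        "cutpoints": list(model.cutpoints.cutpoints),
        "sigma_alpha": model.sigma_alpha,
        "alpha_hat": [[str(k), v] for k, v in model.alpha_hat.items()],
        "alpha_keys_raw": list(model.alpha_hat.keys())
        if all(isinstance(k, (str, int)) for k in model.alpha_hat)
        else None,
        "covariate_stats": None
        if model.covariate_stats is None
        else {
            "names": list(model.covariate_stats.names),
            "mean": model.covariate_stats.mean.tolist(),
            "sd": model.covariate_stats.sd.tolist(),
        },
        "fit_meta": model.fit_meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> FittedSignModel:
    with open(path) as fh:
        payload = json.load(fh)
    keys = payload.get("alpha_keys_raw")
    values = [v for _, v in payload["alpha_hat"]]
    if keys is None:
        keys = [k for k, _ in payload["alpha_hat"]]
    stats = payload["covariate_stats"]
    return FittedSignModel(
        spec=ModelSpec(payload["sign"], tuple(payload["covariate_set"])),
        beta=np.array(payload["beta"]),
        gamma=np.array(payload["gamma"]),
        gamma_se=None if payload["gamma_se"] is None else np.array(payload["gamma_se"]),
        cutpoints=OrderedLogisticParams(tuple(payload["cutpoints"])),
        sigma_alpha=payload["sigma_alpha"],
        alpha_hat=dict(zip(keys, values)),
        covariate_stats=None
        if stats is None
        else CovariateStats(tuple(stats["names"]), np.array(stats["mean"]), np.array(stats["sd"])),
        fit_meta=payload["fit_meta"],
    )
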