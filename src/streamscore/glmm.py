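"""Logistic random-intercept models of hit/miss outcomes.

The marginal likelihood integrates a normal subject intercept by
fixed-order adaptive Gauss-Hermite quadrature (nodes recentred at each
subject's posterior mode, so accuracy does not degrade as the number of
observations per subject grows) and is maximised by quasi-Newton
iteration (L-BFGS-B); standard errors come from the observed information
matrix (central-difference Hessian).  A likelihood-ratio ladder adds
fixed effects of delta-f, deviant position and percept in turn, then
their two-way interactions, then per-term random slopes, retaining each
addition only when the chi-squared test on twice the log-likelihood gain
is significant.  The adjusted count pseudo-R2 quantises fitted
probabilities at 0.5 and measures correct predictions beyond the
majority-class count.

Covariate coding: delta-f as an indicator for 8 vs 4 semitones, position
as ordered numeric early/middle/late -> 0/1/2, percept as an indicator
for integrated reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

log = logging.getLogger(__name__)

DEFAULT_QUAD_ORDER = 20
POSITION_CODE = {"early": 0, "middle": 1, "late": 2}


class GlmmError(ValueError):
    pass


@dataclass
class GlmmFit:
    fixed_names: list
    fixed_coefs: np.ndarray
    fixed_se: np.ndarray
    sigma_subj: float
    sigma_slope: float | None
    slope_term: str | None
    loglik: float
    n_obs: int
    converged: bool
    fitted_prob: np.ndarray = field(default=None, repr=False)

    @property
    def z_scores(self) -> np.ndarray:
        return self.fixed_coefs / self.fixed_se

    def coef(self, name: str) -> float:
        return float(self.fixed_coefs[self.fixed_names.index(name)])


def _design(table: pd.DataFrame, terms: list) -> tuple[np.ndarray, list]:
    """Design matrix (with intercept) for the named terms."""
    cols = [np.ones(len(table))]
    names = ["intercept"]
    base = {
        "delta_f": (table.delta_f == 8).astype(float).to_numpy(),
        "position": table.position.map(POSITION_CODE).astype(float).to_numpy(),
        "percept": (table.percept == "one_stream").astype(float).to_numpy(),
    }
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(base[a] * base[b])
        else:
            cols.append(base[term])
        names.append(term)
    return np.column_stack(cols), names


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _posterior_modes_1d(y, eta0, s0, subj_idx, bounds, n_iter=30):
    """Per-subject mode and curvature of the integrand (intercept only).

    Newton iterations on log p(y | b) + log phi(b); the objective is
    strictly concave so convergence is fast and global.
    """
    n_subj = len(bounds)
    mu = np.zeros(n_subj)
    h = np.full(n_subj, -1.0)
    for _ in range(n_iter):
        pi = _expit(eta0 + s0 * mu[subj_idx])
        g = s0 * np.add.reduceat(y - pi, bounds) - mu
        h = -(s0 * s0 * np.add.reduceat(pi * (1 - pi), bounds) + 1.0)
        step = g / -h
        mu = mu + step
        if np.max(np.abs(step)) < 1e-10:
            break
    pi = _expit(eta0 + s0 * mu[subj_idx])
    h = -(s0 * s0 * np.add.reduceat(pi * (1 - pi), bounds) + 1.0)
    return mu, 1.0 / np.sqrt(-h)


def _adaptive_quad_1d(params, y, sign, X, subj_idx, bounds, gx, glw):
    """Adaptive Gauss-Hermite marginal log likelihood, intercept only.

    Nodes are recentred at each subject's posterior mode and rescaled by
    the local curvature, so a fixed modest order is accurate however many
    observations a subject contributes.  Returns (total loglik, per-node
    log posterior weights, node positions) for reuse by the fitted-
    probability step.
    """
    k = X.shape[1]
    beta, s0 = params[:k], abs(params[k])
    eta0 = X @ beta
    mu, tau = _posterior_modes_1d(y, eta0, s0, subj_idx, bounds)
    b = mu[:, None] + math.sqrt(2.0) * tau[:, None] * gx[None, :]   # (J, M)
    eta = eta0[:, None] + s0 * b[subj_idx]
    ll_obs = -np.logaddexp(0.0, -sign[:, None] * eta)
    ell = np.add.reduceat(ll_obs, bounds, axis=0)                   # (J, M)
    F = ell - 0.5 * b * b - _LOG_SQRT_2PI
    m = glw[None, :] + gx[None, :] ** 2 + F
    mmax = m.max(axis=1, keepdims=True)
    lse = mmax[:, 0] + np.log(np.sum(np.exp(m - mmax), axis=1))
    logL = 0.5 * math.log(2.0) + np.log(tau) + lse
    return float(np.sum(logL)), m, b


def _posterior_modes_2d(y, eta0, s0, s1, Z, subj_idx, bounds, n_iter=30):
    """Joint mode and inverse-curvature Cholesky for intercept + slope."""
    n_subj = len(bounds)
    mu = np.zeros((n_subj, 2))
    for _ in range(n_iter):
        eta = eta0 + s0 * mu[subj_idx, 0] + s1 * Z * mu[subj_idx, 1]
        pi = _expit(eta)
        r = y - pi
        v = pi * (1 - pi)
        g0 = s0 * np.add.reduceat(r, bounds) - mu[:, 0]
        g1 = s1 * np.add.reduceat(Z * r, bounds) - mu[:, 1]
        h00 = s0 * s0 * np.add.reduceat(v, bounds) + 1.0
        h01 = s0 * s1 * np.add.reduceat(Z * v, bounds)
        h11 = s1 * s1 * np.add.reduceat(Z * Z * v, bounds) + 1.0
        det = h00 * h11 - h01 * h01
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        mu[:, 0] += d0
        mu[:, 1] += d1
        if max(np.max(np.abs(d0)), np.max(np.abs(d1))) < 1e-10:
            break
    # Cholesky of the inverse negative Hessian, per subject
    eta = eta0 + s0 * mu[subj_idx, 0] + s1 * Z * mu[subj_idx, 1]
    v = _expit(eta) * (1 - _expit(eta))
    h00 = s0 * s0 * np.add.reduceat(v, bounds) + 1.0
    h01 = s0 * s1 * np.add.reduceat(Z * v, bounds)
    h11 = s1 * s1 * np.add.reduceat(Z * Z * v, bounds) + 1.0
    det = h00 * h11 - h01 * h01
    i00, i01, i11 = h11 / det, -h01 / det, h00 / det
    a00 = np.sqrt(i00)
    a10 = i01 / a00
    a11 = np.sqrt(np.maximum(i11 - a10 * a10, 1e-300))
    return mu, (a00, a10, a11)


def _adaptive_quad_2d(params, y, sign, X, Z, subj_idx, bounds, gx, glw):
    """Adaptive tensor-product quadrature for intercept + independent slope."""
    k = X.shape[1]
    beta, s0, s1 = params[:k], abs(params[k]), abs(params[k + 1])
    eta0 = X @ beta
    mu, (a00, a10, a11) = _posterior_modes_2d(y, eta0, s0, s1, Z,
                                              subj_idx, bounds)
    x0, x1 = np.meshgrid(gx, gx, indexing="ij")
    x0, x1 = x0.ravel(), x1.ravel()
    lw = (glw[:, None] + glw[None, :]).ravel()
    rt2 = math.sqrt(2.0)
    b0 = mu[:, 0][:, None] + rt2 * (a00[:, None] * x0[None, :])
    b1 = mu[:, 1][:, None] + rt2 * (a10[:, None] * x0[None, :]
                                    + a11[:, None] * x1[None, :])
    eta = eta0[:, None] + s0 * b0[subj_idx] + s1 * Z[:, None] * b1[subj_idx]
    ll_obs = -np.logaddexp(0.0, -sign[:, None] * eta)
    ell = np.add.reduceat(ll_obs, bounds, axis=0)
    F = ell - 0.5 * (b0 * b0 + b1 * b1) - 2.0 * _LOG_SQRT_2PI
    m = lw[None, :] + (x0 * x0 + x1 * x1)[None, :] + F
    mmax = m.max(axis=1, keepdims=True)
    lse = mmax[:, 0] + np.log(np.sum(np.exp(m - mmax), axis=1))
    logL = math.log(2.0) + np.log(a00 * a11) + lse
    return float(np.sum(logL)), m, (b0, b1)


def _marginal_nll(params, y, sign, X, subj_idx, bounds, gx, glw, Z=None):
    """Negative marginal log likelihood (adaptive Gauss-Hermite)."""
    if Z is None:
        ll, _, _ = _adaptive_quad_1d(params, y, sign, X, subj_idx, bounds,
                                     gx, glw)
    else:
        ll, _, _ = _adaptive_quad_2d(params, y, sign, X, Z, subj_idx,
                                     bounds, gx, glw)
    return -ll


def _gh(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw Gauss-Hermite nodes and log weights."""
    x, w = np.polynomial.hermite.hermgauss(order)
    return x, np.log(w)


def _hessian(f, x, eps=1e-4):
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_logistic_random_intercept(
    table: pd.DataFrame,
    terms: list | None = None,
    quad_order: int = DEFAULT_QUAD_ORDER,
    slope_term: str | None = None,
    compute_se: bool = True,
    start: np.ndarray | None = None,
) -> GlmmFit:
    """Fit hit ~ terms + (1 | subject) [+ (0 + slope_term | subject)].

    ``table`` needs columns subject, hit (0/1) and the covariates used by
    the requested terms.  Separation (a fitted probability pinned at 0 or
    1 for an entire class) is flagged as non-convergence.
    """
    if quad_order < 5:
        raise GlmmError("quadrature order must be at least 5")
    terms = list(terms or [])
    subjects = pd.Categorical(table.subject)
    order = np.argsort(subjects.codes, kind="stable")
    table_s = table.iloc[order]
    y = table_s.hit.to_numpy().astype(float)
    subj_idx = subjects.codes[order].astype(int)
    n_subj = len(subjects.categories)
    if n_subj < 2:
        raise GlmmError("at least 2 subjects required")
    if len(np.unique(y)) < 2:
        raise GlmmError("all outcomes identical: complete separation")
    bounds = np.flatnonzero(np.r_[1, np.diff(subj_idx)])
    sign = np.where(y == 1, 1.0, -1.0)
    X, names = _design(table_s, terms)
    Z = None
    if slope_term is not None:
        Zfull, _ = _design(table_s, [slope_term])
        Z = Zfull[:, 1]
    gx, glw = _gh(quad_order)
    k = X.shape[1]
    n_par = k + 1 + (1 if Z is not None else 0)
    if start is not None and len(start) == n_par:
        x0 = np.asarray(start, dtype=float).copy()
    else:
        x0 = np.zeros(n_par)
        x0[0] = math.log(max(y.mean(), 1e-3) / max(1 - y.mean(), 1e-3))
        x0[k] = 0.5
    nll = lambda p: _marginal_nll(p, y, sign, X, subj_idx, bounds, gx, glw, Z)
    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-10})
    params = res.x
    sigma0 = abs(params[k])
    converged = bool(res.success)
    separation = bool(np.max(np.abs(params[:k])) > 15)
    if separation:
        log.warning("possible complete separation: |coef| > 15 logits")
        converged = False
    if compute_se:
        H = _hessian(nll, params)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov)[:k], 0.0))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
            converged = False
    else:
        se = np.full(k, np.nan)
    fit = GlmmFit(
        fixed_names=names,
        fixed_coefs=params[:k],
        fixed_se=se,
        sigma_subj=float(sigma0),
        sigma_slope=float(abs(params[k + 1])) if Z is not None else None,
        slope_term=slope_term,
        loglik=-float(res.fun),
        n_obs=len(table),
        converged=converged,
    )
    prob_sorted = _fitted_probabilities(params, y, sign, X, subj_idx,
                                        bounds, gx, glw, Z)
    fitted = np.empty_like(prob_sorted)
    fitted[order] = prob_sorted
    fit.fitted_prob = fitted
    return fit


def _fitted_probabilities(params, y, sign, X, subj_idx, bounds, gx, glw, Z):
    """Conditional fitted probabilities at the empirical-Bayes posterior
    mean of each subject's random effects."""
    k = X.shape[1]
    beta, s0 = params[:k], abs(params[k])
    eta0 = X @ beta
    if Z is None:
        _, m, b = _adaptive_quad_1d(params, y, sign, X, subj_idx, bounds,
                                    gx, glw)
        w = np.exp(m - m.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        b0_hat = np.sum(w * b, axis=1)
        eta_hat = eta0 + s0 * b0_hat[subj_idx]
    else:
        s1 = abs(params[k + 1])
        _, m, (b0, b1) = _adaptive_quad_2d(params, y, sign, X, Z,
                                           subj_idx, bounds, gx, glw)
        w = np.exp(m - m.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        b0_hat = np.sum(w * b0, axis=1)
        b1_hat = np.sum(w * b1, axis=1)
        eta_hat = (eta0 + s0 * b0_hat[subj_idx]
                   + s1 * Z * b1_hat[subj_idx])
    return 1.0 / (1.0 + np.exp(-eta_hat))


def adjusted_count_pseudo_r2(fitted_prob, outcomes) -> float:
    """(n_correct - n_majority) / (n - n_majority), predictions quantised
    at 0.5 with ties counted as the 0 class."""
    p = np.asarray(fitted_prob, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if np.any((p < 0) | (p > 1)):
        raise GlmmError("probabilities must lie in [0, 1]")
    n = y.size
    n_major = int(max(np.sum(y == 1), np.sum(y == 0)))
    if n_major == n:
        raise GlmmError("all outcomes identical: pseudo-R2 undefined")
    pred = (p > 0.5).astype(int)
    n_correct = int(np.sum(pred == y))
    return (n_correct - n_major) / (n - n_major)


@dataclass
class ModelComparison:
    ladder: list          # dicts: terms, added, df, loglik, chi2, p, accepted, pseudo_r2
    winning_terms: list
    winning_fit: GlmmFit


def lr_ladder(
    table: pd.DataFrame,
    candidate_terms: list | None = None,
    test_interactions: bool = True,
    test_random_slopes: bool = True,
    alpha: float = 0.05,
    quad_order: int = DEFAULT_QUAD_ORDER,
    slope_quad_order: int = 9,
) -> ModelComparison:
    """Forward likelihood-ratio ladder over fixed effects, interactions
    and random slopes, starting from the subject-only baseline."""
    candidates = list(candidate_terms or ["delta_f", "position", "percept"])
    if len(set(candidates)) != len(candidates):
        raise GlmmError("duplicate candidate terms would add zero degrees of freedom")
    current_terms: list = []
    base = fit_logistic_random_intercept(table, current_terms, quad_order)
    steps = [{
        "added": "subject (random)", "terms": [], "df": None,
        "loglik": base.loglik, "chi2": None, "p": None, "accepted": True,
        "z": None,
        "pseudo_r2": adjusted_count_pseudo_r2(base.fitted_prob, table.hit),
    }]
    current = base

    def try_add(added_label, new_terms, slope=None, quad=quad_order):
        nonlocal current, current_terms
        if slope is None:
            start = np.r_[current.fixed_coefs, 0.0, current.sigma_subj]
        else:
            start = np.r_[current.fixed_coefs, current.sigma_subj, 0.3]
        try:
            fit = fit_logistic_random_intercept(table, new_terms, quad,
                                                slope_term=slope,
                                                compute_se=(slope is None),
                                                start=start)
        except GlmmError as exc:
            log.warning("candidate %s failed: %s", added_label, exc)
            return
        if not fit.converged:
            log.warning("candidate %s did not converge; skipped", added_label)
            return
        lr = 2.0 * (fit.loglik - current.loglik)
        p = float(chi2.sf(max(lr, 0.0), 1))
        accepted = p < alpha and lr > 0
        z = None
        if slope is None and added_label in fit.fixed_names:
            z = float(fit.z_scores[fit.fixed_names.index(added_label)])
        steps.append({
            "added": added_label, "terms": list(new_terms), "df": 1,
            "loglik": fit.loglik, "chi2": float(max(lr, 0.0)), "p": p,
            "accepted": accepted, "z": z,
            "pseudo_r2": adjusted_count_pseudo_r2(fit.fitted_prob, table.hit),
        })
        if accepted:
            current = fit
            current_terms = list(new_terms)

    for term in candidates:
        try_add(term, current_terms + [term])
    if test_interactions:
        fixed = [t for t in current_terms if ":" not in t]
        for i, a in enumerate(fixed):
            for b in fixed[i + 1:]:
                try_add(f"{a}:{b}", current_terms + [f"{a}:{b}"])
    if test_random_slopes:
        for term in [t for t in current_terms if ":" not in t]:
            try_add(f"({term} | subject)", current_terms, slope=term,
                    quad=slope_quad_order)
    return ModelComparison(steps, current_terms, current)


def percept_entry_order_invariant(
    table: pd.DataFrame, alpha: float = 0.05, quad_order: int = DEFAULT_QUAD_ORDER
) -> bool:
    """Is the percept-inclusion decision the same whichever order the
    fixed effects enter?"""
    orders = [
        ["delta_f", "position", "percept"],
        ["percept", "delta_f", "position"],
        ["position", "percept", "delta_f"],
    ]
    decisions = []
    for order in orders:
        comp = lr_ladder(table, order, test_interactions=False,
                         test_random_slopes=False, alpha=alpha,
                         quad_order=quad_order)
        decisions.append("percept" in comp.winning_terms)
    return len(set(decisions)) == 1


def criterion_contrast(percept_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-subject criterion difference (segregated minus integrated).

    ``percept_scores`` is the percept-conditioned aggregate table with
    columns subject, percept, criterion.  Subjects missing either percept
    cell are excluded with a warning.
    """
    rows = []
    for subj, grp in percept_scores.groupby("subject"):
        cells = grp.set_index("percept").criterion
        if "one_stream" not in cells.index or "two_streams" not in cells.index:
            log.warning("subject %s missing a percept cell; excluded", subj)
            continue
        rows.append({
            "subject": subj,
            "criterion_integrated": float(cells["one_stream"]),
            "criterion_segregated": float(cells["two_streams"]),
            "difference": float(cells["two_streams"] - cells["one_stream"]),
        })
    return pd.DataFrame(rows,
                        columns=["subject", "criterion_integrated",
                                 "criterion_segregated", "difference"])
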