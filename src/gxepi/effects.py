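"""Effect estimation: logistic ML, nested random-intercept logistic (Laplace),
and crude/model-based odds ratios.

The analysis model is a logistic regression for case status with Gaussian
random intercepts on three nested grouping levels -- matched stratum within
hospital within recruitment period -- mirroring a four-level design
(subject, stratum, hospital, period).  The marginal likelihood over the
random intercepts is approximated by the Laplace method: for given
random-effect standard deviations the fixed effects and the random-effect
modes are found by penalized Newton iterations, and the log marginal
likelihood is the penalized log-likelihood at the mode minus half the
log-determinant of the curvature; the SDs are then optimized by a bounded
quasi-Newton search with the boundary (SD = 0) allowed.  This is the same
approximation lme4's glmer uses at its default accuracy setting.

Plain logistic regression is the fixed-effects limit (all SDs pinned at 0)
and is exposed separately; crude 2x2 odds ratios with Woolf confidence
intervals serve the descriptive table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit
from scipy.stats import norm

from .core_data import ValidationError

__all__ = [
    "CollinearityError",
    "NestingError",
    "FittedModel",
    "ORResult",
    "fit_logistic",
    "fit_nested_glmm",
    "crude_or",
    "or_from_model",
]


class CollinearityError(Exception):
    """The fixed-effect design is rank deficient; names the collinear terms."""


class NestingError(ValidationError):
    """Grouping labels are inconsistent with stratum < hospital < period nesting."""


@dataclass
class FittedModel:
    term_names: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    bic: float
    variance_components: dict[str, float]
    n_used: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.beta[self._idx(term)])

    def se(self, term: str) -> float:
        i = self._idx(term)
        return float(math.sqrt(max(self.vcov[i, i], 0.0)))

    def _idx(self, term: str) -> int:
        try:
            return self.term_names.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in model ({self.term_names})") from None

    def vcov_submatrix(self, terms: Sequence[str]) -> np.ndarray:
        idx = [self._idx(t) for t in terms]
        return self.vcov[np.ix_(idx, idx)]


@dataclass(frozen=True)
class ORResult:
    term: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    notes: tuple[str, ...] = ()


def _check_rank(X: np.ndarray, term_names: Sequence[str]) -> None:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        culprits = [term_names[i] for i in sorted(piv[rank:])]
        raise CollinearityError(f"design is rank deficient; collinear terms: {culprits}")


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    y: Sequence[float] | np.ndarray,
    X: np.ndarray,
    term_names: Sequence[str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
) -> FittedModel:
    """Maximum-likelihood logistic regression by Newton iterations.

    Convergence when the score's max-norm falls below ``score_tol`` or the
    relative log-likelihood change falls below 1e-10.  Quasi- or complete
    separation is reported through ``converged=False`` (with a note), never
    raised; the coefficient estimates at the stopping point are returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{i}" for i in range(p)]
    term_names = list(term_names)
    if n <= p:
        raise ValidationError(f"need more observations ({n}) than terms ({p})")
    _check_rank(X, term_names)

    beta = np.zeros(p)
    ll = _loglik(y, X @ beta)
    converged = False
    notes: list[str] = []
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.abs(score).max() < score_tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = X.T @ (w[:, None] * X)
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, score, rcond=None)[0]
        step = 1.0
        for _ in range(40):
            ll_new = _loglik(y, X @ (beta + step * delta))
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        if abs(ll_new - ll) <= 1e-10 * (abs(ll) + 1e-10):
            ll = ll_new
            converged = np.abs(X.T @ (y - expit(X @ beta))).max() < 1e-4
            break
        ll = ll_new
    eta = X @ beta
    ll = _loglik(y, eta)
    if not converged or np.abs(beta).max() > 30.0:
        if np.abs(beta).max() > 30.0:
            converged = False
        if not converged:
            notes.append("possible separation: diverging coefficients or unmet score tolerance")
    w = np.clip(expit(eta) * (1.0 - expit(eta)), 1e-12, None)
    H = X.T @ (w[:, None] * X)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
    bic = -2.0 * ll + p * math.log(n)
    return FittedModel(term_names, beta, vcov, ll, bic, {}, n, bool(converged), notes)


# --------------------------------------------------------------------------
# nested random-intercept logistic model (Laplace approximation)
# --------------------------------------------------------------------------

_SD_FLOOR = 1e-5  # below this a level is treated as variance zero


def _codes(labels) -> tuple[np.ndarray, int]:
    arr = np.asarray(labels)
    _, codes = np.unique(arr, return_inverse=True)
    return codes.astype(np.int64), int(codes.max()) + 1 if arr.size else 0


def _validate_nesting(stratum, hospital, period) -> None:
    import pandas as pd

    df = pd.DataFrame({"s": stratum})
    for name, lab in (("h", hospital), ("p", period)):
        if lab is not None:
            df[name] = lab
    for child, parent in (("s", "h"), ("s", "p"), ("h", "p")):
        if child in df and parent in df:
            if df.groupby(child, sort=False)[parent].nunique().max() > 1:
                raise NestingError(
                    f"labels not nested: a {child!r}-level group spans multiple "
                    f"{parent!r}-level groups"
                )


def fit_nested_glmm(
    y: Sequence[float] | np.ndarray,
    X: np.ndarray,
    term_names: Sequence[str] | None = None,
    *,
    stratum,
    hospital=None,
    period=None,
    start_sd: float = 0.1,
    sd_bound: float = 5.0,
) -> FittedModel:
    """Logistic regression with nested Gaussian random intercepts, Laplace ML.

    Random intercepts are independent within each provided level (stratum,
    hospital, period); levels left as None are omitted.  Variance components
    are optimized on the SD scale with the boundary at zero allowed, starting
    from ``start_sd``; the fit is deterministic given the data.  Fixed-effect
    covariance comes from the curvature of the Laplace objective (the Schur
    complement of the random-effect block).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{i}" for i in range(p)]
    term_names = list(term_names)
    _check_rank(X, term_names)
    _validate_nesting(stratum, hospital, period)

    level_names: list[str] = ["stratum"]
    label_sets = [stratum]
    if hospital is not None:
        level_names.append("hospital")
        label_sets.append(hospital)
    if period is not None:
        level_names.append("period")
        label_sets.append(period)
    n_levels = len(level_names)

    blocks = []
    level_of_col: list[int] = []
    for li, labels in enumerate(label_sets):
        codes, q_l = _codes(labels)
        Zl = sp.csr_matrix(
            (np.ones(n), (np.arange(n), codes)), shape=(n, q_l)
        )
        blocks.append(Zl)
        level_of_col.extend([li] * q_l)
    Z = sp.hstack(blocks, format="csr")
    level_of_col = np.asarray(level_of_col)
    q_total = Z.shape[1]

    state: dict[str, np.ndarray] = {"beta": np.zeros(p), "u": np.zeros(q_total)}

    def inner_fit(sds: np.ndarray):
        """Penalized Newton over (beta, active u) at fixed SDs."""
        active = sds[level_of_col] >= _SD_FLOOR
        Za = Z[:, active]
        prec = 1.0 / np.square(sds[level_of_col[active]])
        q = Za.shape[1]
        beta = state["beta"].copy()
        u = state["u"][active].copy()

        def pen_ll(beta_, u_):
            eta_ = X @ beta_ + Za @ u_
            return _loglik(y, eta_) - 0.5 * float(prec @ np.square(u_)), eta_

        ll_pen, eta = pen_ll(beta, u)
        ok = False
        for _ in range(60):
            mu = expit(eta)
            resid = y - mu
            grad = np.concatenate([X.T @ resid, Za.T @ resid - prec * u])
            if np.abs(grad).max() < 1e-9 * max(1.0, n / 1000.0):
                ok = True
                break
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            XtWX = X.T @ (w[:, None] * X)
            if q == 0:
                delta = np.linalg.solve(XtWX, grad)
            else:
                ZtWX = np.asarray((Za.multiply(w[:, None])).T @ X)  # (q, p)
                ZtWZ = (Za.multiply(w[:, None])).T @ Za
                H = sp.bmat(
                    [[sp.csc_matrix(XtWX), sp.csc_matrix(ZtWX.T)],
                     [sp.csc_matrix(ZtWX), ZtWZ + sp.diags(prec)]],
                    format="csc",
                )
                delta = splu(H).solve(grad)
            step = 1.0
            for _ in range(40):
                cand_beta = beta + step * delta[:p]
                cand_u = u + step * delta[p:]
                ll_new, eta_new = pen_ll(cand_beta, cand_u)
                if ll_new >= ll_pen - 1e-12:
                    break
                step *= 0.5
            beta, u, ll_pen, eta = cand_beta, cand_u, ll_new, eta_new
        state["beta"] = beta
        full_u = np.zeros(q_total)
        full_u[active] = u
        state["u"] = full_u
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        return beta, u, eta, w, ll_pen, active, Za, prec, ok

    def marginal_negloglik(sds: np.ndarray) -> float:
        beta, u, eta, w, ll_pen, active, Za, prec, _ = inner_fit(sds)
        if Za.shape[1] == 0:
            return -_loglik(y, eta)
        C = ((Za.multiply(w[:, None])).T @ Za + sp.diags(prec)).tocsc()
        lu = splu(C)
        logdet_c = float(np.log(np.abs(lu.U.diagonal())).sum())
        logdet_d = float(-np.log(prec).sum())  # log det of the prior covariance
        ll_m = ll_pen - 0.5 * logdet_c - 0.5 * logdet_d
        return -ll_m

    x0 = np.full(n_levels, float(start_sd))
    res = minimize(
        marginal_negloglik,
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, sd_bound)] * n_levels,
        options={"eps": 1e-5, "ftol": 1e-11, "gtol": 1e-7, "maxiter": 300},
    )
    sds0 = np.clip(res.x, 0.0, sd_bound)

    # Stage 2: move the fixed effects into the outer Laplace objective with
    # only the random effects profiled.  Profiling beta through the penalized
    # likelihood alone (stage 1) ignores the dependence of the curvature term
    # on beta; this refinement matches glmer's default Laplace objective and
    # starts at the stage-1 solution, so it is cheap.
    def inner_fit_u(sds: np.ndarray, beta: np.ndarray):
        active = sds[level_of_col] >= _SD_FLOOR
        Za = Z[:, active]
        prec = 1.0 / np.square(sds[level_of_col[active]])
        u = state["u"][active].copy()
        offset = X @ beta

        def pen_ll(u_):
            eta_ = offset + Za @ u_
            return _loglik(y, eta_) - 0.5 * float(prec @ np.square(u_)), eta_

        ll_pen, eta = pen_ll(u)
        ok = Za.shape[1] == 0
        for _ in range(60):
            if Za.shape[1] == 0:
                break
            mu = expit(eta)
            grad = Za.T @ (y - mu) - prec * u
            if np.abs(grad).max() < 1e-9 * max(1.0, n / 1000.0):
                ok = True
                break
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            C = ((Za.multiply(w[:, None])).T @ Za + sp.diags(prec)).tocsc()
            delta = splu(C).solve(grad)
            step = 1.0
            for _ in range(40):
                cand = u + step * delta
                ll_new, eta_new = pen_ll(cand)
                if ll_new >= ll_pen - 1e-12:
                    break
                step *= 0.5
            u, ll_pen, eta = cand, ll_new, eta_new
        full_u = np.zeros(q_total)
        full_u[active] = u
        state["u"] = full_u
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        return u, eta, w, ll_pen, active, Za, prec, ok

    def joint_negloglik(params: np.ndarray) -> float:
        sds_, beta_ = params[:n_levels], params[n_levels:]
        u_, eta_, w_, ll_pen_, _, Za_, prec_, _ = inner_fit_u(sds_, beta_)
        if Za_.shape[1] == 0:
            return -_loglik(y, eta_)
        C = ((Za_.multiply(w_[:, None])).T @ Za_ + sp.diags(prec_)).tocsc()
        logdet_c = float(np.log(np.abs(splu(C).U.diagonal())).sum())
        return -(ll_pen_ - 0.5 * logdet_c + 0.5 * float(np.log(prec_).sum()))

    x1 = np.concatenate([sds0, state["beta"]])
    res2 = minimize(
        joint_negloglik,
        x1,
        method="L-BFGS-B",
        bounds=[(0.0, sd_bound)] * n_levels + [(None, None)] * p,
        options={"eps": 1e-5, "ftol": 1e-12, "gtol": 1e-6, "maxiter": 500},
    )
    sds = np.clip(res2.x[:n_levels], 0.0, sd_bound)
    sds[sds < _SD_FLOOR] = 0.0
    beta = res2.x[n_levels:].copy()
    state["beta"] = beta

    u, eta, w, ll_pen, active, Za, prec, inner_ok = inner_fit_u(np.maximum(sds, 0.0), beta)
    XtWX = X.T @ (w[:, None] * X)
    notes: list[str] = []
    if Za.shape[1] > 0:
        C = ((Za.multiply(w[:, None])).T @ Za + sp.diags(prec)).tocsc()
        lu = splu(C)
        logdet_c = float(np.log(np.abs(lu.U.diagonal())).sum())
        ll_m = ll_pen - 0.5 * logdet_c + 0.5 * float(np.log(prec).sum())
        ZtWX = np.asarray((Za.multiply(w[:, None])).T @ X)
        schur = XtWX - ZtWX.T @ lu.solve(ZtWX)
    else:
        ll_m = _loglik(y, eta)
        schur = XtWX
    try:
        vcov = np.linalg.inv(schur)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(schur)

    converged = bool(res2.success and inner_ok)
    if not converged:
        notes.append(f"optimizer status: {res2.message}")
    if (sds == 0.0).any():
        boundary = [level_names[i] for i in range(n_levels) if sds[i] == 0.0]
        notes.append(f"variance component at boundary zero: {boundary}")

    k = p + n_levels
    bic = -2.0 * ll_m + k * math.log(n)
    return FittedModel(
        term_names=term_names,
        beta=beta,
        vcov=vcov,
        loglik=float(ll_m),
        bic=float(bic),
        variance_components={level_names[i]: float(sds[i]) for i in range(n_levels)},
        n_used=n,
        converged=converged,
        notes=notes,
    )


# --------------------------------------------------------------------------
# odds ratios
# --------------------------------------------------------------------------

def crude_or(
    a: int, b: int, c: int, d: int, ci_level: float = 0.95
) -> ORResult:
    """Crude odds ratio for a 2x2 table with a Woolf (log-scale) CI.

    Layout: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls; OR = ad / (bc).  A 0.5 continuity correction is
    applied iff any cell is zero (recorded in the notes).  Tables with two
    zero cells in the same margin are flagged undefined.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValidationError("2x2 cell counts must be non-negative")
    notes: list[str] = []
    if (a == 0 and b == 0) or (c == 0 and d == 0) or \
       (a == 0 and c == 0) or (b == 0 and d == 0):
        return ORResult("exposure", float("nan"), float("nan"), float("nan"),
                        float("nan"), ("undefined: empty table margin",))
    if (cells == 0).any():
        cells = cells + 0.5
        notes.append("0.5 continuity correction applied (zero cell)")
    a_, b_, c_, d_ = cells
    log_or = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = norm.ppf(0.5 + ci_level / 2.0)
    p = 2.0 * norm.sf(abs(log_or) / se)
    return ORResult(
        term="exposure",
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
        notes=tuple(notes),
    )


def or_from_model(model: FittedModel, term: str, ci_level: float = 0.95) -> ORResult:
    """Wald odds ratio for one model term: exp(beta +/- z * SE)."""
    beta = model.coef(term)
    se = model.se(term)
    z = norm.ppf(0.5 + ci_level / 2.0)
    p = 2.0 * norm.sf(abs(beta) / se) if se > 0 else (0.0 if beta != 0 else 1.0)
    # np.exp saturates to inf/0 instead of raising on extreme Wald bounds
    with np.errstate(over="ignore"):
        return ORResult(
            term=term,
            or_point=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            p_value=float(p),
        )
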