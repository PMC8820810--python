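"""Additive-scale interaction measures from the four-group odds ratios.

With the doubly-unexposed group as reference, write OR10 for the exposed /
wild-type group (G1), OR11 for the exposed / carrier group (G2) and OR01 for
the unexposed / carrier group (G3).  Departure from additivity of the
odds-ratio excesses is summarized by

* RERI = OR11 - OR10 - OR01 + 1   (0 = exactly additive), and
* S    = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1))   (1 = exactly additive),

the standard reporting recommended for interaction in case-control studies.
Confidence intervals come either from the delta method on the fitted model's
coefficient covariance (RERI on the natural scale, S through log S), or from
a parametric bootstrap drawing coefficients from N(beta, Sigma).  When a
component OR is below 1 or the S denominator is non-positive the estimates
are still reported but annotated, since S loses its interpretation there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .core_data import ValidationError
from .effects import FittedModel

__all__ = [
    "InteractionEstimate",
    "reri",
    "synergism_index",
    "interaction_ci_delta",
    "interaction_ci_bootstrap",
]

_S_DENOM_EPS = 1e-12


@dataclass
class InteractionEstimate:
    reri: float
    reri_ci: tuple[float, float]
    s: float | None
    s_ci: tuple[float, float] | None
    method: str
    ci_level: float
    notes: list[str] = field(default_factory=list)


def _check_ors(*ors: float) -> None:
    for value in ors:
        if not value > 0.0:
            raise ValidationError(f"odds ratios must be positive, got {value}")


def reri(or11: float, or10: float, or01: float) -> float:
    """Relative excess risk due to interaction: OR11 - OR10 - OR01 + 1."""
    _check_ors(or11, or10, or01)
    return or11 - or10 - or01 + 1.0


def synergism_index(or11: float, or10: float, or01: float) -> tuple[float | None, list[str]]:
    """Synergy index S = (OR11 - 1) / ((OR10 - 1) + (OR01 - 1)).

    Returns (value, notes); the value is None when the denominator is within
    1e-12 of zero.  Notes flag a negative denominator and component ORs below
    one (S is reported regardless but reads awkwardly there).
    """
    _check_ors(or11, or10, or01)
    notes: list[str] = []
    denominator = (or10 - 1.0) + (or01 - 1.0)
    if or10 < 1.0 or or01 < 1.0:
        notes.append("component OR below 1: synergy index interpretation is limited")
    if abs(denominator) < _S_DENOM_EPS:
        notes.append("synergy index undefined: denominator is zero")
        return None, notes
    if denominator < 0.0:
        notes.append("synergy index denominator is negative")
    return (or11 - 1.0) / denominator, notes


def _component_ors(model: FittedModel, g1: str, g2: str, g3: str):
    b1, b2, b3 = model.coef(g1), model.coef(g2), model.coef(g3)
    return math.exp(b1), math.exp(b2), math.exp(b3)


def interaction_ci_delta(
    model: FittedModel,
    g1_term: str,
    g2_term: str,
    g3_term: str,
    ci_level: float = 0.95,
) -> InteractionEstimate:
    """Delta-method CIs for RERI and S from the model's coefficient covariance.

    RERI variance is grad' Sigma grad with grad = (-e^{b1}, e^{b2}, -e^{b3})
    over (G1, G2, G3); the S interval is built on log S and back-transformed,
    and is left undefined (with a note) when OR11 <= 1 or the S denominator
    is non-positive.
    """
    or10, or11, or01 = _component_ors(model, g1_term, g2_term, g3_term)
    sigma = model.vcov_submatrix([g1_term, g2_term, g3_term])
    eig_min = float(np.linalg.eigvalsh(sigma).min())
    if eig_min < -1e-8 * max(1.0, float(np.abs(sigma).max())):
        raise ValidationError("coefficient covariance submatrix is not PSD")

    z = norm.ppf(0.5 + ci_level / 2.0)
    reri_point = reri(or11, or10, or01)
    grad = np.array([-or10, or11, -or01])
    reri_se = math.sqrt(max(float(grad @ sigma @ grad), 0.0))
    reri_ci = (reri_point - z * reri_se, reri_point + z * reri_se)

    s_point, notes = synergism_index(or11, or10, or01)
    s_ci: tuple[float, float] | None = None
    denominator = (or10 - 1.0) + (or01 - 1.0)
    if s_point is not None and or11 > 1.0 and denominator > 0.0:
        # d logS / d beta, via logS = log(OR11-1) - log(OR10+OR01-2)
        grad_ls = np.array([
            -or10 / denominator,
            or11 / (or11 - 1.0),
            -or01 / denominator,
        ])
        ls_se = math.sqrt(max(float(grad_ls @ sigma @ grad_ls), 0.0))
        s_ci = (s_point * math.exp(-z * ls_se), s_point * math.exp(z * ls_se))
    elif s_point is not None:
        notes.append("synergy index CI undefined: OR11 <= 1 or non-positive denominator")
    return InteractionEstimate(
        reri=reri_point, reri_ci=reri_ci, s=s_point, s_ci=s_ci,
        method="delta", ci_level=ci_level, notes=notes,
    )


def interaction_ci_bootstrap(
    model: FittedModel,
    g1_term: str,
    g2_term: str,
    g3_term: str,
    n_draws: int = 10000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> InteractionEstimate:
    """Parametric-bootstrap percentile CIs: draw beta* ~ N(beta, Sigma).

    Deterministic given ``seed``.  S draws with an (effectively) zero
    denominator are dropped from the S percentile interval; a note records
    the dropped fraction when above 1%.
    """
    if n_draws < 1000:
        raise ValidationError("n_draws must be at least 1000")
    betas = np.array([model.coef(t) for t in (g1_term, g2_term, g3_term)])
    sigma = model.vcov_submatrix([g1_term, g2_term, g3_term])
    eig_min = float(np.linalg.eigvalsh(sigma).min())
    if eig_min < -1e-8 * max(1.0, float(np.abs(sigma).max())):
        raise ValidationError("coefficient covariance submatrix is not PSD")

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(betas, sigma, size=n_draws, method="svd")
    or10_d = np.exp(draws[:, 0])
    or11_d = np.exp(draws[:, 1])
    or01_d = np.exp(draws[:, 2])

    alpha = 1.0 - ci_level
    reri_d = or11_d - or10_d - or01_d + 1.0
    reri_ci = tuple(np.quantile(reri_d, [alpha / 2.0, 1.0 - alpha / 2.0]))

    or10, or11, or01 = _component_ors(model, g1_term, g2_term, g3_term)
    reri_point = reri(or11, or10, or01)
    s_point, notes = synergism_index(or11, or10, or01)
    s_ci: tuple[float, float] | None = None
    if s_point is not None:
        denom_d = (or10_d - 1.0) + (or01_d - 1.0)
        valid = np.abs(denom_d) > _S_DENOM_EPS
        dropped = 1.0 - valid.mean()
        if dropped > 0.01:
            notes.append(f"synergy index bootstrap dropped {dropped:.1%} degenerate draws")
        s_d = (or11_d[valid] - 1.0) / denom_d[valid]
        s_ci = tuple(np.quantile(s_d, [alpha / 2.0, 1.0 - alpha / 2.0]))
    return InteractionEstimate(
        reri=reri_point, reri_ci=reri_ci, s=s_point, s_ci=s_ci,
        method="bootstrap", ci_level=ci_level, notes=notes,
    )
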