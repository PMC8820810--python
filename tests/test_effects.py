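import math
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from gxepi import (
    CollinearityError,
    NestingError,
    crude_or,
    fit_logistic,
    fit_nested_glmm,
    or_from_model,
)


def _sim_logistic(rng, n, betas):
    X = np.column_stack([np.ones(n)] +
                        [rng.binomial(1, 0.4, n).astype(float)
                         for _ in range(len(betas) - 1)])
    y = rng.binomial(1, expit(X @ np.asarray(betas))).astype(float)
    return y, X


def test_balanced_table_gives_zero_slope():
    # identical case fraction in both arms -> OR exactly 1
    y = np.array([1, 0, 1, 0] * 10, dtype=float)
    x = np.array([1, 1, 0, 0] * 10, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    model = fit_logistic(y, X, ["intercept", "arm"])
    assert model.coef("arm") == pytest.approx(0.0, abs=1e-8)
    assert or_from_model(model, "arm").or_point == pytest.approx(1.0, abs=1e-8)


def test_loglik_matches_direct_optimizer_oracle():
    rng = np.random.default_rng(3)
    y, X = _sim_logistic(rng, 40, [-0.4, 0.9, -0.6])
    model = fit_logistic(y, X)

    def negll(beta):
        eta = X @ beta
        return -(y @ eta - np.logaddexp(0.0, eta).sum())

    oracle = minimize(negll, np.zeros(3), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    assert model.loglik == pytest.approx(-oracle.fun, abs=1e-6)


def test_matches_statsmodels_cross_check():
    statsmodels = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(9)
    y, X = _sim_logistic(rng, 300, [-0.2, 0.7, 0.4])
    model = fit_logistic(y, X)
    reference = statsmodels.Logit(y, X).fit(disp=0)
    assert model.beta == pytest.approx(reference.params, abs=1e-6)
    assert np.sqrt(np.diag(model.vcov)) == pytest.approx(reference.bse, rel=1e-4)
    assert model.bic == pytest.approx(reference.bic, abs=1e-5)


def test_complete_separation_reported_not_raised():
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    x = y.copy()  # perfectly separates
    X = np.column_stack([np.ones_like(x), x])
    model = fit_logistic(y, X)
    assert model.converged is False
    assert any("separation" in note for note in model.notes)


def test_rank_deficient_design_names_collinear_term():
    rng = np.random.default_rng(0)
    x = rng.binomial(1, 0.5, 50).astype(float)
    X = np.column_stack([np.ones(50), x, 2.0 * x])
    # either member of the collinear pair may be reported, never the intercept
    with pytest.raises(CollinearityError, match="x|double") as excinfo:
        fit_logistic(rng.binomial(1, 0.5, 50).astype(float), X,
                     ["intercept", "x", "double"])
    assert "intercept" not in str(excinfo.value)


def test_bic_formula_on_three_parameter_fit():
    rng = np.random.default_rng(5)
    y, X = _sim_logistic(rng, 120, [-0.3, 0.5, 0.2])
    model = fit_logistic(y, X)
    assert model.bic == pytest.approx(-2 * model.loglik + 3 * math.log(120), abs=1e-9)


@pytest.mark.parametrize("cells, expected_or", [
    ((20, 10, 10, 20), 4.0),
    ((10, 10, 10, 10), 1.0),
])
def test_crude_or_arithmetic(cells, expected_or):
    result = crude_or(*cells)
    assert result.or_point == pytest.approx(expected_or)
    if expected_or == 1.0:
        assert result.ci_low < 1.0 < result.ci_high


def test_crude_or_zero_cell_correction_and_undefined_margin():
    corrected = crude_or(5, 0, 3, 7)
    assert math.isfinite(corrected.or_point)
    assert any("continuity" in n for n in corrected.notes)
    undefined = crude_or(5, 0, 3, 0)
    assert math.isnan(undefined.or_point)
    assert any("undefined" in n for n in undefined.notes)


def test_or_from_model_closed_forms():
    from gxepi.effects import FittedModel

    model = FittedModel(["b"], np.array([0.0]), np.array([[0.01]]),
                        0.0, 0.0, {}, 10, True)
    result = or_from_model(model, "b")
    assert result.or_point == pytest.approx(1.0)
    assert (result.ci_low, result.ci_high) == (
        pytest.approx(0.822, abs=5e-4), pytest.approx(1.217, abs=5e-4))
    tight = FittedModel(["b"], np.array([math.log(2)]), np.array([[1e-18]]),
                        0.0, 0.0, {}, 10, True)
    res2 = or_from_model(tight, "b")
    assert res2.or_point == pytest.approx(2.0)
    assert res2.ci_low == pytest.approx(2.0, rel=1e-6)
    assert res2.ci_high == pytest.approx(2.0, rel=1e-6)


def _clustered_data(seed, n_groups=120, size=8, sd=0.8, betas=(-0.5, 0.9, 0.4)):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), size)
    u = rng.normal(0, sd, n_groups)
    x1 = rng.binomial(1, 0.4, n_groups * size).astype(float)
    x2 = rng.normal(0, 1, n_groups * size)
    X = np.column_stack([np.ones_like(x1), x1, x2])
    eta = X @ np.asarray(betas) + u[g]
    y = (rng.random(n_groups * size) < expit(eta)).astype(float)
    return y, X, g


def test_glmm_matches_lme4_glmer_oracle(tmp_path):
    """Laplace fit agrees with glmer (the field-standard implementation)."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable: the glmer oracle cannot run")
    y, X, g = _clustered_data(42)
    model = fit_nested_glmm(y, X, ["intercept", "x1", "x2"], stratum=g)
    data = tmp_path / "d.csv"
    np.savetxt(data, np.column_stack([y, X[:, 1], X[:, 2], g]),
               delimiter=",", header="y,x1,x2,g", comments="")
    script = textwrap.dedent("""\
        suppressMessages(library(lme4))
        d <- read.csv(commandArgs(TRUE)[1])
        f <- glmer(y ~ x1 + x2 + (1|g), data=d, family=binomial)
        cat(fixef(f), sqrt(unlist(VarCorr(f))), logLik(f), sep="\\n")
    """)
    (tmp_path / "fit.R").write_text(script)
    out = subprocess.run(["Rscript", str(tmp_path / "fit.R"), str(data)],
                         capture_output=True, text=True, check=True)
    ref = [float(v) for v in out.stdout.split()]
    assert model.beta == pytest.approx(ref[:3], abs=5e-3)
    assert model.variance_components["stratum"] == pytest.approx(ref[3], abs=5e-3)
    assert model.loglik == pytest.approx(ref[4], abs=5e-3)


def test_glmm_recovers_variance_component():
    y, X, g = _clustered_data(1, n_groups=400, size=12, sd=0.5)
    model = fit_nested_glmm(y, X, stratum=g)
    assert model.variance_components["stratum"] == pytest.approx(0.5, rel=0.3)


def test_glmm_likelihood_dominates_logistic():
    y, X, g = _clustered_data(13)
    glmm = fit_nested_glmm(y, X, stratum=g)
    logistic = fit_logistic(y, X)
    assert glmm.loglik >= logistic.loglik - 1e-6


def test_single_stratum_reduces_to_logistic():
    rng = np.random.default_rng(21)
    y, X = _sim_logistic(rng, 200, [-0.4, 0.8])
    one_group = np.zeros(200, dtype=int)
    glmm = fit_nested_glmm(y, X, stratum=one_group)
    logistic = fit_logistic(y, X)
    assert glmm.beta == pytest.approx(logistic.beta, abs=1e-4)
    assert glmm.variance_components["stratum"] == pytest.approx(0.0, abs=0.05)


def test_non_nested_labels_raise():
    y = np.array([0.0, 1.0, 0.0, 1.0])
    X = np.ones((4, 1))
    with pytest.raises(NestingError):
        fit_nested_glmm(y, X, stratum=["s1", "s1", "s2", "s2"],
                        hospital=["h1", "h2", "h1", "h1"])


def test_wald_ci_coverage_under_the_null():
    """95% Wald CIs cover OR=1 in 93-97% of null simulations."""
    rng = np.random.default_rng(123)
    covered = 0
    n_sims = 200
    for _ in range(n_sims):
        y, X = _sim_logistic(rng, 300, [-0.3, 0.0])
        model = fit_logistic(y, X)
        result = or_from_model(model, "x1")
        covered += result.ci_low <= 1.0 <= result.ci_high
    assert 0.93 * n_sims <= covered <= 0.97 * n_sims
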