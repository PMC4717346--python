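"""Single-species occupancy likelihood, MLE, K counting and prediction."""

import itertools

import numpy as np
import pytest
from scipy.special import expit, logit

from felidcam import occupancy_single as occ
from felidcam.camera_records import DetectionHistory

from conftest import make_history


def nll_const(history, psi, p):
    """negloglik of the intercept-only model at probability-scale (psi, p)."""
    spec = occ.parse_model_string("psi(.), p(.)")
    return occ.negloglik(spec, np.array([logit(psi), logit(p)]), history)


# ---------------------------------------------------------------------------
# Likelihood closed forms


def test_negloglik_closed_forms():
    h10 = make_history([[1, 0]])
    # psi * p * (1-p) = 0.5 * 0.5 * 0.5 = 0.125
    assert nll_const(h10, 0.5, 0.5) == pytest.approx(-np.log(0.125), abs=1e-10)
    h00 = make_history([[0, 0]])
    # psi*(1-p)^2 + (1-psi) = 0.125 + 0.5
    assert nll_const(h00, 0.5, 0.5) == pytest.approx(-np.log(0.625), abs=1e-10)


@pytest.mark.parametrize("T", [1, 2, 3, 4])
def test_likelihood_normalizes_over_all_histories(T):
    rng = np.random.default_rng(42 + T)
    for _ in range(20):
        psi, p = rng.uniform(0.05, 0.95, size=2)
        total = sum(
            np.exp(-nll_const(make_history([h]), psi, p))
            for h in itertools.product([0, 1], repeat=T)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_missing_occasions_contribute_no_factor():
    full = make_history([[1, 0]])
    padded = make_history([[1, 0, np.nan]])
    assert nll_const(padded, 0.3, 0.6) == pytest.approx(nll_const(full, 0.3, 0.6))


# ---------------------------------------------------------------------------
# Parameter counting


@pytest.mark.parametrize(
    "model, K",
    [
        ("psi(.), p(PumaCount + HD + G + P3 + G*P3)", 7),
        ("psi(.), p(.)", 2),
        ("psi(.), p(HD)", 3),
        ("psi(.), p(PumaCount + HD)", 4),
        ("psi(.), p(G + P2 + G*P2)", 5),
    ],
)
def test_count_parameters(model, K):
    assert occ.count_parameters(model) == K


def test_unknown_covariate_raises(tiny_history):
    with pytest.raises(KeyError):
        occ.fit_mle("psi(.), p(Elevation)", tiny_history)


# ---------------------------------------------------------------------------
# Fitting


def test_intercept_fit_matches_grid_search():
    """The MLE agrees with a brute-force 2-D grid optimum on a small instance."""
    rng = np.random.default_rng(5)
    z = rng.random(30) < 0.7
    Y = (rng.random((30, 6)) < 0.35) * z[:, None]
    hist = make_history(Y.astype(float))
    fit = occ.fit_mle("psi(.), p(.)", hist, seed=1)
    grid = np.linspace(0.01, 0.99, 197)
    vals = np.array([[nll_const(hist, a, b) for b in grid] for a in grid])
    ia, ib = np.unravel_index(vals.argmin(), vals.shape)
    assert fit.psi_hat == pytest.approx(grid[ia], abs=0.01)
    assert fit.p_hat == pytest.approx(grid[ib], abs=0.01)
    assert fit.converged and not fit.boundary


def test_parameter_recovery_large_sim():
    rng = np.random.default_rng(11)
    psi, p = 0.8, 0.4
    z = rng.random(500) < psi
    Y = (rng.random((500, 10)) < p) * z[:, None]
    fit = occ.fit_mle("psi(.), p(.)", make_history(Y.astype(float)), seed=0)
    # within ~3 standard errors of truth (SEs from the observed information)
    se_psi = fit.se[0] * fit.psi_hat * (1 - fit.psi_hat)
    se_p = fit.se[1] * fit.p_hat * (1 - fit.p_hat)
    assert abs(fit.psi_hat - psi) < 3 * se_psi
    assert abs(fit.p_hat - p) < 3 * se_p


def test_saturated_data_flags_boundary():
    fit = occ.fit_mle("psi(.), p(.)", make_history(np.ones((8, 5))), seed=0)
    assert fit.boundary
    assert fit.psi_hat > 0.99 and fit.p_hat > 0.99


def test_adding_detection_never_decreases_psi_hat():
    rng = np.random.default_rng(3)
    Y = (rng.random((12, 5)) < 0.3).astype(float)
    Y[5] = 0  # ensure at least one empty site
    base = occ.fit_mle("psi(.), p(.)", make_history(Y), seed=0, compute_se=False)
    Y2 = Y.copy()
    Y2[5, 2] = 1
    more = occ.fit_mle("psi(.), p(.)", make_history(Y2), seed=0, compute_se=False)
    assert more.psi_hat >= base.psi_hat - 1e-6


def test_all_zero_data_rejected():
    with pytest.raises(ValueError):
        occ.fit_mle("psi(.), p(.)", make_history(np.zeros((4, 3))))


def test_covariate_effect_recovery_small():
    """Median slope estimate for a time-varying binary covariate is near truth."""
    rng = np.random.default_rng(9)
    beta = -1.0
    est = []
    for _ in range(15):
        z = rng.random(30) < 0.85
        X = (rng.random((30, 40)) < 0.3).astype(float)
        p = expit(logit(0.25) + beta * X)
        Y = ((rng.random((30, 40)) < p) & z[:, None]).astype(float)
        cov = occ.CovariateSet(occasion={"X": X})
        fit = occ.fit_mle("psi(.), p(X)", make_history(Y), cov, n_starts=1, compute_se=False)
        est.append(fit.coef("p:X"))
    assert abs(np.median(est) - beta) < 0.35


# ---------------------------------------------------------------------------
# Prediction


def test_predict_intercept_profile():
    rng = np.random.default_rng(2)
    z = rng.random(60) < 0.8
    Y = ((rng.random((60, 8)) < 0.5) & z[:, None]).astype(float)
    fit = occ.fit_mle("psi(.), p(.)", make_history(Y), seed=0)
    pred, lo, hi = occ.predict_detection(fit, {})
    assert pred == pytest.approx(expit(fit.beta[1]))
    assert 0 <= lo <= pred <= hi <= 1


def test_predict_monotone_in_negative_covariate(survey):
    """A negative puma-count slope makes predicted detection decrease with count."""
    fit = occ.fit_mle(
        "psi(.), p(PumaCount + HD + G + P3 + G*P3)",
        survey.daily_b,
        survey.covariates,
        seed=0,
        n_starts=2,
    )
    coef = fit.coef("p:PumaCount")
    preds = [
        occ.predict_detection(fit, {"PumaCount": v})[0] for v in np.linspace(-1, 3, 5)
    ]
    if coef < 0:
        assert all(a > b for a, b in zip(preds, preds[1:]))
    else:
        assert all(a < b for a, b in zip(preds, preds[1:]))


def test_predict_unknown_covariate_rejected(survey):
    fit = occ.fit_mle("psi(.), p(G)", survey.daily_b, survey.covariates, seed=0)
    with pytest.raises(KeyError):
        occ.predict_detection(fit, {"Elevation": 1.0})


def test_delta_ci_matches_parametric_bootstrap():
    """Delta-method CI bounds agree with a parametric-bootstrap CI."""
    rng = np.random.default_rng(21)
    psi, p = 0.8, 0.45
    n, T = 150, 10
    z = rng.random(n) < psi
    Y = ((rng.random((n, T)) < p) & z[:, None]).astype(float)
    fit = occ.fit_mle("psi(.), p(.)", make_history(Y), seed=0)
    _, lo, hi = occ.predict_detection(fit, {})
    boots = []
    for _ in range(300):
        zb = rng.random(n) < fit.psi_hat
        Yb = ((rng.random((n, T)) < fit.p_hat) & zb[:, None]).astype(float)
        fb = occ.fit_mle("psi(.), p(.)", make_history(Yb), seed=0, n_starts=1, compute_se=False)
        boots.append(fb.p_hat)
    blo, bhi = np.quantile(boots, [0.025, 0.975])
    assert lo == pytest.approx(blo, abs=0.03)
    assert hi == pytest.approx(bhi, abs=0.03)
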