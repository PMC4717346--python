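"""Single-season, single-species occupancy model with detection covariates.

The model: each site i is used by the species with probability Psi_i
(occupancy, here intercept-only), and, given use, the species is detected on
occasion t with probability p_it.  Both probabilities are logit-linked to
covariates; the site likelihood is

    L_i = Psi_i * prod_t p_it^y_it (1 - p_it)^(1 - y_it)
          + (1 - Psi_i) * I(no detection at i),

with missing occasions (camera down) contributing no factor.  Detection
covariates may be site-level (e.g. puma count, human development, grid),
occasion-level (lag indicators P1-P4, effort) or interactions (G*Pk).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._numeric import LOG_EPS, multistart_minimize, numeric_hessian
from .camera_records import DetectionHistory
from .covariates import LagCovariateMatrix

__all__ = [
    "OccupancyModelSpec",
    "CovariateSet",
    "SingleSpeciesFit",
    "parse_model_string",
    "count_parameters",
    "negloglik",
    "fit_mle",
    "predict_detection",
]


@dataclass(frozen=True)
class OccupancyModelSpec:
    """Symbolic formulas for occupancy and detection.

    ``psi_terms`` and ``p_terms`` list covariate names (intercepts are
    implicit); interaction terms are written ``A*B``.  The canonical string
    form is e.g. ``"psi(.), p(PumaCount + HD + G + P3 + G*P3)"``.
    """

    psi_terms: tuple[str, ...] = ()
    p_terms: tuple[str, ...] = ()
    label: str = ""

    def __str__(self) -> str:
        return self.label or format_model_string(self)


def format_model_string(spec: OccupancyModelSpec) -> str:
    psi = " + ".join(spec.psi_terms) or "."
    p = " + ".join(spec.p_terms) or "."
    return f"psi({psi}), p({p})"


def parse_model_string(s: str) -> OccupancyModelSpec:
    """Parse a model string such as ``"psi(.), p(PumaCount+HD+G+P3+G*P3)"``."""
    text = s.replace(" ", "").replace("Psi", "psi").replace("PSI", "psi")
    out: dict[str, tuple[str, ...]] = {}
    for key in ("psi", "p"):
        start = text.find(f"{key}(")
        if key == "p":  # avoid matching the 'p' inside 'psi('
            idx = 0
            while True:
                start = text.find("p(", idx)
                if start == -1 or start == 0 or text[start - 2 : start + 1] != "psi":
                    break
                idx = start + 1
        if start == -1:
            raise ValueError(f"model string lacks a {key}(...) clause: {s!r}")
        depth, j = 0, start + len(key)
        for j in range(start + len(key), len(text)):
            if text[j] == "(":
                depth += 1
            elif text[j] == ")":
                depth -= 1
                if depth == 0:
                    break
        inner = text[start + len(key) + 1 : j]
        terms = tuple(t for t in inner.split("+") if t and t != ".")
        out[key] = terms
    return OccupancyModelSpec(psi_terms=out["psi"], p_terms=out["p"], label=s.strip())


def count_parameters(spec: OccupancyModelSpec | str) -> int:
    """K = (psi terms + intercept) + (p terms + intercept)."""
    if isinstance(spec, str):
        spec = parse_model_string(spec)
    return (1 + len(spec.psi_terms)) + (1 + len(spec.p_terms))


@dataclass
class CovariateSet:
    """Resolved covariate tables for one study area.

    ``site``: DataFrame indexed like the detection history's sites (already
    standardized where appropriate).  ``occasion``: name -> (n_sites,
    n_occasions) matrix for time-varying covariates.  Lag matrices may be
    supplied via ``lags`` and are resolved by name (P1..P4, G*P1..G*P4).
    """

    site: pd.DataFrame | None = None
    occasion: dict[str, np.ndarray] = field(default_factory=dict)
    lags: LagCovariateMatrix | None = None

    def resolve(self, name: str, n_sites: int, n_occasions: int) -> np.ndarray:
        """Covariate column as an (n_sites, n_occasions) matrix."""
        if name in self.occasion:
            return np.asarray(self.occasion[name], dtype=float)
        if self.lags is not None:
            try:
                return np.asarray(self.lags.column(name), dtype=float)
            except KeyError:
                pass
        if self.site is not None:
            if name in self.site.columns:
                col = self.site[name].to_numpy(dtype=float)
                return np.repeat(col[:, None], n_occasions, axis=1)
            if "*" in name:  # interaction of two site columns
                a, b = name.split("*", 1)
                col = (self.site[a] * self.site[b]).to_numpy(dtype=float)
                return np.repeat(col[:, None], n_occasions, axis=1)
        raise KeyError(f"covariate {name!r} not found")


def _design_tensors(
    spec: OccupancyModelSpec,
    history: DetectionHistory,
    covariates: CovariateSet | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(X_psi, X_p): (n, k_psi) site matrix and (n, t, k_p) occasion tensor."""
    n, t = history.Y.shape
    cov = covariates or CovariateSet()
    X_psi = np.ones((n, 1 + len(spec.psi_terms)))
    for j, name in enumerate(spec.psi_terms, start=1):
        X_psi[:, j] = cov.resolve(name, n, t)[:, 0]
    X_p = np.ones((n, t, 1 + len(spec.p_terms)))
    for j, name in enumerate(spec.p_terms, start=1):
        X_p[:, :, j] = cov.resolve(name, n, t)
    if not (np.all(np.isfinite(X_psi)) and np.all(np.isfinite(X_p))):
        raise ValueError("non-finite covariate value in design matrix")
    return X_psi, X_p


def negloglik(
    spec: OccupancyModelSpec,
    params: np.ndarray,
    history: DetectionHistory,
    covariates: CovariateSet | None = None,
) -> float:
    """Negative log-likelihood at logit-scale ``params`` (psi block then p block)."""
    X_psi, X_p = _design_tensors(spec, history, covariates)
    return _negloglik_from_design(params, history.Y, X_psi, X_p)


def _negloglik_from_design(
    params: np.ndarray, Y: np.ndarray, X_psi: np.ndarray, X_p: np.ndarray
) -> float:
    k_psi = X_psi.shape[1]
    beta_psi = np.asarray(params[:k_psi], dtype=float)
    beta_p = np.asarray(params[k_psi:], dtype=float)
    if beta_p.size != X_p.shape[2]:
        raise ValueError("parameter vector length does not match design")
    psi = expit(X_psi @ beta_psi)  # (n,)
    p = expit(X_p @ beta_p)  # (n, t)
    obs = ~np.isnan(Y)
    y = np.nan_to_num(Y, nan=0.0)
    # log of the detection factor over observed occasions only
    logf = np.where(obs, y * np.log(np.maximum(p, LOG_EPS)) + (1 - y) * np.log(np.maximum(1 - p, LOG_EPS)), 0.0)
    log_det_prod = logf.sum(axis=1)
    never = (np.where(obs, y, 0.0).sum(axis=1) == 0)
    lik = psi * np.exp(log_det_prod) + (1 - psi) * never
    return float(-np.log(np.maximum(lik, LOG_EPS)).sum())


@dataclass
class SingleSpeciesFit:
    spec: OccupancyModelSpec
    beta: np.ndarray  # logit-scale coefficients: psi block then p block
    se: np.ndarray | None
    vcov: np.ndarray | None
    neg2loglik: float
    K: int
    converged: bool
    boundary: bool
    psi_hat: float
    p_hat: float
    n_sites: int
    param_names: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.beta[self.param_names.index(name)])

    def coef_se(self, name: str) -> float:
        if self.se is None:
            return float("nan")
        return float(self.se[self.param_names.index(name)])

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": str(self.spec),
                "beta": self.beta.tolist(),
                "se": None if self.se is None else self.se.tolist(),
                "param_names": self.param_names,
                "neg2loglik": self.neg2loglik,
                "K": self.K,
                "converged": self.converged,
                "boundary": self.boundary,
            }
        )


def fit_mle(
    spec: OccupancyModelSpec | str,
    history: DetectionHistory,
    covariates: CovariateSet | None = None,
    *,
    n_starts: int = 5,
    seed: int = 0,
    compute_se: bool = True,
    boundary_logit: float = 6.0,
) -> SingleSpeciesFit:
    """Maximum-likelihood fit by quasi-Newton minimization from jittered starts.

    Standard errors come from the inverse observed information.  Occupancy or
    baseline detection estimates pressed against the boundary of (0, 1)
    (|logit| beyond ``boundary_logit``, i.e. outside roughly [0.0025, 0.9975])
    set the ``boundary`` flag rather than being silently accepted.
    """
    if isinstance(spec, str):
        spec = parse_model_string(spec)
    X_psi, X_p = _design_tensors(spec, history, covariates)
    if np.nansum(history.Y) == 0:
        raise ValueError("cannot fit an occupancy model to all-zero data")
    k = X_psi.shape[1] + X_p.shape[2]
    rng = np.random.default_rng(seed)
    fn = lambda b: _negloglik_from_design(b, history.Y, X_psi, X_p)
    res = multistart_minimize(fn, k, n_starts=n_starts, rng=rng, compute_se=compute_se)
    k_psi = X_psi.shape[1]
    psi_hat = float(expit(res.x[0])) if np.isfinite(res.x[0]) else float("nan")
    p_hat = float(expit(res.x[k_psi])) if np.isfinite(res.x[k_psi]) else float("nan")
    boundary = bool(np.any(np.abs(res.x[[0, k_psi]]) > boundary_logit))
    names = ["psi:(Intercept)"] + [f"psi:{t}" for t in spec.psi_terms]
    names += ["p:(Intercept)"] + [f"p:{t}" for t in spec.p_terms]
    return SingleSpeciesFit(
        spec=spec,
        beta=res.x,
        se=res.se,
        vcov=res.vcov,
        neg2loglik=2.0 * res.fun,
        K=k,
        converged=res.converged,
        boundary=boundary,
        psi_hat=psi_hat,
        p_hat=p_hat,
        n_sites=history.n_sites,
        param_names=names,
    )


def predict_detection(
    fit: SingleSpeciesFit,
    covariate_profile: Mapping[str, float],
    *,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Detection probability and delta-method CI at a covariate profile.

    The profile maps detection covariate names to values (on the same,
    typically standardized, scale used in fitting; unnamed covariates default
    to 0).  The CI is computed on the logit scale and back-transformed, so it
    stays inside [0, 1].
    """
    from scipy.stats import norm

    k_psi = 1 + len(fit.spec.psi_terms)
    terms = fit.spec.p_terms
    unknown = set(covariate_profile) - set(terms)
    if unknown:
        raise KeyError(f"profile references unknown covariate(s): {sorted(unknown)}")
    x = np.array([1.0] + [float(covariate_profile.get(t, 0.0)) for t in terms])
    beta_p = fit.beta[k_psi:]
    eta = float(x @ beta_p)
    if fit.vcov is None:
        return expit(eta), float("nan"), float("nan")
    V = fit.vcov[k_psi:, k_psi:]
    se_eta = float(np.sqrt(x @ V @ x))
    z = norm.ppf(1 - alpha / 2)
    return expit(eta), float(expit(eta - z * se_eta)), float(expit(eta + z * se_eta))
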