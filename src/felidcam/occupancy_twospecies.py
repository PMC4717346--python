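"""Conditional two-species occupancy model (dominant A, subordinate B).

The parameterization follows the conditional co-occurrence formulation used
for dominant/subordinate pairs: occupancy is described by psiA (dominant),
psiBA (subordinate given dominant present) and psiBa (subordinate given
dominant absent); detection by pA (dominant alone), rA (dominant when both
present), pB (subordinate alone), rBA (subordinate when both present and the
dominant was detected that occasion) and rBa (subordinate when both present
and the dominant was not detected).  The site likelihood sums over the four
joint latent states:

    L_i = psiA*psiBA * prod_t f_both(a_t, b_t)
        + psiA*(1-psiBA) * prod_t f_Aonly(a_t) * I(b == 0)
        + (1-psiA)*psiBa * prod_t f_Bonly(b_t) * I(a == 0)
        + (1-psiA)*(1-psiBa) * I(a == 0, b == 0)

Constraint sets express the biological hypotheses: psiBA = psiBa (dominant
does not alter subordinate occupancy), pB = rBA = rBa (dominant does not
alter subordinate detection), or pB free with rBA = rBa.  Covariates attach
to detection parameters on the logit scale, with slopes shared within an
equality group.  Model strings use the field's table notation, e.g.
``"psiA, (psiBA=psiBa), pA, rA, (pB=rBA=rBa(G+HD))"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from ._numeric import LOG_EPS, multistart_minimize
from .camera_records import DetectionHistory
from .occupancy_single import CovariateSet

__all__ = [
    "TwoSpeciesParams",
    "TwoSpeciesSpec",
    "TwoSpeciesFit",
    "parse_two_species_string",
    "count_parameters_two_species",
    "site_likelihood",
    "negloglik_two_species",
    "fit_two_species",
    "detect_degenerate_dominant",
]

_OCC_NAMES = ("psiA", "psiBA", "psiBa")
_DET_NAMES = ("pA", "rA", "pB", "rBA", "rBa")


@dataclass(frozen=True)
class TwoSpeciesParams:
    """Probability-scale parameter values (no covariates)."""

    psiA: float
    psiBA: float
    psiBa: float
    pA: float
    rA: float
    pB: float
    rBA: float
    rBa: float

    def __post_init__(self) -> None:
        for name in _OCC_NAMES + _DET_NAMES:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} = {v} outside (0, 1)")


@dataclass(frozen=True)
class ParamGroup:
    """One free intercept (+ shared covariate slopes) tied to >=1 parameter names."""

    names: tuple[str, ...]
    covariates: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return 1 + len(self.covariates)


@dataclass(frozen=True)
class TwoSpeciesSpec:
    """A two-species model as a list of parameter groups.

    Every one of the 8 canonical parameter names must appear in exactly one
    group; names sharing a group share an intercept and covariate slopes.
    """

    groups: tuple[ParamGroup, ...]
    label: str = ""

    def __post_init__(self) -> None:
        seen: list[str] = []
        for g in self.groups:
            seen.extend(g.names)
        expected = set(_OCC_NAMES) | set(_DET_NAMES)
        if set(seen) != expected or len(seen) != len(expected):
            raise ValueError(
                f"groups must partition {sorted(expected)}; got {sorted(seen)}"
            )

    def group_of(self, name: str) -> int:
        for gi, g in enumerate(self.groups):
            if name in g.names:
                return gi
        raise KeyError(name)

    def __str__(self) -> str:
        return self.label or _format_spec(self)


def _format_spec(spec: TwoSpeciesSpec) -> str:
    parts = []
    for g in spec.groups:
        covs = f"({'+'.join(g.covariates)})" if g.covariates else ""
        if len(g.names) == 1:
            parts.append(g.names[0] + covs)
        else:
            parts.append("(" + "=".join(g.names) + covs + ")")
    return ", ".join(parts)


def parse_two_species_string(s: str) -> TwoSpeciesSpec:
    """Parse table notation like ``"psiA, (psiBA=psiBa), pA(E), rA(E), (pB=rBA=rBa(G+HD+E))"``.

    Superscript carets and emphasis markers are tolerated (``Ψ^A`` or
    ``psi^A`` are read as psiA).  Covariates in parentheses after the last
    name of a group apply to every member of the group.
    """
    text = s.replace("Ψ", "psi").replace("ψ", "psi")
    text = re.sub(r"[\s*^]", "", text)
    # split on top-level commas
    tokens, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            tokens.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if cur:
        tokens.append("".join(cur))

    groups: list[ParamGroup] = []
    for tok in tokens:
        if not tok:
            continue
        if tok.startswith("(") and tok.endswith(")"):
            tok = tok[1:-1]
        covs: tuple[str, ...] = ()
        m = re.search(r"\(([^()]*)\)$", tok)
        if m:
            covs = tuple(c for c in m.group(1).split("+") if c and c != ".")
            tok = tok[: m.start()]
        names = tuple(n for n in tok.split("=") if n)
        for n in names:
            if n not in _OCC_NAMES + _DET_NAMES:
                raise ValueError(f"unknown parameter name {n!r} in {s!r}")
        groups.append(ParamGroup(names, covs))
    return TwoSpeciesSpec(tuple(groups), label=s.strip())


def count_parameters_two_species(spec: TwoSpeciesSpec | str) -> int:
    """K = one intercept per group + one slope per group covariate."""
    if isinstance(spec, str):
        spec = parse_two_species_string(spec)
    return sum(g.k for g in spec.groups)


# ---------------------------------------------------------------------------
# Likelihood


def _bern_logpmf(y: np.ndarray, p: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Per-cell Bernoulli log-pmf, 0 where unobserved."""
    yy = np.nan_to_num(y, nan=0.0)
    lp = yy * np.log(np.maximum(p, LOG_EPS)) + (1 - yy) * np.log(np.maximum(1 - p, LOG_EPS))
    return np.where(obs, lp, 0.0)


def _site_loglik_matrix(
    yA: np.ndarray,
    yB: np.ndarray,
    psiA: np.ndarray,
    psiBA: np.ndarray,
    psiBa: np.ndarray,
    pA: np.ndarray,
    rA: np.ndarray,
    pB: np.ndarray,
    rBA: np.ndarray,
    rBa: np.ndarray,
) -> np.ndarray:
    """Vector of per-site likelihoods. Detection params are (n, t); psi are (n,)."""
    obs = ~(np.isnan(yA) | np.isnan(yB))
    a = np.nan_to_num(yA, nan=0.0)
    b = np.nan_to_num(yB, nan=0.0)

    # State both present: A detected via rA; B via rBA if A detected that
    # occasion, else rBa.
    rB_eff = np.where(a > 0, rBA, rBa)
    log_f_both = (_bern_logpmf(yA, rA, obs) + _bern_logpmf(yB, rB_eff, obs)).sum(axis=1)
    # State A only: B must be all-zero over observed occasions.
    b_never = (np.where(obs, b, 0.0).sum(axis=1) == 0)
    a_never = (np.where(obs, a, 0.0).sum(axis=1) == 0)
    log_f_Aonly = _bern_logpmf(yA, pA, obs).sum(axis=1)
    log_f_Bonly = _bern_logpmf(yB, pB, obs).sum(axis=1)

    lik = (
        psiA * psiBA * np.exp(log_f_both)
        + psiA * (1 - psiBA) * np.exp(log_f_Aonly) * b_never
        + (1 - psiA) * psiBa * np.exp(log_f_Bonly) * a_never
        + (1 - psiA) * (1 - psiBa) * a_never * b_never
    )
    return lik


def site_likelihood(
    params: TwoSpeciesParams,
    historyA: Sequence[float],
    historyB: Sequence[float],
) -> float:
    """Likelihood of one site's aligned occasion vectors (NaN = missing)."""
    yA = np.asarray(historyA, dtype=float)[None, :]
    yB = np.asarray(historyB, dtype=float)[None, :]
    if yA.shape != yB.shape:
        raise ValueError("history vectors must have equal length")
    t = yA.shape[1]
    ones = np.ones((1, t))
    lik = _site_loglik_matrix(
        yA,
        yB,
        np.array([params.psiA]),
        np.array([params.psiBA]),
        np.array([params.psiBa]),
        params.pA * ones,
        params.rA * ones,
        params.pB * ones,
        params.rBA * ones,
        params.rBa * ones,
    )
    return float(lik[0])


def _unpack(
    spec: TwoSpeciesSpec,
    params: np.ndarray,
    n: int,
    t: int,
    covariates: CovariateSet | None,
) -> dict[str, np.ndarray]:
    """Map the free-parameter vector to per-name probability arrays."""
    cov = covariates or CovariateSet()
    out: dict[str, np.ndarray] = {}
    pos = 0
    for g in spec.groups:
        beta = params[pos : pos + g.k]
        pos += g.k
        eta = np.full((n, t), beta[0])
        for j, name in enumerate(g.covariates, start=1):
            eta += beta[j] * cov.resolve(name, n, t)
        prob = expit(eta)
        for name in g.names:
            if name in _OCC_NAMES:
                out[name] = prob[:, 0]  # occupancy: site-level
            else:
                out[name] = prob
    return out


def negloglik_two_species(
    spec: TwoSpeciesSpec,
    params: np.ndarray,
    historyA: DetectionHistory,
    historyB: DetectionHistory,
    covariates: CovariateSet | None = None,
) -> float:
    if historyA.Y.shape != historyB.Y.shape:
        raise ValueError("species histories must share dimensions")
    n, t = historyA.Y.shape
    P = _unpack(spec, np.asarray(params, dtype=float), n, t, covariates)
    lik = _site_loglik_matrix(
        historyA.Y, historyB.Y,
        P["psiA"], P["psiBA"], P["psiBa"],
        P["pA"], P["rA"], P["pB"], P["rBA"], P["rBa"],
    )
    return float(-np.log(np.maximum(lik, LOG_EPS)).sum())


@dataclass
class TwoSpeciesFit:
    spec: TwoSpeciesSpec
    beta: np.ndarray
    se: np.ndarray | None
    neg2loglik: float
    K: int
    converged: bool
    estimates: dict[str, float]  # probability-scale intercept estimates per name
    param_names: list[str] = field(default_factory=list)
    degenerate_dominant: bool = False
    hessian_pd: bool = True

    @property
    def psiA_hat(self) -> float:
        return self.estimates["psiA"]


def fit_two_species(
    spec: TwoSpeciesSpec | str,
    historyA: DetectionHistory,
    historyB: DetectionHistory,
    covariates: CovariateSet | None = None,
    *,
    n_starts: int = 5,
    seed: int = 0,
    compute_se: bool = True,
    boundary_threshold: float = 0.99,
) -> TwoSpeciesFit:
    """MLE of a two-species model under its constraint set.

    The returned fit carries the degenerate-dominant flag (see
    :func:`detect_degenerate_dominant`): near-boundary dominant occupancy is
    the documented failure mode of conditional-detection (pB != rB.) models
    and such fits should be excluded from ranking.
    """
    if isinstance(spec, str):
        spec = parse_two_species_string(spec)
    n, t = historyA.Y.shape
    K = count_parameters_two_species(spec)
    rng = np.random.default_rng(seed)
    fn = lambda b: negloglik_two_species(spec, b, historyA, historyB, covariates)
    res = multistart_minimize(fn, K, n_starts=n_starts, rng=rng, compute_se=compute_se)

    names: list[str] = []
    for g in spec.groups:
        stem = "=".join(g.names)
        names.append(f"{stem}:(Intercept)")
        names += [f"{stem}:{c}" for c in g.covariates]
    estimates: dict[str, float] = {}
    pos = 0
    for g in spec.groups:
        for name in g.names:
            estimates[name] = float(expit(res.x[pos]))
        pos += g.k
    fit = TwoSpeciesFit(
        spec=spec,
        beta=res.x,
        se=res.se,
        neg2loglik=2.0 * res.fun,
        K=K,
        converged=res.converged,
        estimates=estimates,
        param_names=names,
        # Hessian curvature is only informative when SEs were requested.
        hessian_pd=res.hessian_pd if compute_se else True,
    )
    fit.degenerate_dominant = detect_degenerate_dominant(
        fit, boundary_threshold=boundary_threshold
    )
    return fit


def detect_degenerate_dominant(
    fit: TwoSpeciesFit, *, boundary_threshold: float = 0.99
) -> bool:
    """Flag fits whose dominant-species occupancy sits at the boundary.

    When the dominant species' estimated occupancy approaches 1 (or the
    observed information is singular) the conditional-detection split
    pB != rB. is no longer identifiable — there are effectively no
    dominant-absent sites — and the model must be excluded from ranking.
    """
    return bool(fit.psiA_hat >= boundary_threshold or not fit.hessian_pd)
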