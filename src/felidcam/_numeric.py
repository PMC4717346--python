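"""Shared numerical machinery for the occupancy likelihood fitters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize

LOG_EPS = 1e-300  # floor inside log() to avoid -inf at probability-0 corners


def numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.empty((k, k))
    ei = np.eye(k)
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                H[i, i] = (f(x + h * ei[i]) - 2 * f0 + f(x - h * ei[i])) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + h * (ei[i] + ei[j]))
                    - f(x + h * (ei[i] - ei[j]))
                    - f(x + h * (ei[j] - ei[i]))
                    + f(x - h * (ei[i] + ei[j]))
                ) / (4 * h**2)
    return H


@dataclass
class OptimResult:
    x: np.ndarray
    fun: float
    converged: bool
    se: np.ndarray | None
    vcov: np.ndarray | None
    hessian_pd: bool
    message: str = ""


def multistart_minimize(
    negloglik: Callable[[np.ndarray], float],
    k: int,
    *,
    n_starts: int = 5,
    jitter: float = 1.0,
    rng: np.random.Generator | None = None,
    gtol: float = 1e-6,
    compute_se: bool = True,
) -> OptimResult:
    """Quasi-Newton minimization from several jittered starts on the logit scale.

    The first start is the origin (all probabilities 0.5, slopes 0); the rest
    are normal jitters around it.  Standard errors come from the inverse
    observed information (numeric Hessian); a non-positive-definite Hessian
    is reported rather than silently accepted.
    """
    rng = rng or np.random.default_rng(0)
    best = None
    for s in range(n_starts):
        x0 = np.zeros(k) if s == 0 else rng.normal(scale=jitter, size=k)
        try:
            res = minimize(negloglik, x0, method="BFGS", options={"gtol": gtol, "maxiter": 500})
        except (FloatingPointError, ValueError):
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None:
        return OptimResult(np.full(k, np.nan), np.inf, False, None, None, False, "all starts failed")

    se = vcov = None
    hessian_pd = False
    if compute_se:
        H = numeric_hessian(negloglik, best.x)
        try:
            # Positive definite iff Cholesky succeeds.
            np.linalg.cholesky(H)
            vcov = np.linalg.inv(H)
            se = np.sqrt(np.diag(vcov))
            hessian_pd = True
        except np.linalg.LinAlgError:
            hessian_pd = False
    # BFGS can stop with "precision loss" at a perfectly good optimum (flat
    # logit directions near boundaries); judge convergence by the gradient.
    jac = getattr(best, "jac", None)
    grad_norm = float(np.max(np.abs(jac))) if jac is not None else np.inf
    converged = bool(
        np.all(np.isfinite(best.x))
        and (best.success or grad_norm < 1e-3 * max(1.0, abs(best.fun)) or (compute_se and hessian_pd))
    )
    return OptimResult(
        x=best.x,
        fun=float(best.fun),
        converged=bool(converged),
        se=se,
        vcov=vcov,
        hessian_pd=hessian_pd,
        message=str(best.message),
    )
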