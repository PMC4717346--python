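"""AICc model ranking and Akaike weights.

AICc = -2 log L + 2K + 2K(K+1)/(n - K - 1), with n the effective sample size
(number of sites by standard occupancy practice).  Candidate models are
ranked by AICc; Delta_i = AICc_i - min AICc and the Akaike weight of model i
is w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["aicc", "aic", "akaike_weights", "rank_and_weight", "FitRecord"]


def aic(neg2loglik: float, K: int) -> float:
    return neg2loglik + 2 * K


def aicc(neg2loglik: float, K: int, n: int) -> float:
    """Small-sample corrected AIC; falls back to AIC with a warning if n <= K+1."""
    if n <= K + 1:
        warnings.warn(
            f"AICc correction undefined for n={n}, K={K}; returning plain AIC",
            stacklevel=2,
        )
        return aic(neg2loglik, K)
    return neg2loglik + 2 * K + 2 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights from a set of AICc (or Delta-AICc) values.

    Invariant to adding a constant to every value, so a printed Delta column
    can be passed directly.
    """
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2)
    return w / w.sum()


@dataclass(frozen=True)
class FitRecord:
    """Minimal comparison-ready summary of one fitted model."""

    label: str
    K: int
    neg2loglik: float
    converged: bool = True
    excluded: bool = False
    exclusion_reason: str = ""


def rank_and_weight(models: Sequence[FitRecord], n: int) -> pd.DataFrame:
    """Build a model-comparison table (label, K, AICc, Delta, weight, -2logL).

    Flagged/degenerate models are listed in the separate rows of the returned
    table's ``excluded`` attribute rather than ranked.  Ties in AICc break by
    smaller K, then label order, and set the ``tie`` column.
    """
    usable = [m for m in models if m.converged and not m.excluded]
    dropped = [m for m in models if not (m.converged and not m.excluded)]
    if not usable:
        raise ValueError("no converged, non-degenerate model to rank")
    rows = [
        {
            "model": m.label,
            "K": m.K,
            "AICc": aicc(m.neg2loglik, m.K, n),
            "AIC": aic(m.neg2loglik, m.K),
            "neg2loglik": m.neg2loglik,
        }
        for m in usable
    ]
    table = pd.DataFrame(rows).sort_values(
        ["AICc", "K", "model"], kind="stable"
    ).reset_index(drop=True)
    table["delta_AICc"] = table["AICc"] - table["AICc"].iloc[0]
    table["weight"] = akaike_weights(table["AICc"].to_numpy())
    table["tie"] = np.isclose(table["AICc"], table["AICc"].iloc[0], atol=1e-9) & (
        np.arange(len(table)) > 0
    )
    if table["tie"].any():
        table.loc[0, "tie"] = True
    table.attrs["n"] = n
    table.attrs["excluded"] = pd.DataFrame(
        [
            {"model": m.label, "K": m.K, "reason": m.exclusion_reason or "not converged"}
            for m in dropped
        ]
    )
    return table[["model", "K", "AICc", "delta_AICc", "weight", "neg2loglik", "AIC", "tie"]]
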