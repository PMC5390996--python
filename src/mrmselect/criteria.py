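"""Information criteria, delta values, Akaike weights, and model ranking.

With ``L`` the maximised Gaussian likelihood, ``k`` the parameter count
(slopes + intercept + residual variance) and ``m`` the number of rows the
model was fitted to:

    AIC  = -2 ln L + 2k
    AICc = AIC + 2k(k+1) / (m - k - 1)
    BIC  = -2 ln L + k ln m

For distance-based (MRM) fits ``m`` equals N = n(n-1)/2 pairwise distances,
although only n independent observations underlie them -- that inflated
sample size is exactly the mechanism the experiments expose.

Delta values and Akaike weights over a candidate set of R models:

    Delta_i = IC_i - min_r IC_r
    w_i     = exp(-Delta_i / 2) / sum_r exp(-Delta_r / 2)

The sample-size "corrected" variants AICd / AICcd / BICd substitute the
original node count n for m in the penalty and correction terms (the
log-likelihood is left as fitted).  They are experimental: the substitution
does not address the unknown degrees of freedom of distance vectors and is
shipped for illustration only, behind an explicit opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .regression import FittedModel

__all__ = [
    "BASE_CRITERIA",
    "EXPERIMENTAL_CRITERIA",
    "CriterionTable",
    "information_criterion",
    "rank_models",
]

BASE_CRITERIA: tuple[str, ...] = ("AIC", "AICc", "BIC")
EXPERIMENTAL_CRITERIA: tuple[str, ...] = ("AICd", "AICcd", "BICd")

# Each experimental variant reuses a base formula with m overridden by n.
_BASE_OF = {"AICd": "AIC", "AICcd": "AICc", "BICd": "BIC"}


def information_criterion(
    fit: FittedModel, criterion: str, m_override: int | None = None
) -> float:
    """Evaluate one information criterion for one fitted model.

    ``m_override`` replaces the fitted row count in the penalty/correction
    terms; the corrected variants require it (pass the original node count
    n).  The log-likelihood always stays as fitted.
    """
    if criterion in _BASE_OF:
        if m_override is None:
            raise ValueError(
                f"{criterion} requires m_override (the original node count n)"
            )
        criterion = _BASE_OF[criterion]
    elif criterion not in BASE_CRITERIA:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected one of "
            f"{BASE_CRITERIA + EXPERIMENTAL_CRITERIA}"
        )

    m = int(m_override) if m_override is not None else fit.m
    k = fit.k
    aic = -2.0 * fit.loglik + 2.0 * k
    if criterion == "AIC":
        return aic
    if criterion == "AICc":
        if m <= k + 1:
            raise ValueError(
                f"AICc undefined: need m > k + 1, got m = {m}, k = {k}"
            )
        return aic + 2.0 * k * (k + 1) / (m - k - 1)
    return -2.0 * fit.loglik + k * math.log(m)  # BIC


@dataclass(frozen=True)
class CriterionTable:
    """IC values, deltas and Akaike weights for one candidate set.

    ``best_index`` is the minimum-IC model; exact ties go to the model with
    the fewest parameters (parsimony), then the earliest index.
    """

    criterion: str
    values: np.ndarray
    deltas: np.ndarray
    weights: np.ndarray
    best_index: int
    m_used: int

    def __post_init__(self) -> None:
        for name in ("values", "deltas", "weights"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.deltas.min() != 0.0 or np.any(self.deltas < 0):
            raise ValueError("deltas must be non-negative with minimum exactly 0")
        if abs(float(self.weights.sum()) - 1.0) > 1e-12:
            raise ValueError("Akaike weights must sum to 1")


def rank_models(
    fits: Sequence[FittedModel],
    criterion: str,
    m_override: int | None = None,
) -> CriterionTable:
    """Rank a candidate set of fits under one criterion.

    All fits must have been computed on the same response rows (identical
    ``m``); otherwise their likelihoods are not comparable.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 candidate models to rank")
    row_counts = {fit.m for fit in fits}
    if len(row_counts) != 1:
        raise ValueError(
            f"fits computed on differing row counts {sorted(row_counts)}; "
            "IC values are not comparable"
        )
    values = np.array(
        [information_criterion(fit, criterion, m_override) for fit in fits]
    )
    deltas = values - values.min()
    raw = np.exp(-0.5 * deltas)
    weights = raw / raw.sum()

    best_value = values.min()
    tied = np.flatnonzero(values == best_value)
    ks = np.array([fits[i].k for i in tied])
    best_index = int(tied[int(np.argmin(ks))])

    m_used = int(m_override) if m_override is not None else fits[0].m
    return CriterionTable(
        criterion=criterion,
        values=values,
        deltas=deltas,
        weights=weights,
        best_index=best_index,
        m_used=m_used,
    )
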