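"""Ordinary least squares for node-based and distance-based (MRM) analysis.

Fitting an MRM model is computationally identical to fitting a multiple
regression on raw data -- only the rows differ (pairwise distances instead
of per-location observations).  This module therefore exposes a single
`fit_ols` used for both analysis types, plus the nested candidate-model
sets of the two simulation scenarios.

Conventions (matching R's ``lm`` / ``logLik`` / ``AIC``):

* Gaussian profile log-likelihood with the ML variance ``rss / m``:
  ``loglik = -(m/2) * (ln(2*pi) + ln(rss/m) + 1)``.
* Parameter count for information criteria includes the residual variance:
  ``k = |predictors| + 2`` (intercept + slopes + sigma^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PREDICTOR_NAMES",
    "CandidateModel",
    "FittedModel",
    "RankDeficientError",
    "DegenerateFitError",
    "fit_ols",
    "build_candidate_set",
    "CORRECT_MODEL_INDEX",
]

PREDICTOR_NAMES: tuple[str, ...] = ("x1", "x2", "x3", "x4", "x5")

#: Index of the data-generating model within each scenario's candidate list.
CORRECT_MODEL_INDEX: dict[str, int] = {"spurious": 0, "tapering": 2}

# Relative RSS floor below which the profile log-likelihood is unbounded.
_DEGENERATE_RSS_FACTOR = 1e-12


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is not of full column rank."""


class DegenerateFitError(ValueError):
    """RSS is (numerically) zero, so the Gaussian log-likelihood diverges."""


@dataclass(frozen=True)
class CandidateModel:
    """A candidate regression model: an ordered predictor subset + intercept."""

    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        preds = tuple(self.predictors)
        if len(preds) == 0:
            raise ValueError("candidate models must contain at least one predictor")
        if len(set(preds)) != len(preds):
            raise ValueError(f"duplicate predictors in {preds}")
        unknown = [p for p in preds if p not in PREDICTOR_NAMES]
        if unknown:
            raise ValueError(f"unknown predictors {unknown}; expected {PREDICTOR_NAMES}")
        object.__setattr__(self, "predictors", preds)

    @property
    def label(self) -> str:
        return "+".join(self.predictors)

    @property
    def size(self) -> int:
        return len(self.predictors)

    def column_indices(self) -> list[int]:
        """Indices into an (m x 5) predictor matrix ordered x1..x5."""
        return [PREDICTOR_NAMES.index(p) for p in self.predictors]


@dataclass(frozen=True)
class FittedModel:
    """One OLS fit with the quantities the information criteria need.

    ``coefficients`` holds the intercept first, then slopes in the model's
    predictor order.  ``k`` counts the intercept, the slopes, and the
    residual variance.
    """

    model: CandidateModel | None
    coefficients: np.ndarray
    rss: float
    loglik: float
    m: int
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )
        if self.rss < 0:
            raise ValueError(f"rss must be non-negative, got {self.rss}")
        if self.m <= self.k:
            raise ValueError(f"need m > k, got m = {self.m}, k = {self.k}")


def _profile_loglik(rss: float, m: int) -> float:
    return -(m / 2.0) * (math.log(2.0 * math.pi) + math.log(rss / m) + 1.0)


def fit_ols(
    response: np.ndarray,
    predictors: np.ndarray,
    model: CandidateModel | None,
) -> FittedModel:
    """Fit one candidate model by ordinary least squares.

    Parameters
    ----------
    response
        Length-m vector (node observations of y, or pairwise distances D_y).
    predictors
        m x 5 matrix with columns x1..x5 (or D_x1..D_x5); the model picks
        its columns out of it.
    model
        The candidate to fit.  ``None`` fits the intercept-only model, which
        is not a member of any candidate set but is useful for testing.

    Raises
    ------
    RankDeficientError
        If the design matrix is rank deficient (names the collinear columns).
    DegenerateFitError
        If the fit is numerically perfect, making the profile log-likelihood
        unbounded.
    """
    y = np.asarray(response, dtype=float).ravel()
    x_all = np.asarray(predictors, dtype=float)
    if x_all.ndim != 2:
        raise ValueError("predictors must be a 2-D matrix")
    if x_all.shape[0] != y.shape[0]:
        raise ValueError(
            f"row mismatch: response has {y.shape[0]} rows, "
            f"predictors {x_all.shape[0]}"
        )
    if model is None:
        design = np.ones((y.shape[0], 1))
        names = ["intercept"]
    else:
        cols = model.column_indices()
        if x_all.shape[1] <= max(cols):
            raise ValueError(
                f"predictor matrix has {x_all.shape[1]} columns; "
                f"model {model.label} needs column {max(cols) + 1}"
            )
        design = np.column_stack([np.ones(y.shape[0]), x_all[:, cols]])
        names = ["intercept", *model.predictors]

    m, p = design.shape
    k = p + 1  # + residual variance
    if m <= k:
        raise ValueError(f"need m > k = {k} rows to fit {names}, got m = {m}")

    beta, rss_arr, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        collinear = _collinear_columns(design, names)
        raise RankDeficientError(
            f"design matrix rank {rank} < {p}; collinear columns: {collinear}"
        )
    if rss_arr.size:
        rss = float(rss_arr[0])
    else:  # pragma: no cover - full-rank overdetermined systems fill rss_arr
        rss = float(np.sum((y - design @ beta) ** 2))

    floor = _DEGENERATE_RSS_FACTOR * m * float(np.var(y))
    if rss <= floor:
        raise DegenerateFitError(
            f"degenerate fit for {names}: rss = {rss:.3e} <= {floor:.3e}; "
            "profile log-likelihood is unbounded"
        )
    return FittedModel(
        model=model,
        coefficients=beta,
        rss=rss,
        loglik=_profile_loglik(rss, m),
        m=m,
        k=k,
    )


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name the design columns implicated in a rank deficiency."""
    import scipy.linalg

    r_mat, pivots = scipy.linalg.qr(design, mode="r", pivoting=True)
    r_diag = np.abs(np.diag(r_mat))
    tol = r_diag.max() * max(design.shape) * np.finfo(float).eps
    return [
        names[pivots[i]]
        for i in range(len(names))
        if i >= len(r_diag) or r_diag[i] <= tol
    ]


def build_candidate_set(scenario_id: str) -> list[CandidateModel]:
    """The five nested candidate models of a scenario.

    Both scenarios use the nested sequence {x1} subset {x1,x2} subset ...
    subset {x1..x5}, built by sequentially adding predictors to the smallest
    model.  In the ``spurious`` scenario the first model is correct and x2..x5
    are spurious; in the ``tapering`` scenario the third model {x1,x2,x3} is
    correct, the first two are underfitted and the last two overfitted.
    """
    if scenario_id not in CORRECT_MODEL_INDEX:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; "
            f"expected one of {sorted(CORRECT_MODEL_INDEX)}"
        )
    return [CandidateModel(PREDICTOR_NAMES[: size + 1]) for size in range(5)]
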