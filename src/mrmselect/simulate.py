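"""Synthetic node-based datasets and their pairwise-distance transforms.

The simulation world is deliberately idealised: six jointly normal variables
(one response ``y``, five predictors ``x1``..``x5``) with zero means, unit
variances, a prescribed correlation between the response and each predictor,
and mutually independent predictors -- no collinearity and no spatial
autocorrelation.  Two named scenarios are built in:

``spurious``
    one meaningful predictor (``rho_xy = 0.60``) plus four null predictors;
    the recalibrated high-correlation set uses ``rho_xy = 0.80``.
``tapering``
    three meaningful predictors with tapering correlations
    ``(0.30, 0.25, 0.20)`` plus two null predictors; the high-correlation
    set uses ``(0.58, 0.52, 0.47)``.

Each node dataset can be transformed into vectors of the N = n(n-1)/2
pairwise Euclidean distances per variable (for scalars, the absolute
difference).  Regression on those vectors is the "distance-based" (MRM)
analysis whose model-selection behaviour the experiment module studies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COLUMNS",
    "SCENARIO_DEFAULTS",
    "ScenarioSpec",
    "NodeDataset",
    "DistanceDataset",
    "make_scenario",
    "build_correlation_matrix",
    "generate_node_data",
    "to_distance_vectors",
    "generate_hc_distance_data",
    "write_node_csv",
    "write_distance_csv",
]

#: Column order of every dataset matrix: response first, then predictors.
COLUMNS: tuple[str, ...] = ("y", "x1", "x2", "x3", "x4", "x5")

N_PREDICTORS = 5

#: Expected response-predictor correlations defining each scenario.
#: ``rho_node`` parameterises the node-scale draws (and, after distance
#: transformation, the low-correlation distance set); ``rho_hc`` is the
#: recalibrated node-scale vector whose *distance-scale* correlations match
#: the node-scale ones of ``rho_node``.
SCENARIO_DEFAULTS: dict[str, dict[str, tuple[float, ...]]] = {
    "spurious": {
        "rho_node": (0.60, 0.0, 0.0, 0.0, 0.0),
        "rho_hc": (0.80, 0.0, 0.0, 0.0, 0.0),
    },
    "tapering": {
        "rho_node": (0.30, 0.25, 0.20, 0.0, 0.0),
        "rho_hc": (0.58, 0.52, 0.47, 0.0, 0.0),
    },
}

# Role codes for RNG substream derivation: the low-correlation node draw and
# the high-correlation node draw of a replicate are independent streams.
_ROLE_LC = 0
_ROLE_HC = 1
_SCENARIO_CODE = {"spurious": 0, "tapering": 1}


def build_correlation_matrix(rho: "np.typing.ArrayLike") -> np.ndarray:
    """Assemble the 6x6 correlation matrix for one scenario.

    Parameters
    ----------
    rho
        Length-5 vector of expected correlations between the response and
        each predictor.  Predictors are mutually uncorrelated, so the matrix
        has ones on the diagonal, ``rho`` in the response row/column and
        zeros elsewhere.

    Returns
    -------
    numpy.ndarray
        Symmetric positive-definite correlation matrix, response first.

    Raises
    ------
    ValueError
        If any ``|rho_i| >= 1`` or the implied matrix is not positive
        definite (for this arrow structure, iff ``sum(rho_i^2) >= 1``).
    """
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (N_PREDICTORS,):
        raise ValueError(
            f"rho must have length {N_PREDICTORS}, got shape {rho.shape}"
        )
    if np.any(np.abs(rho) >= 1.0):
        raise ValueError(f"each |rho_i| must be < 1, got rho = {tuple(rho)}")
    ssq = float(np.sum(rho**2))
    if ssq >= 1.0:
        raise ValueError(
            "correlation matrix not positive definite: "
            f"sum(rho^2) = {ssq:.4f} >= 1 for rho = {tuple(rho)}"
        )
    corr = np.eye(1 + N_PREDICTORS)
    corr[0, 1:] = rho
    corr[1:, 0] = rho
    return corr


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation condition: correlation structure, size, seed.

    ``rho_node`` drives the node-based data (and the low-correlation
    distance set derived from it); ``rho_hc`` drives an independent draw
    retained only in distance form (the high-correlation distance set).
    """

    scenario_id: str
    rho_node: tuple[float, ...]
    rho_hc: tuple[float, ...]
    n: int
    n_reps: int
    master_seed: int

    def __post_init__(self) -> None:
        if self.scenario_id not in _SCENARIO_CODE:
            raise ValueError(
                f"unknown scenario {self.scenario_id!r}; "
                f"expected one of {sorted(_SCENARIO_CODE)}"
            )
        object.__setattr__(self, "rho_node", tuple(float(r) for r in self.rho_node))
        object.__setattr__(self, "rho_hc", tuple(float(r) for r in self.rho_hc))
        # validates length and positive definiteness
        build_correlation_matrix(self.rho_node)
        build_correlation_matrix(self.rho_hc)
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")

    @property
    def n_pairs(self) -> int:
        """Number of unique pairwise distances, N = n(n-1)/2."""
        return self.n * (self.n - 1) // 2


def make_scenario(
    scenario_id: str,
    n: int,
    n_reps: int = 1000,
    master_seed: int = 0,
    rho_node: tuple[float, ...] | None = None,
    rho_hc: tuple[float, ...] | None = None,
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec`, filling correlations from the defaults.

    Explicit ``rho_node`` / ``rho_hc`` override the scenario's built-in
    correlation vectors (useful for calibration experiments).
    """
    try:
        defaults = SCENARIO_DEFAULTS[scenario_id]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; "
            f"expected one of {sorted(SCENARIO_DEFAULTS)}"
        ) from None
    return ScenarioSpec(
        scenario_id=scenario_id,
        rho_node=tuple(rho_node) if rho_node is not None else defaults["rho_node"],
        rho_hc=tuple(rho_hc) if rho_hc is not None else defaults["rho_hc"],
        n=n,
        n_reps=n_reps,
        master_seed=master_seed,
    )


@dataclass(frozen=True)
class NodeDataset:
    """Per-location observations: an n x 6 matrix, columns (y, x1..x5)."""

    values: np.ndarray
    replicate_index: int
    seed_used: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(COLUMNS):
            raise ValueError(f"values must be n x {len(COLUMNS)}, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("node data contains non-finite entries")
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def response(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def predictors(self) -> np.ndarray:
        return self.values[:, 1:]


@dataclass(frozen=True)
class DistanceDataset:
    """Pairwise-distance vectors: an N x 6 matrix, N = n(n-1)/2.

    ``pair_index`` holds the 0-based source-row pairs (i, j), i < j, in
    lexicographic order -- the lower triangle of each distance matrix read
    column-consistently.  ``provenance`` records whether the vectors came
    from the low-correlation node data ("LC") or the recalibrated
    high-correlation draw ("HC").
    """

    values: np.ndarray
    pair_index: np.ndarray  # (N, 2) int array, i < j
    provenance: str  # "LC" or "HC"
    source_n: int
    replicate_index: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        pair_index = np.asarray(self.pair_index, dtype=int)
        n = int(self.source_n)
        n_pairs = n * (n - 1) // 2
        if values.shape != (n_pairs, len(COLUMNS)):
            raise ValueError(
                f"expected {n_pairs} x {len(COLUMNS)} distance matrix for "
                f"n = {n}, got {values.shape}"
            )
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        if pair_index.shape != (n_pairs, 2):
            raise ValueError("pair_index must have one (i, j) row per distance")
        if self.provenance not in ("LC", "HC"):
            raise ValueError(f"provenance must be 'LC' or 'HC', got {self.provenance!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pair_index", pair_index)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def response(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def predictors(self) -> np.ndarray:
        return self.values[:, 1:]


def _substream(spec: ScenarioSpec, replicate_index: int, role: int) -> np.random.SeedSequence:
    """Deterministic, mutually independent RNG substream per (replicate, role).

    The spawn key encodes scenario, sample size, replicate and role, so the
    LC and HC draws of a replicate are independent and adding replicates or
    conditions never perturbs earlier ones.
    """
    if not 0 <= replicate_index < spec.n_reps:
        raise ValueError(
            f"replicate_index {replicate_index} outside [0, {spec.n_reps})"
        )
    return np.random.SeedSequence(
        entropy=spec.master_seed,
        spawn_key=(_SCENARIO_CODE[spec.scenario_id], spec.n, replicate_index, role),
    )


def _draw_node_values(
    rho: tuple[float, ...], n: int, rng: np.random.Generator
) -> np.ndarray:
    # Cholesky factor of the correlation matrix applied to iid N(0, 1) draws;
    # distributionally equivalent to MASS::mvrnorm with this covariance.
    corr = build_correlation_matrix(rho)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, corr.shape[0]))
    return z @ chol.T


def generate_node_data(spec: ScenarioSpec, replicate_index: int) -> NodeDataset:
    """Draw one node-based replicate from the scenario's ``rho_node``.

    Deterministic given ``(master_seed, scenario, n, replicate_index)``.
    """
    seed_seq = _substream(spec, replicate_index, _ROLE_LC)
    rng = np.random.default_rng(seed_seq)
    values = _draw_node_values(spec.rho_node, spec.n, rng)
    return NodeDataset(
        values=values,
        replicate_index=replicate_index,
        seed_used=int(seed_seq.generate_state(1)[0]),
    )


def to_distance_vectors(node: NodeDataset, provenance: str = "LC") -> DistanceDataset:
    """Transform node data into pairwise-distance vectors, column by column.

    For a single variable the Euclidean distance between two observations
    reduces to the absolute difference ``|v_j - v_i|``.  Rows are the
    n(n-1)/2 unordered pairs (i, j), i < j, sorted by i then j.
    """
    n = node.n
    if n < 2:
        raise ValueError("need at least 2 rows to form pairwise distances")
    idx_i, idx_j = np.triu_indices(n, k=1)
    values = np.abs(node.values[idx_j, :] - node.values[idx_i, :])
    return DistanceDataset(
        values=values,
        pair_index=np.column_stack([idx_i, idx_j]),
        provenance=provenance,
        source_n=n,
        replicate_index=node.replicate_index,
    )


def generate_hc_distance_data(spec: ScenarioSpec, replicate_index: int) -> DistanceDataset:
    """Distance vectors from an independent draw at the recalibrated ``rho_hc``.

    A fresh node dataset is drawn from ``rho_hc`` on an RNG substream
    independent of the replicate's low-correlation draw, distance-transformed,
    and only the distance vectors are retained.
    """
    seed_seq = _substream(spec, replicate_index, _ROLE_HC)
    rng = np.random.default_rng(seed_seq)
    values = _draw_node_values(spec.rho_hc, spec.n, rng)
    node = NodeDataset(
        values=values,
        replicate_index=replicate_index,
        seed_used=int(seed_seq.generate_state(1)[0]),
    )
    return to_distance_vectors(node, provenance="HC")


def write_node_csv(node: NodeDataset, path_or_buffer) -> None:
    """Serialize a node dataset as CSV with header (y, x1..x5)."""
    _write_csv(path_or_buffer, COLUMNS, node.values)


def write_distance_csv(dist: DistanceDataset, path_or_buffer) -> None:
    """Serialize distance vectors as CSV with 1-based source-pair columns i, j."""
    header = ("i", "j") + COLUMNS
    body = np.column_stack([dist.pair_index + 1, dist.values])
    _write_csv(path_or_buffer, header, body, int_cols=2)


def _write_csv(path_or_buffer, header, matrix, int_cols: int = 0) -> None:
    def _dump(fh: io.TextIOBase) -> None:
        fh.write(",".join(header) + "\n")
        for row in matrix:
            cells = [str(int(v)) for v in row[:int_cols]]
            cells += [format(float(v), ".17g") for v in row[int_cols:]]
            fh.write(",".join(cells) + "\n")

    if hasattr(path_or_buffer, "write"):
        _dump(path_or_buffer)
    else:
        with open(path_or_buffer, "w", encoding="utf-8", newline="\n") as fh:
            _dump(fh)
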