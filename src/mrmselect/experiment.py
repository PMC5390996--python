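"""Monte Carlo experiment: scenarios x sample sizes x analyses x criteria.

The study design: for each scenario ("spurious": one meaningful predictor
plus four null ones; "tapering": three progressively weaker meaningful
predictors plus two null ones) and each sample size n in {30, 100, 300},
draw ``n_reps`` replicate node datasets, analyse each replicate three ways --

``node``
    multiple regression on the raw per-location observations (benchmark),
``dist_lc``
    MRM on the pairwise-distance vectors of that same node data
    (low-correlation distance set),
``dist_hc``
    MRM on distance vectors from an independent draw recalibrated so the
    *distance-scale* correlation matches the node-scale one
    (high-correlation distance set),

-- rank the five nested candidate models under each criterion, and aggregate
the proportion of replicates in which each candidate is selected as best.
Per-replicate empirical correlations between the response and the meaningful
predictors are summarised alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from . import simulate as _simulate
from .criteria import BASE_CRITERIA, EXPERIMENTAL_CRITERIA, CriterionTable, rank_models
from .regression import CORRECT_MODEL_INDEX, build_candidate_set, fit_ols
from .simulate import (
    SCENARIO_DEFAULTS,
    ScenarioSpec,
    generate_hc_distance_data,
    generate_node_data,
    make_scenario,
    to_distance_vectors,
)

__all__ = [
    "ANALYSIS_TYPES",
    "MEANINGFUL_PREDICTORS",
    "ExperimentConfig",
    "ReplicateResult",
    "SelectionSummary",
    "CorrelationSummary",
    "ExperimentResult",
    "run_replicate",
    "run_experiment",
    "summarize_correlations",
]

ANALYSIS_TYPES: tuple[str, ...] = ("node", "dist_lc", "dist_hc")

#: Predictors with a non-zero expected correlation to the response.
MEANINGFUL_PREDICTORS: dict[str, tuple[str, ...]] = {
    "spurious": ("x1",),
    "tapering": ("x1", "x2", "x3"),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment grid; the defaults reproduce the published design:

    2 scenarios x 3 sample sizes x 3 analysis types x 3 criteria x 1000
    replicates.
    """

    scenarios: tuple[str, ...] = ("spurious", "tapering")
    sample_sizes: tuple[int, ...] = (30, 100, 300)
    n_reps: int = 1000
    criteria: tuple[str, ...] = BASE_CRITERIA
    analysis_types: tuple[str, ...] = ANALYSIS_TYPES
    master_seed: int = 0
    experimental_corrected: bool = False
    # optional overrides of the scenario correlation vectors; only valid
    # when a single scenario is selected
    rho_node: tuple[float, ...] | None = None
    rho_hc: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", tuple(self.scenarios))
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "analysis_types", tuple(self.analysis_types))
        if self.rho_node is not None:
            object.__setattr__(self, "rho_node", tuple(float(r) for r in self.rho_node))
        if self.rho_hc is not None:
            object.__setattr__(self, "rho_hc", tuple(float(r) for r in self.rho_hc))

        unknown = set(self.scenarios) - set(SCENARIO_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown scenarios {sorted(unknown)}")
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not self.sample_sizes or any(n < 4 for n in self.sample_sizes):
            raise ValueError(f"sample sizes must be >= 4, got {self.sample_sizes}")
        allowed = set(BASE_CRITERIA) | set(EXPERIMENTAL_CRITERIA)
        bad = set(self.criteria) - allowed
        if bad:
            raise ValueError(f"unknown criteria {sorted(bad)}")
        if not self.experimental_corrected and set(self.criteria) & set(
            EXPERIMENTAL_CRITERIA
        ):
            raise ValueError(
                "corrected criteria (AICd/AICcd/BICd) require "
                "experimental_corrected=True"
            )
        bad_analysis = set(self.analysis_types) - set(ANALYSIS_TYPES)
        if bad_analysis:
            raise ValueError(f"unknown analysis types {sorted(bad_analysis)}")
        if (self.rho_node is not None or self.rho_hc is not None) and len(
            self.scenarios
        ) != 1:
            raise ValueError(
                "rho_node / rho_hc overrides require exactly one scenario"
            )
        for rho in (self.rho_node, self.rho_hc):
            if rho is not None:
                _simulate.build_correlation_matrix(rho)

    def scenario_spec(self, scenario_id: str, n: int) -> ScenarioSpec:
        return make_scenario(
            scenario_id,
            n=n,
            n_reps=self.n_reps,
            master_seed=self.master_seed,
            rho_node=self.rho_node,
            rho_hc=self.rho_hc,
        )


@dataclass(frozen=True)
class ReplicateResult:
    """All tables and correlations produced by one replicate."""

    replicate_index: int
    tables: dict[tuple[str, str], CriterionTable]  # (analysis_type, criterion)
    correlations: dict[str, np.ndarray]  # analysis_type -> cor(y, meaningful x)


@dataclass(frozen=True)
class SelectionSummary:
    """Selection proportions over the candidate set for one condition."""

    scenario: str
    n: int
    analysis_type: str
    criterion: str
    model_labels: tuple[str, ...]
    counts: tuple[int, ...]
    proportions: tuple[float, ...]
    correct_index: int
    correct_proportion: float
    grouped: dict[str, float] | None = None  # tapering: under/correct/overfit


@dataclass(frozen=True)
class CorrelationSummary:
    """Mean and sd over replicates of cor(response, meaningful predictor)."""

    scenario: str
    n: int
    analysis_type: str
    predictors: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    selection_summaries: list[SelectionSummary]
    correlation_summaries: list[CorrelationSummary]
    replicate_rows: pd.DataFrame | None = None

    def selection_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.selection_summaries:
            for label, count, prop in zip(s.model_labels, s.counts, s.proportions):
                rows.append(
                    {
                        "scenario": s.scenario,
                        "n": s.n,
                        "analysis_type": s.analysis_type,
                        "criterion": s.criterion,
                        "model_label": label,
                        "count": count,
                        "proportion": prop,
                    }
                )
        return pd.DataFrame(rows)

    def correlation_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.correlation_summaries:
            for pred, mean, sd in zip(c.predictors, c.means, c.sds):
                rows.append(
                    {
                        "scenario": c.scenario,
                        "n": c.n,
                        "analysis_type": c.analysis_type,
                        "predictor": pred,
                        "mean": mean,
                        "sd": sd,
                    }
                )
        return pd.DataFrame(rows)

    def get_selection(
        self, scenario: str, n: int, analysis_type: str, criterion: str
    ) -> SelectionSummary:
        for s in self.selection_summaries:
            if (s.scenario, s.n, s.analysis_type, s.criterion) == (
                scenario,
                n,
                analysis_type,
                criterion,
            ):
                return s
        raise KeyError((scenario, n, analysis_type, criterion))

    def get_correlation(
        self, scenario: str, n: int, analysis_type: str
    ) -> CorrelationSummary:
        for c in self.correlation_summaries:
            if (c.scenario, c.n, c.analysis_type) == (scenario, n, analysis_type):
                return c
        raise KeyError((scenario, n, analysis_type))


def _meaningful_correlations(values: np.ndarray, scenario_id: str) -> np.ndarray:
    """cor(column 0, each meaningful predictor column) of a dataset matrix."""
    idx = [
        _simulate.COLUMNS.index(p) for p in MEANINGFUL_PREDICTORS[scenario_id]
    ]
    corr = np.corrcoef(values[:, [0, *idx]], rowvar=False)
    return corr[0, 1:]


def run_replicate(
    spec: ScenarioSpec,
    replicate_index: int,
    analysis_types: Iterable[str] = ANALYSIS_TYPES,
    criteria: Iterable[str] = BASE_CRITERIA,
) -> ReplicateResult:
    """Generate and analyse a single replicate.

    The node dataset drawn from ``rho_node`` underlies both the ``node``
    analysis and the ``dist_lc`` analysis; ``dist_hc`` uses an independent
    draw from ``rho_hc`` retained in distance form only.  Each analysis fits
    the five nested candidates and ranks them under every criterion; the
    corrected variants feed the original node count n into the penalties.
    """
    analysis_types = tuple(analysis_types)
    criteria = tuple(criteria)
    candidates = build_candidate_set(spec.scenario_id)

    datasets: dict[str, np.ndarray] = {}
    node = None
    if "node" in analysis_types or "dist_lc" in analysis_types:
        node = generate_node_data(spec, replicate_index)
    if "node" in analysis_types:
        datasets["node"] = node.values
    if "dist_lc" in analysis_types:
        datasets["dist_lc"] = to_distance_vectors(node).values
    if "dist_hc" in analysis_types:
        datasets["dist_hc"] = generate_hc_distance_data(spec, replicate_index).values

    tables: dict[tuple[str, str], CriterionTable] = {}
    correlations: dict[str, np.ndarray] = {}
    for analysis in analysis_types:
        values = datasets[analysis]
        correlations[analysis] = _meaningful_correlations(values, spec.scenario_id)
        fits = [fit_ols(values[:, 0], values[:, 1:], mdl) for mdl in candidates]
        for criterion in criteria:
            m_override = spec.n if criterion in EXPERIMENTAL_CRITERIA else None
            tables[(analysis, criterion)] = rank_models(fits, criterion, m_override)
    return ReplicateResult(
        replicate_index=replicate_index, tables=tables, correlations=correlations
    )


def run_experiment(
    config: ExperimentConfig,
    keep_replicates: bool = False,
    progress: Callable[[str], None] | None = None,
) -> ExperimentResult:
    """Run the full grid of conditions and aggregate over replicates.

    Deterministic given ``config.master_seed``: every replicate draws from
    its own derived RNG substream, so results do not depend on the order in
    which conditions are evaluated.
    """
    selection: list[SelectionSummary] = []
    correlation: list[CorrelationSummary] = []
    replicate_rows: list[dict] = []

    for scenario_id in config.scenarios:
        correct_idx = CORRECT_MODEL_INDEX[scenario_id]
        for n in config.sample_sizes:
            spec = config.scenario_spec(scenario_id, n)
            labels = tuple(m.label for m in build_candidate_set(scenario_id))
            counts = {
                (a, c): np.zeros(len(labels), dtype=int)
                for a in config.analysis_types
                for c in config.criteria
            }
            cors = {a: [] for a in config.analysis_types}

            for rep in range(config.n_reps):
                result = run_replicate(
                    spec, rep, config.analysis_types, config.criteria
                )
                for (analysis, criterion), table in result.tables.items():
                    counts[(analysis, criterion)][table.best_index] += 1
                    if keep_replicates:
                        for j, label in enumerate(labels):
                            replicate_rows.append(
                                {
                                    "scenario": scenario_id,
                                    "n": n,
                                    "replicate": rep,
                                    "analysis_type": analysis,
                                    "criterion": criterion,
                                    "model_label": label,
                                    "ic_value": table.values[j],
                                    "delta": table.deltas[j],
                                    "weight": table.weights[j],
                                    "selected_flag": int(j == table.best_index),
                                }
                            )
                for analysis, cor in result.correlations.items():
                    cors[analysis].append(cor)

            for (analysis, criterion), cnt in counts.items():
                props = cnt / config.n_reps
                grouped = None
                if scenario_id == "tapering":
                    grouped = {
                        "underfit": float(props[:correct_idx].sum()),
                        "correct": float(props[correct_idx]),
                        "overfit": float(props[correct_idx + 1 :].sum()),
                    }
                selection.append(
                    SelectionSummary(
                        scenario=scenario_id,
                        n=n,
                        analysis_type=analysis,
                        criterion=criterion,
                        model_labels=labels,
                        counts=tuple(int(c) for c in cnt),
                        proportions=tuple(float(p) for p in props),
                        correct_index=correct_idx,
                        correct_proportion=float(props[correct_idx]),
                        grouped=grouped,
                    )
                )
            for analysis in config.analysis_types:
                arr = np.asarray(cors[analysis])
                correlation.append(
                    CorrelationSummary(
                        scenario=scenario_id,
                        n=n,
                        analysis_type=analysis,
                        predictors=MEANINGFUL_PREDICTORS[scenario_id],
                        means=tuple(float(v) for v in arr.mean(axis=0)),
                        sds=tuple(float(v) for v in arr.std(axis=0, ddof=1)),
                    )
                )
            if progress is not None:
                tally = {
                    f"{a}/{c}": counts[(a, c)].tolist()
                    for a in config.analysis_types
                    for c in config.criteria
                }
                progress(
                    f"{scenario_id} n={n}: completed {config.n_reps} replicates; "
                    f"selection tallies {tally}"
                )

    return ExperimentResult(
        config=config,
        selection_summaries=selection,
        correlation_summaries=correlation,
        replicate_rows=pd.DataFrame(replicate_rows) if keep_replicates else None,
    )


def summarize_correlations(config: ExperimentConfig) -> list[CorrelationSummary]:
    """Correlation summaries only -- skips all model fitting.

    Useful for the calibration checks (mean and sd of the empirical
    correlation between the response and each meaningful predictor, per
    analysis type), which do not require OLS.
    """
    out: list[CorrelationSummary] = []
    for scenario_id in config.scenarios:
        for n in config.sample_sizes:
            spec = config.scenario_spec(scenario_id, n)
            cors = {a: [] for a in config.analysis_types}
            for rep in range(config.n_reps):
                node = None
                if "node" in config.analysis_types or "dist_lc" in config.analysis_types:
                    node = generate_node_data(spec, rep)
                if "node" in config.analysis_types:
                    cors["node"].append(
                        _meaningful_correlations(node.values, scenario_id)
                    )
                if "dist_lc" in config.analysis_types:
                    cors["dist_lc"].append(
                        _meaningful_correlations(
                            to_distance_vectors(node).values, scenario_id
                        )
                    )
                if "dist_hc" in config.analysis_types:
                    cors["dist_hc"].append(
                        _meaningful_correlations(
                            generate_hc_distance_data(spec, rep).values, scenario_id
                        )
                    )
            for analysis in config.analysis_types:
                arr = np.asarray(cors[analysis])
                out.append(
                    CorrelationSummary(
                        scenario=scenario_id,
                        n=n,
                        analysis_type=analysis,
                        predictors=MEANINGFUL_PREDICTORS[scenario_id],
                        means=tuple(float(v) for v in arr.mean(axis=0)),
                        sds=tuple(float(v) for v in arr.std(axis=0, ddof=1)),
                    )
                )
    return out
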