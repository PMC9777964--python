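"""Parameter calibration by differential evolution, and validation loops.

Calibration follows the standard validation protocol for stress-test data:
initialise the model at its flat-driver steady state, pre-roll past the first
sample to wash out transients, simulate through the canonical 20-min stress
episode, sample the solution on the subject's grid, and score the fit with
the mean-normalised spline cost.  A self-contained rand/1/bin differential
evolution (DE) minimiser searches the bounded free-parameter space; the
model's default parameter vector is injected as one initial population
member, so an optimised cost can never exceed the default-parameter cost.

The repeated-run protocol mirrors common practice: several independent DE
repeats per dataset (distinct seeds), per-dataset mean +/- SD and best single
cost, and an overall model score equal to the mean of the per-dataset means.
:func:`generalization_matrix` evaluates saved parameter sets across all
subjects of a cohort to probe whether a calibrated model transfers between
individuals and groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .cost import CostBreakdown, CostConvention, CostError, sse_cost
from .datasets import Cohort, SubjectRecord, cohort_mean
from .desolver import IntegrationError, integrate, sample
from .models import (
    Drivers,
    ModelSpec,
    SteadyStateError,
    StressProtocol,
    canonical_tsst_protocol,
    steady_state,
)

__all__ = [
    "OptimizationRun",
    "ValidationReport",
    "DatasetResult",
    "BatchResult",
    "GeneralizationResult",
    "EvaluationConfig",
    "ValidationProtocol",
    "differential_evolution",
    "evaluate_params",
    "simulate_for_subject",
    "run_validation",
    "batch_over_subjects",
    "generalization_matrix",
    "rank_models",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# differential evolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizationRun:
    """One complete optimiser repeat."""

    run_id: str
    algorithm: str
    seed: int
    popsize: int
    generations: int
    best_params: dict[str, float]
    best_cost: float
    trace: np.ndarray  # best-so-far cost after each generation (incl. init)

    @property
    def best_vector(self) -> np.ndarray:
        return np.array(list(self.best_params.values()))


def differential_evolution(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    popsize: int = 10,
    mutation: tuple[float, float] = (0.5, 1.0),
    recombination: float = 0.7,
    generations: int = 100,
    seed: int | None = None,
    tol: float = 0.0,
    x0: np.ndarray | None = None,
    param_names: Sequence[str] | None = None,
    run_id: str = "de",
) -> OptimizationRun:
    """Minimise ``objective`` over a box with rand/1/bin differential evolution.

    The population is initialised uniformly within ``bounds`` from ``seed``
    (member 0 replaced by ``x0`` when given).  Each generation builds, for
    every member, a mutant ``a + F*(b - c)`` from three distinct other
    members with the dither factor ``F`` drawn uniformly from ``mutation``,
    applies binomial crossover with probability ``recombination`` (one
    coordinate always crosses), clips to bounds, and keeps the trial iff its
    cost does not exceed the parent's (greedy selection).  Non-finite
    objective values are treated as +inf and logged.  Terminates at the
    generation budget or when the population cost spread drops below
    ``tol``.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a sequence of (lower, upper) pairs")
    if not np.all(np.isfinite(bounds)):
        raise ValueError("bounds must be finite")
    if np.any(bounds[:, 0] >= bounds[:, 1]):
        raise ValueError("each lower bound must be below its upper bound")
    if popsize < 4:
        raise ValueError("popsize must be >= 4 for rand/1 mutation")
    ndim = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(seed)

    def _eval(x: np.ndarray) -> float:
        v = objective(x)
        if not np.isfinite(v):
            logger.debug("non-finite objective at %s; rejecting candidate", x)
            return np.inf
        return float(v)

    pop = lo + rng.uniform(size=(popsize, ndim)) * (hi - lo)
    if x0 is not None:
        pop[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    costs = np.array([_eval(x) for x in pop])

    trace = [float(costs.min())]
    gens_done = 0
    for _ in range(generations):
        for i in range(popsize):
            idx = [j for j in range(popsize) if j != i]
            a, b, c = rng.choice(idx, size=3, replace=False)
            F = rng.uniform(*mutation)
            mutant = np.clip(pop[a] + F * (pop[b] - pop[c]), lo, hi)
            cross = rng.uniform(size=ndim) < recombination
            cross[rng.integers(ndim)] = True
            trial = np.where(cross, mutant, pop[i])
            trial_cost = _eval(trial)
            if trial_cost <= costs[i]:
                pop[i] = trial
                costs[i] = trial_cost
        gens_done += 1
        trace.append(float(costs.min()))
        finite = costs[np.isfinite(costs)]
        if finite.size == popsize and np.ptp(finite) < tol:
            break

    best = int(np.argmin(costs))
    names = list(param_names) if param_names is not None else [
        f"x{i}" for i in range(ndim)
    ]
    return OptimizationRun(
        run_id=run_id,
        algorithm="de/rand/1/bin",
        seed=-1 if seed is None else int(seed),
        popsize=popsize,
        generations=gens_done,
        best_params=dict(zip(names, pop[best])),
        best_cost=float(costs[best]),
        trace=np.array(trace),
    )


# ---------------------------------------------------------------------------
# objective: simulate a subject protocol and score it
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationConfig:
    """How a parameter set is turned into a cost on one subject.

    ``burn_in`` minutes are simulated before the subject's first sample so
    that the trajectory has settled onto the driven attractor before scoring
    starts (default one full day); ``stress`` is the acute episode aligned to
    t = 0 (default the canonical 20-min test).
    """

    convention: CostConvention = field(default_factory=CostConvention)
    stress: StressProtocol = field(default_factory=canonical_tsst_protocol)
    burn_in: float = 1440.0
    rtol: float = 1e-6
    atol: float = 1e-9


def simulate_for_subject(
    model: ModelSpec,
    params: Mapping[str, float] | None,
    subject: SubjectRecord,
    config: EvaluationConfig = EvaluationConfig(),
):
    """Steady-state-initialised simulation spanning the subject's grid.

    Returns the :class:`~hpakit.desolver.Solution`; raises on integration or
    steady-state failure (callers wanting a cost use :func:`evaluate_params`,
    which converts failures to +inf).
    """
    drivers = Drivers(
        circadian=model.default_drivers.circadian, stress=config.stress
    )
    y0 = steady_state(model, params=params, drivers=drivers)
    t_first = float(subject.times[0])
    t_last = float(subject.times[-1])
    return integrate(
        model,
        params=params,
        span=(t_first - config.burn_in, t_last),
        initial=y0,
        rtol=config.rtol,
        atol=config.atol,
        drivers=drivers,
    )


_FAILED = object()


def evaluate_params(
    model: ModelSpec,
    params: Mapping[str, float] | None,
    subject: SubjectRecord,
    config: EvaluationConfig = EvaluationConfig(),
) -> CostBreakdown:
    """Cost of one parameter set on one subject (+inf on simulation failure).

    Parameters outside their declared bounds are allowed (saved sets may be
    re-used across datasets) but a warning is logged.
    """
    if params:
        for name, value in params.items():
            entry = model.params[name]
            if not entry.lower <= value <= entry.upper:
                logger.warning(
                    "parameter %s=%g outside declared bounds [%g, %g]",
                    name, value, entry.lower, entry.upper,
                )
    try:
        solution = simulate_for_subject(model, params, subject, config)
        return sse_cost(solution, model, subject, config.convention)
    except (IntegrationError, SteadyStateError, CostError, ValueError) as exc:
        logger.warning(
            "evaluation failed for model %r (%s); cost set to +inf",
            model.name, exc,
        )
        return CostBreakdown(
            per_hormone={}, n_points=0, total=np.inf,
            convention=config.convention.label,
        )


# ---------------------------------------------------------------------------
# repeated-run validation protocol
# ---------------------------------------------------------------------------

def run_validation(
    model: ModelSpec,
    subject: SubjectRecord,
    free_param_names: Sequence[str] | None = None,
    repeats: int = 5,
    popsize: int = 10,
    generations: int = 40,
    seeds: Sequence[int] | None = None,
    base_seed: int = 0,
    config: EvaluationConfig = EvaluationConfig(),
    mutation: tuple[float, float] = (0.5, 1.0),
    recombination: float = 0.7,
    run_prefix: str = "run",
) -> list[OptimizationRun]:
    """Run ``repeats`` independent DE calibrations of one model on one subject.

    ``free_param_names`` defaults to every parameter flagged optimisable;
    an empty free set degenerates to a single evaluation at the defaults.
    Distinct seeds are required (defaults: ``base_seed + repeat index``).
    """
    free = (
        list(free_param_names)
        if free_param_names is not None
        else model.params.optimizable()
    )
    for name in free:
        model.params[name]  # KeyError for unknown names

    if seeds is None:
        seeds = [base_seed + r for r in range(repeats)]
    seeds = [int(s) for s in seeds]
    if len(seeds) != repeats or len(set(seeds)) != repeats:
        raise ValueError("need one distinct seed per repeat")

    if not free:
        cost = evaluate_params(model, {}, subject, config).total
        return [
            OptimizationRun(
                run_id=f"{run_prefix}-default",
                algorithm="none",
                seed=seeds[0] if seeds else 0,
                popsize=0,
                generations=0,
                best_params={},
                best_cost=cost,
                trace=np.array([cost]),
            )
        ]

    defaults = model.params.defaults()
    x0 = np.array([defaults[n] for n in free])
    bounds = model.params.bounds(free)

    def objective(x: np.ndarray) -> float:
        return evaluate_params(
            model, dict(zip(free, x)), subject, config
        ).total

    runs = []
    for r, seed in enumerate(seeds):
        runs.append(
            differential_evolution(
                objective,
                bounds,
                popsize=popsize,
                mutation=mutation,
                recombination=recombination,
                generations=generations,
                seed=seed,
                x0=x0,
                param_names=free,
                run_id=f"{run_prefix}-{r + 1}",
            )
        )
    return runs


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetResult:
    dataset_id: str
    mean_cost: float
    sd_cost: float
    best_cost: float
    n_repeats: int
    default_cost: float | None = None


@dataclass(frozen=True)
class ValidationReport:
    """Per-dataset summaries plus the overall mean-of-means model score."""

    model_name: str
    rows: tuple[DatasetResult, ...]
    overall_mean: float
    overall_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dataset": r.dataset_id,
                    "mean_cost": r.mean_cost,
                    "sd_cost": r.sd_cost,
                    "best_cost": r.best_cost,
                    "n_repeats": r.n_repeats,
                    "default_cost": r.default_cost,
                }
                for r in self.rows
            ]
        )


def build_report(
    model_name: str,
    results: Mapping[str, Sequence[OptimizationRun]],
    default_costs: Mapping[str, float] | None = None,
) -> ValidationReport:
    rows = []
    for dataset_id, runs in results.items():
        costs = np.array([r.best_cost for r in runs], dtype=float)
        rows.append(
            DatasetResult(
                dataset_id=dataset_id,
                mean_cost=float(costs.mean()),
                sd_cost=float(costs.std(ddof=1)) if costs.size > 1 else 0.0,
                best_cost=float(costs.min()),
                n_repeats=len(runs),
                default_cost=(
                    None if default_costs is None else default_costs.get(dataset_id)
                ),
            )
        )
    means = np.array([r.mean_cost for r in rows], dtype=float)
    return ValidationReport(
        model_name=model_name,
        rows=tuple(rows),
        overall_mean=float(means.mean()),
        overall_sd=float(means.std(ddof=1)) if means.size > 1 else 0.0,
    )


@dataclass(frozen=True)
class ValidationProtocol:
    """The full repeated-run protocol for :func:`batch_over_subjects`."""

    repeats: int = 5
    popsize: int = 10
    generations: int = 40
    free_params: tuple[str, ...] | None = None
    base_seed: int = 0
    config: EvaluationConfig = field(default_factory=EvaluationConfig)
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7
    include_default_cost: bool = True


#: The documented seven-dataset selection: six individual subjects plus the
#: cohort mean profile.
DEFAULT_SUBJECT_SELECTION = ("1", "10", "20", "30", "40", "50", "mean")


@dataclass(frozen=True)
class BatchResult:
    report: ValidationReport
    runs: dict[str, list[OptimizationRun]]
    subjects: dict[str, SubjectRecord]


def batch_over_subjects(
    model: ModelSpec,
    cohort: Cohort,
    subject_selection: Sequence[str] = DEFAULT_SUBJECT_SELECTION,
    protocol: ValidationProtocol = ValidationProtocol(),
) -> BatchResult:
    """Run the repeated validation protocol over several datasets.

    ``subject_selection`` names subject ids in the cohort, with the special
    id ``"mean"`` standing for the cohort mean profile.  Returns the
    aggregated report (per-dataset mean +/- SD, best single cost, optional
    default-parameter cost, and the overall mean of per-dataset means).
    """
    selections: dict[str, SubjectRecord] = {}
    for sid in subject_selection:
        if sid == "mean":
            selections[sid] = cohort_mean(cohort).mean
        else:
            selections[sid] = cohort.get(sid)  # KeyError for unknown ids

    results: dict[str, list[OptimizationRun]] = {}
    default_costs: dict[str, float] | None = (
        {} if protocol.include_default_cost else None
    )
    for k, (sid, subject) in enumerate(selections.items()):
        seeds = [protocol.base_seed + 1000 * k + r for r in range(protocol.repeats)]
        results[sid] = run_validation(
            model,
            subject,
            free_param_names=protocol.free_params,
            repeats=protocol.repeats,
            popsize=protocol.popsize,
            generations=protocol.generations,
            seeds=seeds,
            config=protocol.config,
            mutation=protocol.mutation,
            recombination=protocol.recombination,
            run_prefix=f"{model.name}-{sid}",
        )
        if default_costs is not None:
            default_costs[sid] = evaluate_params(
                model, {}, subject, protocol.config
            ).total
    report = build_report(model.name, results, default_costs)
    return BatchResult(report=report, runs=results, subjects=selections)


def rank_models(reports: Mapping[str, ValidationReport]) -> list[str]:
    """Model names ordered by ascending overall mean cost (ties by name)."""
    return sorted(reports, key=lambda n: (reports[n].overall_mean, n))


# ---------------------------------------------------------------------------
# generalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneralizationResult:
    matrix: pd.DataFrame       # rows: parameter-set id; columns: subject id
    group_means: pd.DataFrame  # rows: parameter-set id; columns: subject group


def generalization_matrix(
    model: ModelSpec,
    saved_param_sets: Mapping[str, Mapping[str, float]],
    cohort: Cohort,
    config: EvaluationConfig = EvaluationConfig(),
) -> GeneralizationResult:
    """Cost of every saved parameter set on every cohort subject.

    Failures are recorded as +inf cells, never aborts.  ``group_means``
    averages the matrix columns by subject group label.
    """
    subject_ids = cohort.ids
    data = {}
    for set_id, params in saved_param_sets.items():
        row = []
        for s in cohort.subjects:
            row.append(evaluate_params(model, dict(params), s, config).total)
        data[set_id] = row
    matrix = pd.DataFrame.from_dict(
        data, orient="index", columns=subject_ids
    )
    groups = {s.subject_id: s.group for s in cohort.subjects}
    group_of = pd.Series({sid: groups[sid] for sid in subject_ids})
    group_means = matrix.T.groupby(group_of).mean().T
    return GeneralizationResult(matrix=matrix, group_means=group_means)
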