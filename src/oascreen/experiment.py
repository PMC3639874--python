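"""Evaluation protocol: randomized 50/50 splits, multiruns, stability.

For each of ``n_splits`` label-stratified 50/50 splits of a screening
dataset, the assignment-edge weights are optimized on the optimization
half (``n_multiruns`` independent restarts) and the best multirun —
selected by its optimization-split fitness, never by test performance —
is scored on the held-out external half.  Multirun stability is the
per-split sample standard deviation of the optimized metric averaged
over splits; convergence speed is the number of fitness evaluations
needed to come within a tolerance (1% relative, or a fixed 0.01) of the
final best performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assignment import VirtualScreen, normalize_weights
from .chemgraph import MoleculeGraph, ScreeningDataset
from .optimize import OptimizationRun, OptimizerConfig, VSFitness, run_optimization
from .vsmetrics import MetricReport, RankedList, compute_report

__all__ = [
    "SplitPlan",
    "make_splits",
    "multirun_stability",
    "relative_sd",
    "convergence_point",
    "average_ranks",
    "ExperimentConfig",
    "SplitResult",
    "ExperimentResult",
    "run_experiment",
]


@dataclass
class SplitPlan:
    """Per-split boolean masks (True = optimization half) over the records."""

    seed: int
    masks: list[np.ndarray]

    @property
    def n_splits(self) -> int:
        return len(self.masks)

    def optimization_indices(self, split: int) -> np.ndarray:
        return np.flatnonzero(self.masks[split])

    def test_indices(self, split: int) -> np.ndarray:
        return np.flatnonzero(~self.masks[split])


def make_splits(dataset: ScreeningDataset, n_splits: int = 10, seed: int = 0) -> SplitPlan:
    """Label-stratified randomized 50/50 splits, reproducible from the seed.

    Each half holds (about) half of the actives and half of the decoys;
    with an odd label count the optimization half gets the smaller part
    (floor), the external half the extra record.
    """
    if dataset.n_actives < 2 or dataset.n_decoys < 2:
        raise ValueError("need at least 2 actives and 2 decoys to split")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    masks = []
    for _ in range(n_splits):
        mask = np.zeros(len(dataset), dtype=bool)
        for value in (True, False):
            idx = np.flatnonzero(labels == value)
            rng.shuffle(idx)
            mask[idx[: len(idx) // 2]] = True
        masks.append(mask)
    return SplitPlan(seed=seed, masks=masks)


def _as_value_table(results) -> list[np.ndarray]:
    """Normalize per-split multirun values to a list of float arrays."""
    if isinstance(results, dict):
        results = list(results.values())
    table = [np.asarray(v, dtype=float) for v in results]
    if not table:
        raise ValueError("no splits given")
    for v in table:
        if v.size < 2:
            raise ValueError("multirun stability needs >= 2 multiruns per split")
    return table


def multirun_stability(results) -> float:
    """Mean over splits of the per-split sample SD of the optimized metric."""
    table = _as_value_table(results)
    return float(np.mean([np.std(v, ddof=1) for v in table]))


def relative_sd(results) -> float:
    """%RSD: per-split sample SD over mean x 100, averaged over splits."""
    table = _as_value_table(results)
    out = []
    for v in table:
        mean = v.mean()
        if mean == 0:
            raise ValueError("relative SD undefined for zero per-split mean")
        out.append(100.0 * np.std(v, ddof=1) / mean)
    return float(np.mean(out))


def convergence_point(trace, mode: str = "relative", tol: float | None = None) -> int:
    """Evaluations needed to come within a tolerance of the final best.

    ``trace`` is a best-so-far *performance* trace (monotone non-decreasing,
    one entry per fitness evaluation).  Relative mode uses a band of
    ``tol`` (default 1%) of the final best; absolute mode a fixed band of
    ``tol`` (default 0.01).  Returns the 1-based evaluation index.  A
    final best of zero makes the relative band degenerate, so it falls
    back to the absolute mode.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    final = trace[-1]
    if mode == "relative":
        if final == 0:
            return convergence_point(trace, mode="absolute", tol=None)
        threshold = final - abs(final) * (0.01 if tol is None else tol)
    elif mode == "absolute":
        threshold = final - (0.01 if tol is None else tol)
    else:
        raise ValueError("mode must be 'relative' or 'absolute'")
    return int(np.argmax(trace >= threshold)) + 1


def average_ranks(table: dict[str, list[float]], higher_better: bool = True) -> dict[str, float]:
    """Average rank of each method over datasets (rank 1 = best, ties averaged)."""
    from scipy.stats import rankdata

    methods = list(table)
    values = np.array([table[m] for m in methods], dtype=float)
    if values.ndim != 2:
        raise ValueError("each method needs one value per dataset")
    ranks = np.empty_like(values)
    for j in range(values.shape[1]):
        col = -values[:, j] if higher_better else values[:, j]
        ranks[:, j] = rankdata(col)
    return {m: float(ranks[k].mean()) for k, m in enumerate(methods)}


@dataclass
class ExperimentConfig:
    n_splits: int = 10
    n_multiruns: int = 10
    budget: int = 15000
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    metric: str = "auc"
    alpha: float = 53.6
    roce_levels: tuple[float, ...] = (1.0, 5.0)
    seed: int = 0


@dataclass
class SplitResult:
    runs: list[OptimizationRun]
    best_run_index: int
    external_report: MetricReport
    baseline_report: MetricReport
    optimization_ids: list[str]
    test_ids: list[str]

    @property
    def best_run(self) -> OptimizationRun:
        return self.runs[self.best_run_index]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    splits: list[SplitResult]

    def optimized_metric_values(self) -> list[list[float]]:
        """Per split: the optimized (1 - fitness) metric of every multirun."""
        return [[1.0 - run.best_fitness for run in s.runs] for s in self.splits]

    @property
    def mean_external_auc(self) -> float:
        return float(np.mean([s.external_report.auc for s in self.splits]))

    @property
    def mean_baseline_auc(self) -> float:
        return float(np.mean([s.baseline_report.auc for s in self.splits]))


def _external_report(screen: VirtualScreen, subset: ScreeningDataset,
                     weights: np.ndarray | None, config: ExperimentConfig) -> MetricReport:
    scores = screen.scores(weights)
    ranked = RankedList.from_records(subset.ids, scores, subset.labels, subset.clusters)
    return compute_report(ranked, alpha=config.alpha, roce_levels=config.roce_levels)


def run_experiment(dataset: ScreeningDataset, query: MoleculeGraph,
                   config: ExperimentConfig,
                   screen: VirtualScreen | None = None) -> ExperimentResult:
    """Full protocol: splits x multiruns, external scoring of the best run.

    External metrics are computed only on records never seen by any
    fitness evaluation.  Multirun seeds are spawned deterministically
    from ``config.seed``, so a rerun reproduces the result exactly.
    """
    if config.metric not in ("auc", "bedroc"):
        raise ValueError("metric must be 'auc' or 'bedroc'")
    plan = make_splits(dataset, config.n_splits, seed=config.seed)
    if screen is None:
        screen = VirtualScreen(query, dataset.molecules)
    # deterministic per-(split, run) seeds below 2**31
    seed_rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    seeds = seed_rng.integers(0, 2**31 - 1, size=(config.n_splits, config.n_multiruns))
    splits: list[SplitResult] = []
    for s in range(config.n_splits):
        opt_idx = plan.optimization_indices(s)
        test_idx = plan.test_indices(s)
        opt_subset = dataset.subset(opt_idx)
        test_subset = dataset.subset(test_idx)
        opt_screen = screen.subset(opt_idx)
        test_screen = screen.subset(test_idx)
        runs = []
        for r in range(config.n_multiruns):
            fitness = VSFitness(query, opt_subset, metric=config.metric,
                                alpha=config.alpha, screen=opt_screen)
            runs.append(run_optimization(fitness, query.n_atoms, config.optimizer,
                                         config.budget, int(seeds[s, r])))
        best = min(range(len(runs)), key=lambda k: (runs[k].best_fitness, k))
        weights = normalize_weights(runs[best].best_position)
        splits.append(SplitResult(
            runs=runs, best_run_index=best,
            external_report=_external_report(test_screen, test_subset, weights, config),
            baseline_report=_external_report(test_screen, test_subset, None, config),
            optimization_ids=opt_subset.ids, test_ids=test_subset.ids))
    return ExperimentResult(config=config, splits=splits)
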