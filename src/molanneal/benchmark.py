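"""Reference surrogate benchmarks for offline evaluation.

Two complementary tasks probe the two algorithmic components:

* The **moat task** starts from methylcyclopentane and asks for a second
  ring while penalizing extra heavy atoms, with the ring-size window set
  to 5-8 so no direct cyclization is legal: the walker must first accept a
  strictly worse insertion and only then close a fused ring. At the cold
  constant temperature used here the Metropolis rule essentially never
  crosses that one-step moat, while reversible sampling's secondary-edit
  lookahead does - an idealized activity cliff.

* The **scaffold task** starts from 2-ethylnaphthalene under a tight
  similarity constraint: edits on the aromatic core are mostly rejected,
  so productive edits concentrate on the short aliphatic tail, which is
  exactly the signal the history-trained position predictor can learn.

The ablation comparison computes, per mode, the median best score over the
paired seeds separately for each task and sums the two medians. Each task's
median isolates its own mechanism under seed pairing; summing per-seed
totals instead would let the moat task's bimodal outcomes (crossed /
stuck) reshuffle which seed sits at the median of the combined score and
drown the scaffold task's signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annealer import AnnealOptions, AnnealSchedule, Trajectory, anneal, run_ablation
from .molgraph import MolGraph, parse_molecule
from .position import (
    PositionModel,
    PositionModelConfig,
    harvest_history,
    train_position_model,
)
from .scoring import ObjectiveSpec, PharmacophoreProfile, SurrogateDockScorer

__all__ = [
    "BenchmarkTask",
    "moat_task",
    "scaffold_task",
    "optimization_task",
    "train_benchmark_model",
    "run_optimization_benchmark",
    "run_ablation_benchmark",
]


@dataclass(frozen=True)
class BenchmarkTask:
    name: str
    x0: MolGraph
    spec: ObjectiveSpec
    schedule: AnnealSchedule
    options: AnnealOptions


def _spec(profile, alpha=1.0, beta=0.2, gamma=0.2, delta=0.05):
    return ObjectiveSpec(
        dock_scorer=SurrogateDockScorer(profile),
        alpha=alpha, beta=beta, gamma=gamma, delta=delta, dock_sign=1,
    )


def moat_task() -> BenchmarkTask:
    """Reversible-sampling probe: one-edit-deep score moat."""
    profile = PharmacophoreProfile(
        targets={"heavy_atoms": 6, "rings": 2, "hbd": 0, "hba": 0},
        weights={"heavy_atoms": 0.5, "rings": 2.0, "hbd": 0.5, "hba": 0.5},
    )
    return BenchmarkTask(
        name="moat",
        x0=parse_molecule("CC1CCCC1", provenance="moat-start"),
        spec=_spec(profile, beta=0.0, gamma=0.0, delta=0.05),
        schedule=AnnealSchedule(t_init=0.02, t_min=0.02, n_steps=200),
        options=AnnealOptions(
            K=10,
            ring_window=(5, 8),
            op_weights={
                "insertion": 0.35, "replacement": 0.1,
                "deletion": 0.1, "cyclization": 0.45,
            },
        ),
    )


def scaffold_task(n_steps: int = 120) -> BenchmarkTask:
    """Position-predictor probe: aromatic core with a productive tail."""
    profile = PharmacophoreProfile(
        targets={"heavy_atoms": 16, "rings": 3, "hbd": 1, "hba": 2},
        weights={"heavy_atoms": 0.25, "rings": 1.0, "hbd": 0.5, "hba": 0.5},
    )
    return BenchmarkTask(
        name="scaffold",
        x0=parse_molecule("c1ccc2ccccc2c1CC", provenance="scaffold-start"),
        spec=_spec(profile, delta=0.3),
        schedule=AnnealSchedule(n_steps=n_steps),
        options=AnnealOptions(K=4),
    )


def optimization_task(n_steps: int = 300) -> BenchmarkTask:
    """Plain optimization probe: hexane toward a two-ring profile."""
    return BenchmarkTask(
        name="optimization",
        x0=parse_molecule("CCCCCC", provenance="chain-start"),
        spec=_spec(PharmacophoreProfile(), delta=0.05),
        schedule=AnnealSchedule(n_steps=n_steps),
        options=AnnealOptions(K=5),
    )


def train_benchmark_model(
    seed: int = 100, n_runs: int = 10, harvest_steps: int = 100
) -> PositionModel:
    """Harvest random-position history on the scaffold task and fit the
    position predictor used by the full / wo-reverse ablation modes."""
    task = scaffold_task()
    history = harvest_history(
        task.x0, task.spec, AnnealSchedule(n_steps=harvest_steps),
        n_runs=n_runs, seed=seed,
    )
    return train_position_model(
        history, PositionModelConfig(max_iter=300, seed=0)
    )


def run_optimization_benchmark(
    seeds, n_steps: int = 300
) -> tuple[float, list[float], list[Trajectory]]:
    """Run the optimization probe for each seed.

    Returns ``(start score, best scores per seed, trajectories)``.
    """
    from .scoring import objective

    task = optimization_task(n_steps)
    start = objective(task.x0, task.x0, task.spec).total
    trajectories = [
        anneal(task.x0, task.spec, task.schedule, model=None, seed=s,
               options=task.options)
        for s in seeds
    ]
    return start, [t.best_score for t in trajectories], trajectories


def run_ablation_benchmark(
    seeds, model: PositionModel | None = None
) -> dict:
    """Paired-seed ablation over the moat + scaffold suite.

    For each mode the summary score is the sum over tasks of the per-task
    median best score (see module docstring for why medians are taken per
    task). Per-task score lists and all trajectories are returned for
    audits.
    """
    if model is None:
        model = train_benchmark_model()
    per_task: dict[str, dict[str, list[float]]] = {}
    trajectories: dict = {}
    tasks = (moat_task(), scaffold_task())
    for task in tasks:
        res = run_ablation(
            task.x0, task.spec, task.schedule, model, seeds=seeds,
            options=task.options,
        )
        for mode, stats in res["modes"].items():
            per_task.setdefault(mode, {})[task.name] = stats["best_scores"]
            trajectories.setdefault(mode, {}).setdefault(task.name, []).extend(
                stats["trajectories"]
            )
    medians = {
        mode: float(sum(np.median(scores) for scores in task_scores.values()))
        for mode, task_scores in per_task.items()
    }
    return {
        "seeds": list(seeds),
        "per_task_scores": per_task,
        "medians": medians,
        "trajectories": trajectories,
        "tasks": {t.name: t for t in tasks},
    }
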