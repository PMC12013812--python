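"""Simulated-annealing engine: schedule, acceptance, reversible sampling.

One walker iteratively edits a molecular graph. A proposal beating the
incumbent is always accepted; a worse one survives a Metropolis draw at the
current temperature, and — uniquely — a rejected candidate gets one
secondary edit: if that secondary edit beats the incumbent, the *original*
candidate is accepted after all (reversible sampling), on the grounds that
it is one step from something better.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .editing import EditProposal, NoEditError, propose
from .molgraph import MolGraph
from .position import (
    FrequencyRecord,
    UniformPositionPolicy,
    predict_positions,
    transfer_frequency,
)
from .scoring import ObjectiveSpec, ScoreBreakdown, objective

__all__ = [
    "AnnealSchedule",
    "AnnealOptions",
    "StepRecord",
    "Trajectory",
    "StuckError",
    "ABLATION_MODES",
    "temperature",
    "accept_probability",
    "reversible_step",
    "anneal",
    "run_ablation",
]

ABLATION_MODES = ("full", "wo-pos", "wo-reverse", "origin")

_STREAMS = ("position", "operator", "payload", "metropolis", "reversible")


@dataclass(frozen=True)
class AnnealSchedule:
    """Reciprocal cooling schedule with a temperature floor."""

    t_init: float = 1.0
    t_min: float = 0.05
    n_steps: int = 500

    def __post_init__(self) -> None:
        if self.t_init <= 0 or self.t_min <= 0:
            raise ValueError("temperatures must be positive")
        if self.t_min > self.t_init:
            raise ValueError("t_min must not exceed t_init")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")


def temperature(t: int, sched: AnnealSchedule) -> float:
    """``max(t_min, t_init / (t + 1))`` — non-increasing in t."""
    if t < 0:
        raise ValueError("step must be >= 0")
    return max(sched.t_min, sched.t_init / (t + 1))


def accept_probability(f_new: float, f_cur: float, T: float) -> float:
    """Metropolis probability ``min(1, exp((f_new - f_cur) / T))``.

    A gated (-inf) candidate has probability exactly 0.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not math.isfinite(f_cur):
        raise ValueError("incumbent score must be finite")
    if f_new == -math.inf:
        return 0.0
    delta = f_new - f_cur
    if delta >= 0:
        return 1.0
    return math.exp(delta / T)


@dataclass
class AnnealOptions:
    """Run-shaping knobs shared by all ablation modes."""

    K: int = 5
    op_weights: dict[str, float] | None = None
    reversible: bool = True
    max_position_retries: int = 8
    ring_window: tuple[int, int] = (3, 8)


@dataclass(frozen=True)
class StepRecord:
    t: int
    temperature: float
    incumbent: str
    proposal: str | None
    operator: str | None
    position: int | None
    proposal_score: float
    incumbent_score: float
    decision: str  # accept | reject | reversible-accept | reversible-reject | stuck

    def as_dict(self) -> dict:
        return {
            "t": self.t,
            "temperature": self.temperature,
            "incumbent": self.incumbent,
            "proposal": self.proposal,
            "operator": self.operator,
            "position": self.position,
            "proposal_score": self.proposal_score,
            "incumbent_score": self.incumbent_score,
            "decision": self.decision,
        }


@dataclass
class Trajectory:
    """Ordered record of one annealing run plus the best state found."""

    x0: MolGraph
    seed: int
    steps: list[StepRecord] = field(default_factory=list)
    best: MolGraph | None = None
    best_score: float = -math.inf
    best_breakdown: ScoreBreakdown | None = None
    best_step: int = 0
    frequency_records: list[FrequencyRecord] = field(default_factory=list)

    @property
    def final(self) -> MolGraph:
        return self.best if self.best is not None else self.x0

    def best_so_far_series(self) -> list[float]:
        out, cur = [], -math.inf
        for s in self.steps:
            cur = max(cur, s.incumbent_score)
            out.append(cur)
        return out

    def decisions(self) -> list[str]:
        return [s.decision for s in self.steps]

    def log_hash(self) -> str:
        payload = json.dumps([s.as_dict() for s in self.steps], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.steps:
                fh.write(json.dumps(s.as_dict()) + "\n")

    def summary(self, config_hash: str = "") -> dict:
        return {
            "best_smiles": self.final.canonical,
            "best_score": self.best_score,
            "best_breakdown": (
                self.best_breakdown.as_dict() if self.best_breakdown else None
            ),
            "best_step": self.best_step,
            "seed": self.seed,
            "config_hash": config_hash,
        }


class StuckError(RuntimeError):
    """No valid proposal was ever found; carries the partial trajectory."""

    def __init__(self, message: str, trajectory: Trajectory) -> None:
        super().__init__(message)
        self.trajectory = trajectory


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def reversible_step(
    x_star: EditProposal,
    f_cur: float,
    x0: MolGraph,
    spec: ObjectiveSpec,
    model,
    options: AnnealOptions,
    rng: np.random.Generator,
) -> bool:
    """Secondary-edit test applied after a primary Metropolis rejection.

    Predicts a position on the rejected candidate, samples one secondary
    edit and scores it; returns True (accept the *original* candidate) iff
    the secondary edit's score strictly beats the incumbent's.
    """
    mol = x_star.result
    try:
        _, pos = predict_positions(model, mol, options.K, rng)
        secondary = propose(mol, pos, options.op_weights, rng, payload_rng=rng,
                            ring_window=options.ring_window)
    except NoEditError:
        return False
    f_second = objective(secondary.result, x0, spec).total
    return f_second > f_cur


def anneal(
    x0: MolGraph,
    spec: ObjectiveSpec,
    sched: AnnealSchedule,
    model=None,
    seed: int = 0,
    options: AnnealOptions | None = None,
    op_weights: dict[str, float] | None = None,
    collect_frequency: bool = False,
) -> Trajectory:
    """Run one annealing trajectory from ``x0``.

    ``model=None`` selects uniform random positions (the wo-pos ablation);
    ``options.reversible=False`` disables the secondary-edit re-acceptance.
    Fully reproducible from ``seed``.
    """
    if options is None:
        options = AnnealOptions()
    if op_weights is not None:
        options.op_weights = op_weights
    start = objective(x0, x0, spec)
    if not math.isfinite(start.total):
        raise ValueError("starting molecule must score finite under the objective")

    rng = _streams(seed)
    traj = Trajectory(x0=x0, seed=seed)
    cur, f_cur, cur_breakdown = x0, start.total, start
    traj.best, traj.best_score, traj.best_breakdown, traj.best_step = (
        x0, start.total, start, 0,
    )
    freq = FrequencyRecord.zeros(x0) if collect_frequency else None
    any_proposal = False

    for t in range(sched.n_steps):
        T = temperature(t, sched)
        proposal = None
        for _ in range(options.max_position_retries):
            _, pos = predict_positions(model, cur, options.K, rng["position"])
            try:
                proposal = propose(
                    cur, pos, options.op_weights, rng["operator"],
                    payload_rng=rng["payload"], ring_window=options.ring_window,
                )
                break
            except NoEditError:
                continue
        if proposal is None:
            traj.steps.append(
                StepRecord(t, T, cur.canonical, None, None, None,
                           -math.inf, f_cur, "stuck")
            )
            continue
        any_proposal = True
        cand = objective(proposal.result, x0, spec)
        p = accept_probability(cand.total, f_cur, T)
        accepted = rng["metropolis"].random() < p if p < 1.0 else True
        decision = "accept" if accepted else "reject"
        # gated (-inf) candidates are excluded from reversible rescue: they
        # must never become the incumbent
        if not accepted and options.reversible and math.isfinite(cand.total):
            if reversible_step(
                proposal, f_cur, x0, spec, model, options, rng["reversible"]
            ):
                accepted, decision = True, "reversible-accept"
            else:
                decision = "reversible-reject"
        if accepted:
            if freq is not None:
                freq = transfer_frequency(freq, proposal)
                traj.frequency_records.append(freq)
            cur, f_cur, cur_breakdown = proposal.result, cand.total, cand
            if f_cur > traj.best_score:
                traj.best, traj.best_score = cur, f_cur
                traj.best_breakdown, traj.best_step = cand, t + 1
        traj.steps.append(
            StepRecord(
                t, T, cur.canonical, proposal.result.canonical,
                proposal.action.kind, proposal.action.position,
                cand.total, f_cur, decision,
            )
        )
    if sched.n_steps > 0 and not any_proposal:
        raise StuckError("no valid proposal found at any step", traj)
    return traj


def _mode_settings(mode: str, model) -> tuple[object, bool]:
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    use_model = model if mode in ("full", "wo-reverse") else None
    reversible = mode in ("full", "wo-pos")
    return use_model, reversible


def run_ablation(
    x0: MolGraph,
    spec: ObjectiveSpec,
    sched: AnnealSchedule,
    model,
    seeds: Sequence[int],
    modes: Sequence[str] = ABLATION_MODES,
    options: AnnealOptions | None = None,
) -> dict:
    """Paired-seed comparison of ablation modes.

    Modes: ``full`` = predictor + reversible; ``wo-pos`` = random positions
    + reversible; ``wo-reverse`` = predictor only; ``origin`` = neither.
    Returns per-mode best-score lists with mean / median summaries.
    """
    base = options or AnnealOptions()
    out: dict = {"modes": {}, "seeds": list(seeds)}
    for mode in modes:
        use_model, reversible = _mode_settings(mode, model)
        scores, trajectories = [], []
        for seed in seeds:
            opts = AnnealOptions(
                K=base.K, op_weights=base.op_weights, reversible=reversible,
                max_position_retries=base.max_position_retries,
                ring_window=base.ring_window,
            )
            traj = anneal(x0, spec, sched, model=use_model, seed=seed, options=opts)
            scores.append(traj.best_score)
            trajectories.append(traj)
        out["modes"][mode] = {
            "best_scores": scores,
            "mean": float(np.mean(scores)),
            "median": float(np.median(scores)),
            "trajectories": trajectories,
        }
    return out
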