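"""Gated multi-constraint objective and pluggable docking scorers.

The objective is a weighted sum of a docking term, synthetic accessibility
and drug-likeness, gated by chemical validity and a similarity constraint
to the starting fragment; gated-out candidates score -inf so they can never
win an acceptance comparison.

Internally "larger total is better": raw docking energies (kcal/mol, lower
= tighter) are negated before entering the weighted sum; logs keep the
native sign.
"""

from __future__ import annotations

import hashlib
import math
import os
import re
import subprocess
import sys
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

from rdkit import Chem
from rdkit.Chem import AllChem, Lipinski, QED, rdMolDescriptors

from .molgraph import MolGraph, check_valence, similarity

__all__ = [
    "ObjectiveSpec",
    "ScoreBreakdown",
    "DockingScorer",
    "ScorerError",
    "PharmacophoreProfile",
    "SurrogateDockScorer",
    "DockingBox",
    "VinaDockScorer",
    "property_score",
    "validity_gate",
    "objective",
    "surrogate_dock",
    "sa_score",
    "qed_score",
    "count_features",
]


class ScorerError(RuntimeError):
    """A docking scorer failed on a specific molecule."""


@runtime_checkable
class DockingScorer(Protocol):
    """Contract: deterministic ``score(mol) -> float`` (raw convention:
    lower = better binding, as docking programs report)."""

    def score(self, mol: MolGraph) -> float: ...


@dataclass
class ObjectiveSpec:
    """Weights and constraints of the gated objective.

    ``dock_sign = -1`` converts raw lower-is-better docking energies to the
    internal higher-is-better orientation; use ``+1`` for scorers that are
    already oriented (e.g. the surrogate).
    """

    dock_scorer: DockingScorer
    alpha: float = 1.0
    beta: float = 0.2
    gamma: float = 0.2
    delta: float = 0.4
    dock_sign: int = -1

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("weights must be non-negative")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0,1]")
        if self.dock_sign not in (-1, 1):
            raise ValueError("dock_sign must be -1 or +1")


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-term scores for one candidate. ``dock`` is the oriented value
    entering the weighted sum; ``dock_raw`` keeps the scorer's native sign."""

    dock: float
    syn: float
    qed: float
    sim: float
    valid: bool
    total: float
    dock_raw: float = math.nan

    def as_dict(self) -> dict:
        return {
            "dock": self.dock,
            "dock_raw": self.dock_raw,
            "syn": self.syn,
            "qed": self.qed,
            "sim": self.sim,
            "valid": self.valid,
            "total": self.total,
        }


_SASCORER = None


def _load_sascorer():
    global _SASCORER
    if _SASCORER is None:
        from rdkit.Chem import RDConfig

        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer  # type: ignore

        _SASCORER = sascorer
    return _SASCORER


def sa_score(mol: MolGraph) -> float:
    """Raw synthetic-accessibility score: 1 (easy) .. 10 (hard)."""
    return float(_load_sascorer().calculateScore(mol.to_rdkit()))


def normalized_sa(mol: MolGraph) -> float:
    """SA mapped to [0,1] with 1 = easiest, so it adds with positive weight."""
    return 1.0 - (sa_score(mol) - 1.0) / 9.0


def qed_score(mol: MolGraph) -> float:
    return float(QED.qed(mol.to_rdkit()))


def property_score(x_star: MolGraph, spec: ObjectiveSpec) -> ScoreBreakdown:
    """Ungated weighted property score (similarity/validity not evaluated)."""
    try:
        raw = float(spec.dock_scorer.score(x_star))
    except ScorerError:
        raise
    except Exception as exc:
        raise ScorerError(f"docking scorer failed on {x_star.canonical}: {exc}")
    dock = spec.dock_sign * raw
    syn = normalized_sa(x_star) if spec.beta > 0 else 0.0
    qed = qed_score(x_star) if spec.gamma > 0 else 0.0
    total = spec.alpha * dock + spec.beta * syn + spec.gamma * qed
    if math.isnan(total):
        raise ScorerError(f"NaN score for {x_star.canonical}")
    return ScoreBreakdown(
        dock=dock, syn=syn, qed=qed, sim=math.nan, valid=True, total=total,
        dock_raw=raw,
    )


def validity_gate(x_star: MolGraph, x0: MolGraph, spec: ObjectiveSpec) -> bool:
    """True iff valence-valid AND similarity to the start strictly exceeds
    the threshold delta."""
    if not check_valence(x_star):
        return False
    return similarity(x_star, x0).value > spec.delta


def objective(x_star: MolGraph, x0: MolGraph, spec: ObjectiveSpec) -> ScoreBreakdown:
    """Gated objective: the weighted property score when the candidate
    passes the gate, -inf otherwise."""
    sim = similarity(x_star, x0).value
    if not check_valence(x_star) or not sim > spec.delta:
        return ScoreBreakdown(
            dock=math.nan, syn=math.nan, qed=math.nan, sim=sim,
            valid=False, total=-math.inf,
        )
    part = property_score(x_star, spec)
    return ScoreBreakdown(
        dock=part.dock, syn=part.syn, qed=part.qed, sim=sim,
        valid=True, total=part.total, dock_raw=part.dock_raw,
    )


# -- surrogate docking ------------------------------------------------------

_FEATURES = ("heavy_atoms", "rings", "hbd", "hba")


def count_features(mol: MolGraph) -> dict[str, int]:
    """Graph-invariant pharmacophore-style counts."""
    rdmol = mol.to_rdkit()
    return {
        "heavy_atoms": rdmol.GetNumAtoms(),
        "rings": rdMolDescriptors.CalcNumRings(rdmol),
        "hbd": Lipinski.NumHDonors(rdmol),
        "hba": Lipinski.NumHAcceptors(rdmol),
    }


@dataclass(frozen=True)
class PharmacophoreProfile:
    """Target feature counts and per-feature penalty weights for the
    surrogate scorer."""

    targets: dict[str, int] = field(
        default_factory=lambda: {"heavy_atoms": 12, "rings": 2, "hbd": 1, "hba": 2}
    )
    weights: dict[str, float] = field(
        default_factory=lambda: {"heavy_atoms": 0.25, "rings": 2.0, "hbd": 1.0, "hba": 1.0}
    )

    def __post_init__(self) -> None:
        for key in self.targets:
            if key not in _FEATURES:
                raise ValueError(f"unknown feature {key!r}")


def surrogate_dock(mol: MolGraph, profile: PharmacophoreProfile) -> float:
    """Deterministic docking stand-in: negative weighted L1 deviation from
    the profile; 0 when the molecule matches the profile exactly."""
    counts = count_features(mol)
    return -sum(
        profile.weights.get(f, 0.0) * abs(counts[f] - t)
        for f, t in profile.targets.items()
    )


@dataclass
class SurrogateDockScorer:
    """:class:`DockingScorer` wrapper around :func:`surrogate_dock`.

    Already oriented higher-is-better, so pair it with ``dock_sign=+1``.
    """

    profile: PharmacophoreProfile = field(default_factory=PharmacophoreProfile)

    def score(self, mol: MolGraph) -> float:
        return surrogate_dock(mol, self.profile)


# -- external docking adapter ----------------------------------------------


@dataclass(frozen=True)
class DockingBox:
    """Search box in ångström, Vina convention."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.size) != 3:
            raise ValueError("center and size must be 3-vectors")
        if min(self.size) <= 0:
            raise ValueError("box sizes must be positive")


_AFFINITY_RE = re.compile(r"^\s*1\s+(-?\d+\.\d+)", re.MULTILINE)


class VinaDockScorer:
    """Adapter invoking an AutoDock-Vina-compatible binary as a subprocess.

    Embeds a 3-D conformer, writes the ligand, runs the binary and parses
    the best-pose affinity (kcal/mol, more negative = tighter). Results are
    cached by (canonical SMILES, receptor hash, box). The pose search and
    scoring function themselves are entirely the external program's.
    """

    def __init__(
        self,
        receptor: str | Path,
        box: DockingBox,
        binary: str = "qvina2",
        exhaustiveness: int = 8,
        seed: int = 0,
        runner: Callable[..., subprocess.CompletedProcess] | None = None,
    ) -> None:
        receptor = Path(receptor)
        if not receptor.exists():
            raise EnvironmentError(f"receptor file not found: {receptor}")
        self.receptor = receptor
        self.box = box  # validated by DockingBox itself
        self.binary = binary
        self.exhaustiveness = exhaustiveness
        self.seed = seed
        self._runner = runner or subprocess.run
        self._receptor_hash = hashlib.sha256(receptor.read_bytes()).hexdigest()[:16]
        self._cache: dict[tuple, float] = {}

    def _cache_key(self, mol: MolGraph) -> tuple:
        return (mol.canonical, self._receptor_hash, self.box.center, self.box.size)

    def score(self, mol: MolGraph) -> float:
        key = self._cache_key(mol)
        if key in self._cache:
            return self._cache[key]
        value = self._invoke(mol)
        self._cache[key] = value
        return value

    def _prepare_ligand(self, mol: MolGraph, path: Path) -> None:
        rdmol = Chem.AddHs(mol.to_rdkit())
        params = AllChem.ETKDGv3()
        params.randomSeed = self.seed
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise ScorerError(f"3D embedding failed for {mol.canonical}")
        AllChem.MMFFOptimizeMolecule(rdmol)
        Chem.MolToMolFile(rdmol, str(path))

    def _invoke(self, mol: MolGraph) -> float:
        with tempfile.TemporaryDirectory() as tmp:
            ligand = Path(tmp) / "ligand.mol"
            self._prepare_ligand(mol, ligand)
            cmd = [
                self.binary,
                "--receptor", str(self.receptor),
                "--ligand", str(ligand),
                "--center_x", str(self.box.center[0]),
                "--center_y", str(self.box.center[1]),
                "--center_z", str(self.box.center[2]),
                "--size_x", str(self.box.size[0]),
                "--size_y", str(self.box.size[1]),
                "--size_z", str(self.box.size[2]),
                "--exhaustiveness", str(self.exhaustiveness),
                "--seed", str(self.seed),
            ]
            try:
                proc = self._runner(cmd, capture_output=True, text=True, check=False)
            except FileNotFoundError:
                raise EnvironmentError(
                    f"docking binary {self.binary!r} not on PATH; "
                    "use SurrogateDockScorer for offline runs"
                )
            if proc.returncode != 0:
                raise ScorerError(
                    f"docking failed for {mol.canonical}: {proc.stderr[:500]}"
                )
            match = _AFFINITY_RE.search(proc.stdout)
            if match is None:
                raise ScorerError(f"no affinity parsed for {mol.canonical}")
            return float(match.group(1))
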