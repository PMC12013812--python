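"""History-guided editing-position prediction.

During random-position annealing runs, a per-molecule frequency vector
records how often each atom (and its neighbors) sat at an accepted edit
site. A node regressor — graph-isomorphism-style message passing to build
per-atom representations, followed by a trained regression head — learns
to predict those frequencies, and the annealer samples edit positions from
the predictor's top-K atoms.

PyTorch is deliberately not a dependency: the fixed message-passing encoder
is a few lines of NumPy, and the trained head is a scikit-learn regressor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .editing import EditProposal
from .molgraph import ELEMENT_VOCABULARY, MolGraph, parse_molecule

__all__ = [
    "FrequencyRecord",
    "HistoryDataset",
    "PositionModel",
    "PositionModelConfig",
    "UniformPositionPolicy",
    "update_frequency",
    "transfer_frequency",
    "harvest_history",
    "train_position_model",
    "predict_positions",
    "node_features",
]


@dataclass(frozen=True)
class FrequencyRecord:
    """Per-atom editing-frequency counts for one molecule."""

    molecule: MolGraph
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != self.molecule.num_atoms:
            raise ValueError("counts length must equal atom count")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @classmethod
    def zeros(cls, molecule: MolGraph) -> "FrequencyRecord":
        return cls(molecule, (0,) * molecule.num_atoms)


def update_frequency(record: FrequencyRecord, pos: int) -> FrequencyRecord:
    """Increment the count at ``pos`` and at each of its graph neighbors."""
    if not 0 <= pos < record.molecule.num_atoms:
        raise IndexError(f"position {pos} out of range")
    bump = {pos, *record.molecule.neighbors(pos)}
    counts = tuple(
        c + 1 if i in bump else c for i, c in enumerate(record.counts)
    )
    return replace(record, counts=counts)


def transfer_frequency(record: FrequencyRecord, edit: EditProposal) -> FrequencyRecord:
    """Carry counts across an edit to the child molecule.

    Surviving atoms keep their counts via the edit's index map, inserted
    atoms start at zero, deleted atoms' entries are dropped. For
    non-deletion edits the edited position (which survives) then receives
    the usual neighborhood increment in the child graph; for deletion the
    edited atom no longer exists and no increment is applied.
    """
    if edit.parent != record.molecule:
        raise ValueError("edit parent does not match record molecule")
    if len(edit.index_map) != record.molecule.num_atoms:
        raise RuntimeError("edit index map length mismatch")
    child = edit.result
    counts = [0] * child.num_atoms
    for parent_i, child_i in enumerate(edit.index_map):
        if child_i is not None:
            counts[child_i] = record.counts[parent_i]
    out = FrequencyRecord(child, tuple(counts))
    if edit.action.kind != "deletion":
        child_pos = edit.index_map[edit.action.position]
        if child_pos is None:  # pragma: no cover - defensive
            raise RuntimeError("edited position lost by a non-deletion edit")
        out = update_frequency(out, child_pos)
    return out


@dataclass
class HistoryDataset:
    """Accepted-state molecules with their frequency snapshots."""

    records: list[FrequencyRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def append(self, record: FrequencyRecord) -> None:
        self.records.append(record)

    def extend(self, records: Sequence[FrequencyRecord]) -> None:
        self.records.extend(records)

    def save_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(
                    json.dumps(
                        {"smiles": r.molecule.canonical, "counts": list(r.counts)}
                    )
                    + "\n"
                )

    @classmethod
    def load_jsonl(cls, path: str | Path) -> "HistoryDataset":
        ds = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            ds.append(
                FrequencyRecord(parse_molecule(obj["smiles"]), tuple(obj["counts"]))
            )
        return ds


def harvest_history(
    x0: MolGraph,
    spec,
    schedule,
    n_runs: int,
    seed: int,
    op_weights=None,
) -> HistoryDataset:
    """Collect (molecule, counts) pairs from random-position annealing runs.

    Runs ``n_runs`` trajectories in the random-position ("wo-pos") mode with
    reversible sampling enabled, threading the frequency record through
    every accepted edit. Deterministic given ``seed``.
    """
    from .annealer import anneal  # local import to avoid a cycle

    dataset = HistoryDataset()
    for run in range(n_runs):
        traj = anneal(
            x0,
            spec,
            schedule,
            model=None,
            seed=seed + run,
            op_weights=op_weights,
            collect_frequency=True,
        )
        dataset.extend(traj.frequency_records)
    return dataset


# -- node featurization and message passing ---------------------------------

_ELEMENTS = tuple(ELEMENT_VOCABULARY) + ("other",)
_MAX_DEGREE = 5


def node_features(mol: MolGraph) -> np.ndarray:
    """Per-atom input features: element one-hot, degree one-hot, ring and
    aromaticity flags, total bond order, implicit-H count."""
    rdmol = mol.to_rdkit()
    rows = []
    for atom in rdmol.GetAtoms():
        sym = atom.GetSymbol()
        elem = [0.0] * len(_ELEMENTS)
        elem[_ELEMENTS.index(sym) if sym in _ELEMENTS else -1] = 1.0
        deg = [0.0] * (_MAX_DEGREE + 1)
        deg[min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
        rows.append(
            elem
            + deg
            + [
                1.0 if atom.IsInRing() else 0.0,
                1.0 if atom.GetIsAromatic() else 0.0,
                atom.GetTotalValence() / 4.0,
                atom.GetTotalNumHs() / 4.0,
            ]
        )
    return np.asarray(rows, dtype=np.float64)


def adjacency(mol: MolGraph) -> np.ndarray:
    n = mol.num_atoms
    A = np.zeros((n, n))
    for i, j, _ in mol.bonds:
        A[i, j] = A[j, i] = 1.0
    return A


@dataclass(frozen=True)
class PositionModelConfig:
    """Architecture and training settings for the position predictor."""

    n_layers: int = 3
    hidden_dim: int = 64
    eps: float = 0.1
    encoder_seed: int = 7
    loss: str = "mse"  # "mse" (MLP head) or "poisson" (gradient boosting)
    hidden_layer_sizes: tuple[int, ...] = (64,)
    max_iter: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.n_layers <= 5:
            raise ValueError("n_layers must be in 3..5")
        if self.loss not in ("mse", "poisson"):
            raise ValueError("loss must be 'mse' or 'poisson'")


class _GINEncoder:
    """Fixed (seeded) graph-isomorphism-style message passing.

    Layer update: ``h <- relu(((1 + eps) * h + A h) W + b)``; the per-node
    embeddings of every round are concatenated, which keeps the map exactly
    permutation-equivariant.
    """

    def __init__(self, in_dim: int, config: PositionModelConfig) -> None:
        rng = np.random.default_rng(config.encoder_seed)
        self.eps = config.eps
        self.weights = []
        dim = in_dim
        for _ in range(config.n_layers):
            W = rng.standard_normal((dim, config.hidden_dim)) / np.sqrt(dim)
            b = rng.standard_normal(config.hidden_dim) * 0.01
            self.weights.append((W, b))
            dim = config.hidden_dim

    def encode(self, mol: MolGraph) -> np.ndarray:
        h = node_features(mol)
        A = adjacency(mol)
        outs = [h]
        for W, b in self.weights:
            h = np.maximum(((1.0 + self.eps) * h + A @ h) @ W + b, 0.0)
            outs.append(h)
        return np.concatenate(outs, axis=1)


@dataclass
class PositionModel:
    """Trained node regressor: molecule -> predicted per-atom frequencies."""

    config: PositionModelConfig
    encoder: _GINEncoder
    head: object  # fitted sklearn regressor
    train_loss_curve: tuple[float, ...] = ()

    def predict(self, mol: MolGraph) -> np.ndarray:
        X = self.encoder.encode(mol)
        return np.asarray(self.head.predict(X), dtype=np.float64)

    def weights_hash(self) -> str:
        """Stable digest of the fitted parameters (reproducibility check)."""
        h = hashlib.sha256()
        if hasattr(self.head, "coefs_"):
            for W in self.head.coefs_:
                h.update(np.ascontiguousarray(W).tobytes())
            for b in self.head.intercepts_:
                h.update(np.ascontiguousarray(b).tobytes())
        else:
            h.update(repr(self.head).encode())
            preds = self.head.predict(np.zeros((1, self._n_features())))
            h.update(np.asarray(preds).tobytes())
        return h.hexdigest()

    def _n_features(self) -> int:
        W0 = self.encoder.weights[0][0]
        return W0.shape[0] + sum(W.shape[1] for W, _ in self.encoder.weights)


class EmptyDatasetError(ValueError):
    pass


def train_position_model(
    data: HistoryDataset, config: PositionModelConfig | None = None
) -> PositionModel:
    """Fit the node regressor on harvested frequency records."""
    if config is None:
        config = PositionModelConfig()
    if len(data) == 0:
        raise EmptyDatasetError("cannot train on an empty history dataset")
    in_dim = node_features(data.records[0].molecule).shape[1]
    encoder = _GINEncoder(in_dim, config)
    X = np.concatenate([encoder.encode(r.molecule) for r in data.records])
    y = np.concatenate([np.asarray(r.counts, dtype=np.float64) for r in data.records])

    if config.loss == "mse":
        from sklearn.neural_network import MLPRegressor

        head = MLPRegressor(
            hidden_layer_sizes=config.hidden_layer_sizes,
            max_iter=config.max_iter,
            random_state=config.seed,
            early_stopping=False,
        )
        head.fit(X, y)
        curve = tuple(float(v) for v in head.loss_curve_)
    else:
        from sklearn.ensemble import HistGradientBoostingRegressor

        head = HistGradientBoostingRegressor(
            loss="poisson", random_state=config.seed, max_iter=config.max_iter
        )
        head.fit(X, np.maximum(y, 0.0))
        curve = tuple(-float(v) for v in getattr(head, "train_score_", []))
    return PositionModel(config=config, encoder=encoder, head=head,
                         train_loss_curve=curve)


def predict_positions(
    model: "PositionModel | UniformPositionPolicy | None",
    mol: MolGraph,
    K: int,
    rng: np.random.Generator,
) -> tuple[list[int], int]:
    """Top-K candidate positions and one uniformly sampled position.

    Ties in predicted frequency break toward the lower atom index. A
    ``None`` / uniform model degenerates to K = n with uniform sampling
    (the random-position ablation).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = mol.num_atoms
    if model is None or isinstance(model, UniformPositionPolicy):
        candidates = list(range(n))
    else:
        scores = model.predict(mol)
        order = sorted(range(n), key=lambda i: (-scores[i], i))
        candidates = sorted(order[: min(K, n)])
    pick = candidates[int(rng.integers(len(candidates)))]
    return candidates, pick


class UniformPositionPolicy:
    """Degenerate position policy: every atom, uniform (the wo-pos mode)."""

    def predict(self, mol: MolGraph) -> np.ndarray:
        return np.zeros(mol.num_atoms)
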