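"""Molecular graph data model, validity checking, similarity and I/O.

Molecules are 2-D heavy-atom graphs with implicit hydrogens. All editing
elsewhere in the package operates on kekulized copies so bond-order
arithmetic stays integral; aromaticity is re-perceived on serialization.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MolGraph",
    "SimilarityScore",
    "MoleculeFormatError",
    "DisconnectedMoleculeError",
    "ELEMENT_VOCABULARY",
    "MAX_VALENCE",
    "parse_molecule",
    "check_valence",
    "similarity",
    "canonical_form",
    "read_smiles_file",
    "write_smiles_file",
    "read_sdf",
    "write_sdf",
]

#: Editable element vocabulary (neutral atoms only) and the maximum total
#: bond order each element supports; multi-valent P/S use their highest
#: common valence since implicit hydrogens fill any remaining capacity.
ELEMENT_VOCABULARY: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br")
MAX_VALENCE: dict[str, int] = {
    "C": 4,
    "N": 3,
    "O": 2,
    "F": 1,
    "P": 5,
    "S": 6,
    "Cl": 1,
    "Br": 1,
}

_FP_RADIUS = 2
_FP_BITS = 2048


class MoleculeFormatError(ValueError):
    """Raised when a molecule cannot be parsed or serialized."""


class DisconnectedMoleculeError(ValueError):
    """Raised when a multi-fragment molecule is supplied where one connected
    graph is required."""


class MolGraph:
    """An attributed, connected molecular graph (the annealer state).

    Wraps a sanitized RDKit molecule. Atom indices are 0-based and dense;
    hydrogens are implicit. Instances compare equal iff their canonical
    SMILES agree, so equality is invariant under atom reindexing.

    Parameters
    ----------
    rdmol:
        A sanitized RDKit ``Mol``. A defensive copy is stored.
    provenance:
        Free-text origin tag (e.g. fragment id), carried through edits.
    """

    __slots__ = ("_mol", "provenance", "_canonical")

    def __init__(self, rdmol: Chem.Mol, provenance: str = "") -> None:
        if rdmol is None or rdmol.GetNumAtoms() == 0:
            raise MoleculeFormatError("molecule must contain at least one atom")
        if len(Chem.GetMolFrags(rdmol)) != 1:
            raise DisconnectedMoleculeError(
                "MolGraph requires a connected graph; split fragments first"
            )
        self._mol = Chem.Mol(rdmol)
        self.provenance = provenance
        self._canonical: str | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def num_atoms(self) -> int:
        return self._mol.GetNumAtoms()

    @property
    def atoms(self) -> list[tuple[str, int, int]]:
        """Ordered ``(element, formal charge, implicit H count)`` triples."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in self._mol.GetAtoms()
        ]

    @property
    def bonds(self) -> frozenset[tuple[int, int, float]]:
        """Unordered, unique ``(i, j, order)`` with i < j; aromatic = 1.5."""
        out = set()
        for b in self._mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i > j:
                i, j = j, i
            out.add((i, j, b.GetBondTypeAsDouble()))
        return frozenset(out)

    def neighbors(self, idx: int) -> list[int]:
        return [n.GetIdx() for n in self._mol.GetAtomWithIdx(idx).GetNeighbors()]

    def degree(self, idx: int) -> int:
        return self._mol.GetAtomWithIdx(idx).GetDegree()

    def ring_atoms(self) -> set[int]:
        info = self._mol.GetRingInfo()
        return {i for ring in info.AtomRings() for i in ring}

    def to_rdkit(self, kekulized: bool = False) -> Chem.Mol:
        """Return a copy of the wrapped molecule, optionally kekulized with
        explicit integer bond orders."""
        mol = Chem.Mol(self._mol)
        if kekulized:
            Chem.Kekulize(mol, clearAromaticFlags=True)
        return mol

    # -- canonical form ----------------------------------------------------

    @property
    def canonical(self) -> str:
        if self._canonical is None:
            try:
                self._canonical = Chem.MolToSmiles(self._mol)
            except Exception as exc:  # pragma: no cover - rdkit internal
                raise MoleculeFormatError(f"cannot serialize molecule: {exc}")
        return self._canonical

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolGraph):
            return NotImplemented
        return self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MolGraph({self.canonical!r})"


@dataclass(frozen=True)
class SimilarityScore:
    """Tanimoto coefficient of circular fingerprints, in [0, 1]."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"similarity outside [0,1]: {self.value}")

    def __float__(self) -> float:
        return self.value


def parse_molecule(text: str, provenance: str = "") -> MolGraph:
    """Parse a SMILES string into a sanitized, connected :class:`MolGraph`.

    Multi-fragment (dot-separated) inputs are rejected with
    :class:`DisconnectedMoleculeError`.
    """
    if not text or not text.strip():
        raise MoleculeFormatError("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise MoleculeFormatError(f"unparsable SMILES: {text!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise DisconnectedMoleculeError(f"multi-fragment SMILES: {text!r}")
    return MolGraph(mol, provenance=provenance)


def _allowed_valence(symbol: str, charge: int) -> int | None:
    """Maximum total bond order for an atom, or None if unknown."""
    if symbol in MAX_VALENCE:
        base = MAX_VALENCE[symbol]
        if charge == 0:
            return base
        # cations of N/P/S gain a bond, anions of N/O/S lose one
        if symbol in ("N", "P", "O", "S"):
            return max(base + charge, 0)
        return base
    table = Chem.GetPeriodicTable()
    try:
        default = table.GetDefaultValence(symbol)
    except Exception:
        return None
    return default if default >= 0 else None


def check_valence(mol: MolGraph) -> bool:
    """True iff every atom's bond-order sum fits its element's capacity.

    Total function: chemically absurd but structurally well-formed graphs
    return ``False`` rather than raising. Works on the kekulized graph so
    aromatic orders are integral.
    """
    try:
        rdmol = mol.to_rdkit(kekulized=True)
    except Exception:
        return False
    for atom in rdmol.GetAtoms():
        allowed = _allowed_valence(atom.GetSymbol(), atom.GetFormalCharge())
        if allowed is None:
            return False
        order_sum = sum(
            int(b.GetBondTypeAsDouble()) for b in atom.GetBonds()
        )
        if order_sum > allowed:
            return False
    return True


@functools.lru_cache(maxsize=1)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def fingerprint(mol: MolGraph, radius: int = _FP_RADIUS, n_bits: int = _FP_BITS):
    """Circular (Morgan-type) bit fingerprint of a molecule."""
    return _morgan_generator(radius, n_bits).GetFingerprint(mol.to_rdkit())


def similarity(
    a: MolGraph,
    b: MolGraph,
    radius: int = _FP_RADIUS,
    n_bits: int = _FP_BITS,
) -> SimilarityScore:
    """Tanimoto coefficient of the two molecules' circular fingerprints."""
    fa = fingerprint(a, radius, n_bits)
    fb = fingerprint(b, radius, n_bits)
    return SimilarityScore(TanimotoSimilarity(fa, fb))


def canonical_form(mol: MolGraph) -> str:
    """Canonical SMILES; equal graphs map to equal strings."""
    return mol.canonical


# -- file I/O ---------------------------------------------------------------


def read_smiles_file(path: str | Path, skip_invalid: bool = False) -> list[MolGraph]:
    """Read a one-molecule-per-line SMILES file (optional name column)."""
    mols: list[MolGraph] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
        try:
            mols.append(parse_molecule(smiles, provenance=name))
        except (MoleculeFormatError, DisconnectedMoleculeError):
            if not skip_invalid:
                raise
    return mols


def write_smiles_file(path: str | Path, mols: Iterable[MolGraph]) -> None:
    lines = [f"{m.canonical}\t{m.provenance}".rstrip() for m in mols]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sdf(path: str | Path, skip_invalid: bool = False) -> list[MolGraph]:
    mols: list[MolGraph] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            if skip_invalid:
                continue
            raise MoleculeFormatError(f"unreadable SDF record #{i}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{i}"
        try:
            mols.append(MolGraph(mol, provenance=name))
        except DisconnectedMoleculeError:
            if not skip_invalid:
                raise
    return mols


def write_sdf(
    path: str | Path,
    mols: Sequence[MolGraph],
    properties: Sequence[dict] | None = None,
) -> None:
    """Write molecules to SDF; ``properties[i]`` become SD tags of record i."""
    writer = Chem.SDWriter(str(path))
    try:
        for i, m in enumerate(mols):
            rdmol = m.to_rdkit()
            rdmol.SetProp("_Name", m.provenance or f"mol{i}")
            if properties is not None:
                for key, val in properties[i].items():
                    rdmol.SetProp(str(key), str(val))
            writer.write(rdmol)
    finally:
        writer.close()


def iter_unique(mols: Iterable[MolGraph]) -> Iterator[MolGraph]:
    """Yield molecules with duplicate canonical forms removed (order kept)."""
    seen: set[str] = set()
    for m in mols:
        if m.canonical not in seen:
            seen.add(m.canonical)
            yield m
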