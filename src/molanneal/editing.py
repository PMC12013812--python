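"""The complete single-step edit operator set and candidate generation.

Four operators — insertion, replacement, deletion, cyclization — each make
one local change to a heavy-atom graph. Together they are complete: any
valence-valid molecule is reachable from a single atom (grow operators) and
any molecule can be turned into any other (delete to a common substructure,
then grow), which :func:`edit_path_exists` demonstrates constructively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from rdkit import Chem

from .molgraph import (
    ELEMENT_VOCABULARY,
    MAX_VALENCE,
    MolGraph,
    check_valence,
    parse_molecule,
)

__all__ = [
    "OPERATORS",
    "BOND_ORDERS",
    "RING_SIZE_WINDOW",
    "EditAction",
    "EditProposal",
    "ValenceEditError",
    "DuplicateBondError",
    "RingSizeError",
    "DegenerateInputError",
    "EmptyResultError",
    "NoEditError",
    "insertion",
    "deletion",
    "deletion_components",
    "replacement",
    "cyclization",
    "enumerate_edits",
    "propose",
    "edit_path_exists",
]

OPERATORS: tuple[str, ...] = ("insertion", "replacement", "deletion", "cyclization")
BOND_ORDERS: tuple[int, ...] = (1, 2, 3)
RING_SIZE_WINDOW: tuple[int, int] = (3, 8)
#: Components smaller than this are discarded by deletion when the parent
#: has at least 3 atoms (prevents collapse to single atoms).
MIN_COMPONENT_ATOMS = 2

_BOND_TYPE = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


class EditError(ValueError):
    """Base class for invalid edit requests."""


class ValenceEditError(EditError):
    pass


class DuplicateBondError(EditError):
    pass


class RingSizeError(EditError):
    pass


class DegenerateInputError(EditError):
    pass


class EmptyResultError(EditError):
    """Deletion left no component passing the validity / size filters."""


class NoEditError(EditError):
    """No valid edit of any kind exists at the requested position."""


@dataclass(frozen=True)
class EditAction:
    """One local modification: operator kind, anchor position, payload.

    Payloads: insertion ``(element, order)``; replacement ``element``;
    deletion ``None``; cyclization ``(partner index, order)``.
    """

    kind: str
    position: int
    payload: Any = None

    def __post_init__(self) -> None:
        if self.kind not in OPERATORS:
            raise ValueError(f"unknown operator: {self.kind}")


@dataclass(frozen=True)
class EditProposal:
    """A candidate molecule produced by one action on a parent.

    ``index_map`` maps each parent atom index to its child index, or None
    for atoms removed by the edit; used for frequency-matrix transfer.
    """

    action: EditAction
    parent: MolGraph
    result: MolGraph
    valid: bool
    index_map: tuple[int | None, ...] = field(default=(), repr=False)


def _editable(mol: MolGraph) -> Chem.RWMol:
    return Chem.RWMol(mol.to_rdkit(kekulized=True))


def _finalize(rw: Chem.RWMol, provenance: str) -> MolGraph:
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return MolGraph(mol, provenance=provenance)


def _order_sum(atom: Chem.Atom) -> int:
    return sum(int(b.GetBondTypeAsDouble()) for b in atom.GetBonds())


def free_valence(mol: MolGraph, pos: int) -> int:
    """Remaining bonding capacity of the (neutral) atom at ``pos``."""
    rdmol = mol.to_rdkit(kekulized=True)
    atom = rdmol.GetAtomWithIdx(pos)
    cap = MAX_VALENCE.get(atom.GetSymbol())
    if cap is None:
        return 0
    cap += atom.GetFormalCharge() if atom.GetSymbol() in ("N", "P", "O", "S") else 0
    return max(cap - _order_sum(atom), 0)


def _check_pos(mol: MolGraph, pos: int) -> None:
    if not 0 <= pos < mol.num_atoms:
        raise IndexError(f"position {pos} out of range for {mol.num_atoms} atoms")


def insertion(mol: MolGraph, pos: int, element: str, order: int = 1) -> MolGraph:
    """Append one new atom bonded to ``pos``; existing indices unchanged."""
    _check_pos(mol, pos)
    if element not in ELEMENT_VOCABULARY:
        raise ValueError(f"element {element!r} not in vocabulary")
    if order not in BOND_ORDERS:
        raise ValueError(f"unsupported bond order {order}")
    if free_valence(mol, pos) < order:
        raise ValenceEditError(f"atom {pos} lacks free valence for order {order}")
    if MAX_VALENCE[element] < order:
        raise ValenceEditError(f"{element} cannot support a bond of order {order}")
    rw = _editable(mol)
    new_idx = rw.AddAtom(Chem.Atom(element))
    rw.AddBond(pos, new_idx, _BOND_TYPE[order])
    return _finalize(rw, mol.provenance)


def deletion_components(mol: MolGraph, pos: int) -> list[tuple[MolGraph, tuple[int | None, ...]]]:
    """Remove the atom at ``pos``; return surviving connected components.

    Each entry is ``(component, index_map)`` where ``index_map`` maps parent
    atom indices to component indices (None for atoms absent from that
    component). Components failing the valence check are discarded; when the
    parent has >= 3 atoms, sub-floor (single-atom) components are discarded
    too, unless no component meets the floor — then all valid components are
    kept so deletion of a small molecule's linker still yields candidates.
    """
    _check_pos(mol, pos)
    if mol.num_atoms < 2:
        raise DegenerateInputError("cannot delete the only atom")
    rw = _editable(mol)
    rw.RemoveAtom(pos)
    # RDKit reindexes: parent atom i maps to i when i < pos, i-1 when i > pos
    pruned = rw.GetMol()
    frag_ids = list(Chem.GetMolFrags(pruned))  # tuples of pruned-mol indices
    if mol.num_atoms >= 3 and any(len(f) >= MIN_COMPONENT_ATOMS for f in frag_ids):
        frag_ids = [f for f in frag_ids if len(f) >= MIN_COMPONENT_ATOMS]
    out: list[tuple[MolGraph, tuple[int | None, ...]]] = []
    for frag in frag_ids:
        sub = Chem.RWMol()
        local = {}
        for new_i, old_i in enumerate(frag):
            a = pruned.GetAtomWithIdx(old_i)
            na = Chem.Atom(a.GetSymbol())
            na.SetFormalCharge(a.GetFormalCharge())
            sub.AddAtom(na)
            local[old_i] = new_i
        for b in pruned.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in local and j in local:
                sub.AddBond(local[i], local[j], b.GetBondType())
        try:
            comp = _finalize(sub, mol.provenance)
        except Exception:
            continue
        if not check_valence(comp):
            continue
        idx_map: list[int | None] = []
        for parent_i in range(mol.num_atoms):
            if parent_i == pos:
                idx_map.append(None)
            else:
                pruned_i = parent_i if parent_i < pos else parent_i - 1
                idx_map.append(local.get(pruned_i))
        out.append((comp, tuple(idx_map)))
    return out


def deletion(
    mol: MolGraph, pos: int, rng: np.random.Generator
) -> tuple[list[MolGraph], MolGraph]:
    """Delete the atom at ``pos`` and sample one surviving component.

    Returns ``(all surviving components, the sampled component)``.
    """
    comps = deletion_components(mol, pos)
    if not comps:
        raise EmptyResultError(f"deletion at {pos} leaves no usable component")
    pick = int(rng.integers(len(comps)))
    return [c for c, _ in comps], comps[pick][0]


def replacement(mol: MolGraph, pos: int, element: str) -> MolGraph:
    """Swap the element at ``pos``; bonds unchanged, hydrogens recomputed."""
    _check_pos(mol, pos)
    if element not in ELEMENT_VOCABULARY:
        raise ValueError(f"element {element!r} not in vocabulary")
    rdmol = mol.to_rdkit(kekulized=True)
    atom = rdmol.GetAtomWithIdx(pos)
    if atom.GetSymbol() == element:
        raise ValueError("replacement element equals current element")
    if _order_sum(atom) > MAX_VALENCE[element]:
        raise ValenceEditError(
            f"{element} valence {MAX_VALENCE[element]} < bond sum at {pos}"
        )
    rw = Chem.RWMol(rdmol)
    new_atom = Chem.Atom(element)
    rw.ReplaceAtom(pos, new_atom)
    return _finalize(rw, mol.provenance)


def cyclization(
    mol: MolGraph,
    pos_a: int,
    pos_b: int,
    order: int = 1,
    ring_window: tuple[int, int] = RING_SIZE_WINDOW,
) -> MolGraph:
    """Add a bond between two unbonded atoms, closing exactly one new ring."""
    _check_pos(mol, pos_a)
    _check_pos(mol, pos_b)
    if pos_a == pos_b:
        raise ValueError("cyclization endpoints must differ")
    if order not in BOND_ORDERS:
        raise ValueError(f"unsupported bond order {order}")
    rdmol = mol.to_rdkit(kekulized=True)
    if rdmol.GetBondBetweenAtoms(pos_a, pos_b) is not None:
        raise DuplicateBondError(f"atoms {pos_a},{pos_b} already bonded")
    path = Chem.GetShortestPath(rdmol, pos_a, pos_b)
    ring_size = len(path)  # path includes both endpoints; new ring = path + bond
    lo, hi = ring_window
    if not lo <= ring_size <= hi:
        raise RingSizeError(f"new ring size {ring_size} outside [{lo},{hi}]")
    if free_valence(mol, pos_a) < order or free_valence(mol, pos_b) < order:
        raise ValenceEditError("insufficient free valence at a ring endpoint")
    rw = Chem.RWMol(rdmol)
    rw.AddBond(pos_a, pos_b, _BOND_TYPE[order])
    return _finalize(rw, mol.provenance)


def _identity_map(n: int) -> tuple[int, ...]:
    return tuple(range(n))


def enumerate_edits(
    mol: MolGraph,
    pos: int,
    operators: Sequence[str] = OPERATORS,
    vocabulary: Sequence[str] = ELEMENT_VOCABULARY,
    orders: Sequence[int] = BOND_ORDERS,
    ring_window: tuple[int, int] = RING_SIZE_WINDOW,
) -> list[EditProposal]:
    """Every valid single edit at ``pos``, in deterministic order.

    Order: insertion (element-major, then bond order), replacement
    (vocabulary order), deletion (component order), cyclization (partner
    ascending, then bond order). All returned proposals are valid.
    """
    _check_pos(mol, pos)
    n = mol.num_atoms
    proposals: list[EditProposal] = []

    if "insertion" in operators:
        for element in vocabulary:
            for order in orders:
                try:
                    child = insertion(mol, pos, element, order)
                except (EditError, ValueError):
                    continue
                action = EditAction("insertion", pos, (element, order))
                proposals.append(
                    EditProposal(action, mol, child, True, _identity_map(n))
                )

    if "replacement" in operators:
        for element in vocabulary:
            try:
                child = replacement(mol, pos, element)
            except (EditError, ValueError):
                continue
            action = EditAction("replacement", pos, element)
            proposals.append(EditProposal(action, mol, child, True, _identity_map(n)))

    if "deletion" in operators and n >= 2:
        for comp, idx_map in deletion_components(mol, pos):
            action = EditAction("deletion", pos, None)
            proposals.append(EditProposal(action, mol, comp, True, idx_map))

    if "cyclization" in operators:
        for partner in range(n):
            if partner == pos:
                continue
            for order in orders:
                try:
                    child = cyclization(mol, pos, partner, order, ring_window)
                except (EditError, ValueError):
                    continue
                action = EditAction("cyclization", pos, (partner, order))
                proposals.append(
                    EditProposal(action, mol, child, True, _identity_map(n))
                )

    return proposals


def propose(
    mol: MolGraph,
    pos: int,
    op_weights: dict[str, float] | Sequence[float] | None,
    rng: np.random.Generator,
    payload_rng: np.random.Generator | None = None,
    ring_window: tuple[int, int] = RING_SIZE_WINDOW,
) -> EditProposal:
    """Sample one edit at ``pos``: operator from ``op_weights``, then a
    uniformly chosen valid payload for that operator.

    If the drawn operator has no valid edit at ``pos`` the weights are
    renormalized over operators that do. Raises :class:`NoEditError` when no
    operator has a valid edit (caller re-samples the position).
    """
    if payload_rng is None:
        payload_rng = rng
    weights = _normalize_weights(op_weights)
    pools = {
        op: enumerate_edits(mol, pos, operators=(op,), ring_window=ring_window)
        for op in OPERATORS
    }
    feasible = [op for op in OPERATORS if pools[op]]
    if not feasible:
        raise NoEditError(f"no valid edit at position {pos}")
    p = np.array([weights[op] if op in feasible else 0.0 for op in OPERATORS])
    if p.sum() <= 0:
        p = np.array([1.0 if op in feasible else 0.0 for op in OPERATORS])
    p = p / p.sum()
    op = OPERATORS[int(rng.choice(len(OPERATORS), p=p))]
    pool = pools[op]
    return pool[int(payload_rng.integers(len(pool)))]


def _normalize_weights(
    op_weights: dict[str, float] | Sequence[float] | None,
) -> dict[str, float]:
    if op_weights is None:
        return {op: 0.25 for op in OPERATORS}
    if isinstance(op_weights, dict):
        w = {op: float(op_weights.get(op, 0.0)) for op in OPERATORS}
    else:
        if len(op_weights) != len(OPERATORS):
            raise ValueError("op_weights must cover all four operators")
        w = dict(zip(OPERATORS, map(float, op_weights)))
    total = sum(w.values())
    if total <= 0:
        raise ValueError("op_weights must have positive mass")
    return {op: v / total for op, v in w.items()}


# -- constructive edit-path search ------------------------------------------


def edit_path_exists(
    a: MolGraph, b: MolGraph, max_steps: int
) -> tuple[bool, list[EditProposal]]:
    """Search for an edit sequence transforming ``a`` into ``b``.

    Strategy: delete down to a maximum common substructure of the two
    molecules, then grow toward ``b`` with insertion / replacement /
    cyclization. Falls back to shrinking ``a`` to a single atom when the
    common substructure is unusable (e.g. extra bonds among its atoms).
    Returns ``(found, path)``; the path re-applies cleanly via the real
    operators.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 1")
    if a == b:
        return True, []
    pivots = [
        _mcs_pivot(a, b, match_elements=True),
        _mcs_pivot(a, b, match_elements=False),
        None,
    ]
    best: list[EditProposal] | None = None
    for pivot in pivots:
        found, path = _plan_path(a, b, pivot, max_steps)
        if found and (best is None or len(path) < len(best)):
            best = path
    if best is not None:
        return True, best
    return False, []


def _mcs_pivot(
    a: MolGraph, b: MolGraph, match_elements: bool = True
) -> tuple[tuple[int, ...], tuple[int, ...]] | None:
    """Atom index tuples (in a, in b) of a connected MCS, or None.

    With ``match_elements=False`` the skeleton may match across elements;
    the planner fixes mismatches with replacement steps.
    """
    from rdkit.Chem import rdFMCS

    try:
        res = rdFMCS.FindMCS(
            [a.to_rdkit(kekulized=True), b.to_rdkit(kekulized=True)],
            atomCompare=(
                rdFMCS.AtomCompare.CompareElements
                if match_elements
                else rdFMCS.AtomCompare.CompareAny
            ),
            bondCompare=rdFMCS.BondCompare.CompareOrderExact,
            timeout=5,
        )
    except Exception:
        return None
    if res.canceled or res.numAtoms == 0:
        return None
    patt = Chem.MolFromSmarts(res.smartsString)
    if patt is None:
        return None
    ma = a.to_rdkit(kekulized=True).GetSubstructMatch(patt)
    mb = b.to_rdkit(kekulized=True).GetSubstructMatch(patt)
    if not ma or not mb:
        return None
    return tuple(ma), tuple(mb)


def _plan_path(
    a: MolGraph,
    b: MolGraph,
    pivot: tuple[tuple[int, ...], tuple[int, ...]] | None,
    max_steps: int,
) -> tuple[bool, list[EditProposal]]:
    try:
        return _plan_path_inner(a, b, pivot, max_steps)
    except (EditError, ValueError, IndexError):
        return False, []


def _plan_path_inner(a, b, pivot, max_steps):
    path: list[EditProposal] = []
    cur = a
    # live map: b atom index -> current-molecule atom index (for kept atoms)
    if pivot is None:
        keep_a: set[int] = {0}  # arbitrary single-atom pivot
    else:
        ma, mb = pivot
        keep_a = set(ma)

    # --- phase 1: delete non-pivot atoms of a, outside-in -------------------
    cur_of_a = {i: i for i in range(a.num_atoms)}  # a index -> current index
    while len(cur_of_a) > len(keep_a):
        target = _peel_atom(cur, {cur_of_a[i] for i in keep_a})
        comps = deletion_components(cur, target)
        chosen = None
        for comp, idx_map in comps:
            if all(idx_map[cur_of_a[i]] is not None for i in keep_a):
                chosen = (comp, idx_map)
                break
        if chosen is None:
            raise EditError("pivot component filtered out")
        comp, idx_map = chosen
        path.append(
            EditProposal(EditAction("deletion", target, None), cur, comp, True, idx_map)
        )
        cur_of_a = {
            i: idx_map[ci]
            for i, ci in cur_of_a.items()
            if idx_map[ci] is not None
        }
        cur = comp
    if pivot is None:
        # cur is a single atom; align its element with an arbitrary b atom
        b_root = 0
        want = b.atoms[b_root][0]
        have = cur.atoms[0][0]
        if want != have:
            child = replacement(cur, 0, want)
            path.append(
                EditProposal(
                    EditAction("replacement", 0, want), cur, child, True, (0,)
                )
            )
            cur = child
        mapping_b2cur = {b_root: 0}
    else:
        mapping_b2cur = {bi: cur_of_a[ai] for bi, ai in zip(pivot[1], pivot[0])}
        # phase 1.5: fix element mismatches on mapped atoms by replacement
        for bi in sorted(mapping_b2cur):
            ci = mapping_b2cur[bi]
            want = b.atoms[bi][0]
            if cur.atoms[ci][0] != want:
                child = replacement(cur, ci, want)
                path.append(
                    EditProposal(
                        EditAction("replacement", ci, want), cur, child, True,
                        _identity_map(cur.num_atoms),
                    )
                )
                cur = child
        _check_pivot_subgraph(cur, b, mapping_b2cur)

    # --- phase 2: insert missing atoms of b in BFS order from the pivot -----
    b_kek = b.to_rdkit(kekulized=True)
    order_of = {}
    for bond in b_kek.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order_of[(i, j)] = order_of[(j, i)] = int(bond.GetBondTypeAsDouble())
    placed = set(mapping_b2cur)
    bfs_parent: dict[int, int] = {}
    seen = set(placed)
    queue = sorted(placed)
    while queue:
        u = queue.pop(0)
        for nb in b_kek.GetAtomWithIdx(u).GetNeighbors():
            v = nb.GetIdx()
            if v not in seen:
                seen.add(v)
                bfs_parent[v] = u
                queue.append(v)
    # insert in BFS discovery order so each new atom's parent is placed
    disc = [v for v in _bfs_order(b_kek, sorted(placed)) if v not in placed]
    for v in disc:
        p = bfs_parent[v]
        child = insertion(
            cur, mapping_b2cur[p], b.atoms[v][0], order_of[(p, v)]
        )
        path.append(
            EditProposal(
                EditAction("insertion", mapping_b2cur[p], (b.atoms[v][0], order_of[(p, v)])),
                cur,
                child,
                True,
                _identity_map(cur.num_atoms),
            )
        )
        mapping_b2cur[v] = cur.num_atoms  # appended index
        cur = child

    # --- phase 3: close remaining bonds of b by cyclization -----------------
    for bond in b_kek.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        ci, cj = mapping_b2cur[i], mapping_b2cur[j]
        if cur.to_rdkit().GetBondBetweenAtoms(ci, cj) is not None:
            continue
        child = cyclization(cur, ci, cj, order_of[(i, j)])
        path.append(
            EditProposal(
                EditAction("cyclization", ci, (cj, order_of[(i, j)])),
                cur,
                child,
                True,
                _identity_map(cur.num_atoms),
            )
        )
        cur = child

    if cur != b or len(path) > max_steps:
        return False, []
    return True, path


def _bfs_order(rdmol: Chem.Mol, sources: list[int]) -> list[int]:
    seen = set(sources)
    queue = list(sources)
    order = []
    while queue:
        u = queue.pop(0)
        order.append(u)
        for nb in rdmol.GetAtomWithIdx(u).GetNeighbors():
            v = nb.GetIdx()
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return order


def _peel_atom(mol: MolGraph, keep: set[int]) -> int:
    """A deletable atom outside ``keep``: a leaf of a BFS tree rooted at
    ``keep`` (deepest first), so removal keeps the rest connected."""
    rdmol = mol.to_rdkit()
    depth = {i: 0 for i in keep}
    queue = sorted(keep)
    order = []
    while queue:
        u = queue.pop(0)
        order.append(u)
        for nb in rdmol.GetAtomWithIdx(u).GetNeighbors():
            v = nb.GetIdx()
            if v not in depth:
                depth[v] = depth[u] + 1
                queue.append(v)
    candidates = [i for i in depth if i not in keep]
    if not candidates:
        raise EditError("nothing to peel")
    return max(candidates, key=lambda i: (depth[i], i))


def _check_pivot_subgraph(cur: MolGraph, b: MolGraph, mapping_b2cur: dict[int, int]) -> None:
    """The shrunken molecule must be exactly an induced subgraph of b with
    matching elements and bond orders; otherwise growing cannot reach b."""
    cur_kek = cur.to_rdkit(kekulized=True)
    b_kek = b.to_rdkit(kekulized=True)
    if len(mapping_b2cur) != cur.num_atoms:
        raise EditError("pivot mapping incomplete")
    for bi, ci in mapping_b2cur.items():
        if b_kek.GetAtomWithIdx(bi).GetSymbol() != cur_kek.GetAtomWithIdx(ci).GetSymbol():
            raise EditError("pivot element mismatch")
    cur_of_b = mapping_b2cur
    for bond in cur_kek.GetBonds():
        ci, cj = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bi = next(k for k, v in cur_of_b.items() if v == ci)
        bj = next(k for k, v in cur_of_b.items() if v == cj)
        bbond = b_kek.GetBondBetweenAtoms(bi, bj)
        if bbond is None or int(bbond.GetBondTypeAsDouble()) != int(
            bond.GetBondTypeAsDouble()
        ):
            raise EditError("pivot bond not present in target")
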