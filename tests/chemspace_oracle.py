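"""Independent brute-force oracles used by the test suite.

Everything here is coded directly against RDKit primitives — never against
the package under test — so set comparisons are genuine dual-route checks.
"""

import itertools

from rdkit import Chem

ORACLE_VALENCE = {"C": 4, "N": 3, "O": 2}
_BT = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def build_canonical(elements, bonds):
    """Canonical SMILES of an explicit graph, or None if unsanitizable.

    ``bonds`` is a list of ((i, j), order) with integer orders.
    """
    rw = Chem.RWMol()
    for sym in elements:
        rw.AddAtom(Chem.Atom(sym))
    for (i, j), order in bonds:
        rw.AddBond(i, j, _BT[order])
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def _connected(n, present_edges):
    if n == 1:
        return True
    adj = {i: set() for i in range(n)}
    for i, j in present_edges:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = {0}, [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


def enumerate_chemical_space(max_atoms=4, elements=("C", "N", "O")):
    """All valence-valid connected molecules over ``elements`` with at most
    ``max_atoms`` heavy atoms, as a set of canonical SMILES. Exhaustive
    enumeration over labeled graphs, deduplicated by canonicalization."""
    space = set()
    for n in range(1, max_atoms + 1):
        pairs = list(itertools.combinations(range(n), 2))
        for orders in itertools.product((0, 1, 2, 3), repeat=len(pairs)):
            present = [p for p, o in zip(pairs, orders) if o]
            if not _connected(n, present):
                continue
            bond_sum = [0] * n
            for (i, j), o in zip(pairs, orders):
                bond_sum[i] += o
                bond_sum[j] += o
            for elems in itertools.product(elements, repeat=n):
                if any(
                    bond_sum[i] > ORACLE_VALENCE[elems[i]] for i in range(n)
                ):
                    continue
                bonds = [(p, o) for p, o in zip(pairs, orders) if o]
                smi = build_canonical(elems, bonds)
                if smi is not None:
                    space.add(smi)
    return space


def brute_force_edits_at(mol_smiles, pos, elements=("C", "N", "O"),
                         max_atoms=None, ring_window=(3, 8)):
    """All results of one valid edit at ``pos``: canonical SMILES set.

    Re-implements the four operators from scratch with raw RDKit calls and
    its own valence table.
    """
    parent = Chem.MolFromSmiles(mol_smiles)
    Chem.Kekulize(parent, clearAromaticFlags=True)
    n = parent.GetNumAtoms()
    results = set()

    def try_add(mol):
        try:
            m = Chem.Mol(mol)
            Chem.SanitizeMol(m)
        except Exception:
            return
        kek = Chem.Mol(m)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        for atom in kek.GetAtoms():
            cap = ORACLE_VALENCE.get(atom.GetSymbol())
            if cap is None:
                return
            if sum(int(b.GetBondTypeAsDouble()) for b in atom.GetBonds()) > cap:
                return
        if max_atoms is not None and m.GetNumAtoms() > max_atoms:
            return
        results.add(Chem.MolToSmiles(m))

    def order_sum(mol, idx):
        return sum(
            int(b.GetBondTypeAsDouble())
            for b in mol.GetAtomWithIdx(idx).GetBonds()
        )

    # insertion
    for elem in elements:
        for order in (1, 2, 3):
            if order_sum(parent, pos) + order > ORACLE_VALENCE[
                parent.GetAtomWithIdx(pos).GetSymbol()
            ]:
                continue
            if order > ORACLE_VALENCE[elem]:
                continue
            rw = Chem.RWMol(parent)
            new = rw.AddAtom(Chem.Atom(elem))
            rw.AddBond(pos, new, _BT[order])
            try_add(rw.GetMol())

    # replacement
    for elem in elements:
        if elem == parent.GetAtomWithIdx(pos).GetSymbol():
            continue
        if order_sum(parent, pos) > ORACLE_VALENCE[elem]:
            continue
        rw = Chem.RWMol(parent)
        rw.ReplaceAtom(pos, Chem.Atom(elem))
        try_add(rw.GetMol())

    # deletion: all surviving components (size floor when parent >= 3,
    # relaxed when nothing meets it)
    if n >= 2:
        rw = Chem.RWMol(parent)
        rw.RemoveAtom(pos)
        pruned = rw.GetMol()
        frags = list(
            Chem.GetMolFrags(pruned, asMols=True, sanitizeFrags=False)
        )
        sizes = [f.GetNumAtoms() for f in frags]
        if n >= 3 and any(s >= 2 for s in sizes):
            frags = [f for f, s in zip(frags, sizes) if s >= 2]
        for frag in frags:
            try_add(frag)

    # cyclization
    for partner in range(n):
        if partner == pos or parent.GetBondBetweenAtoms(pos, partner):
            continue
        ring = len(Chem.GetShortestPath(parent, pos, partner))
        if not ring_window[0] <= ring <= ring_window[1]:
            continue
        for order in (1, 2, 3):
            sym_a = parent.GetAtomWithIdx(pos).GetSymbol()
            sym_b = parent.GetAtomWithIdx(partner).GetSymbol()
            if order_sum(parent, pos) + order > ORACLE_VALENCE[sym_a]:
                continue
            if order_sum(parent, partner) + order > ORACLE_VALENCE[sym_b]:
                continue
            rw = Chem.RWMol(parent)
            rw.AddBond(pos, partner, _BT[order])
            try_add(rw.GetMol())

    return results
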