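import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from molanneal.annealer import AnnealSchedule
from molanneal.editing import enumerate_edits
from molanneal.molgraph import MolGraph, parse_molecule
from molanneal.position import (
    EmptyDatasetError,
    FrequencyRecord,
    HistoryDataset,
    PositionModelConfig,
    UniformPositionPolicy,
    harvest_history,
    node_features,
    predict_positions,
    train_position_model,
    transfer_frequency,
    update_frequency,
)
from molanneal.scoring import ObjectiveSpec, PharmacophoreProfile, SurrogateDockScorer


def _spec(delta=0.05):
    return ObjectiveSpec(
        dock_scorer=SurrogateDockScorer(PharmacophoreProfile()),
        alpha=1.0, beta=0.0, gamma=0.0, delta=delta, dock_sign=1,
    )


class TestUpdateFrequency:
    def test_path_center(self):
        rec = FrequencyRecord.zeros(parse_molecule("CCO"))
        rec = update_frequency(rec, 1)
        assert rec.counts == (1, 1, 1)

    def test_path_end(self):
        rec = FrequencyRecord.zeros(parse_molecule("CCO"))
        rec = update_frequency(rec, 0)
        assert rec.counts == (1, 1, 0)

    def test_single_atom(self, methane):
        rec = FrequencyRecord.zeros(methane)
        assert update_frequency(rec, 0).counts == (1,)

    def test_out_of_range(self, methane):
        with pytest.raises(IndexError):
            update_frequency(FrequencyRecord.zeros(methane), 3)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 4), min_size=1, max_size=25))
    def test_conservation_law(self, positions):
        mol = parse_molecule("CCCCC")
        rec = FrequencyRecord.zeros(mol)
        for pos in positions:
            rec = update_frequency(rec, pos)
        expected = sum(mol.degree(p) + 1 for p in positions)
        assert sum(rec.counts) == expected


class TestTransferFrequency:
    def test_insertion_appends_zero_then_increments(self, ethanol):
        rec = FrequencyRecord(ethanol, (3, 2, 1))
        edit = next(
            p for p in enumerate_edits(ethanol, 0)
            if p.action.kind == "insertion"
        )
        out = transfer_frequency(rec, edit)
        assert len(out.counts) == edit.result.num_atoms == 4
        # carried (3,2,1,0) then +1 at position 0 and its child neighbors
        nbrs = {0, *edit.result.neighbors(0)}
        expected = [c + (1 if i in nbrs else 0)
                    for i, c in enumerate((3, 2, 1, 0))]
        assert list(out.counts) == expected

    def test_insertion_sum_identity(self, ethanol):
        rec = FrequencyRecord(ethanol, (3, 2, 1))
        edit = next(
            p for p in enumerate_edits(ethanol, 0)
            if p.action.kind == "insertion"
        )
        out = transfer_frequency(rec, edit)
        deg_child = edit.result.degree(0)
        assert sum(out.counts) == sum(rec.counts) + deg_child + 1

    def test_deletion_drops_entries(self, ethanol):
        rec = FrequencyRecord(ethanol, (3, 2, 1))
        edit = next(
            p for p in enumerate_edits(ethanol, 1)
            if p.action.kind == "deletion"
        )
        out = transfer_frequency(rec, edit)
        assert len(out.counts) == edit.result.num_atoms
        surviving = [rec.counts[i] for i, c in enumerate(edit.index_map)
                     if c is not None]
        assert sorted(out.counts) == sorted(surviving)

    def test_parent_mismatch_rejected(self, ethanol, pentane):
        rec = FrequencyRecord(pentane, (0,) * 5)
        edit = enumerate_edits(ethanol, 0)[0]
        with pytest.raises(ValueError):
            transfer_frequency(rec, edit)

    def test_length_bookkeeping_chain(self, pentane):
        # a scripted insertion/deletion chain keeps counts aligned
        rng = np.random.default_rng(0)
        rec = FrequencyRecord.zeros(pentane)
        mol = pentane
        for _ in range(12):
            pool = enumerate_edits(mol, int(rng.integers(mol.num_atoms)))
            pool = [p for p in pool if p.action.kind in ("insertion", "deletion")]
            if not pool:
                continue
            edit = pool[int(rng.integers(len(pool)))]
            rec = transfer_frequency(rec, edit)
            mol = edit.result
            assert len(rec.counts) == mol.num_atoms


class TestHarvest:
    def test_empty(self, ethanol):
        data = harvest_history(ethanol, _spec(), AnnealSchedule(n_steps=10),
                               n_runs=0, seed=0)
        assert len(data) == 0

    def test_deterministic(self):
        x0 = parse_molecule("CCCCCC")
        args = (x0, _spec(), AnnealSchedule(n_steps=30))
        a = harvest_history(*args, n_runs=2, seed=5)
        b = harvest_history(*args, n_runs=2, seed=5)
        assert [(r.molecule.canonical, r.counts) for r in a.records] == [
            (r.molecule.canonical, r.counts) for r in b.records
        ]

    def test_jsonl_roundtrip(self, tmp_path):
        x0 = parse_molecule("CCCCCC")
        data = harvest_history(x0, _spec(), AnnealSchedule(n_steps=20),
                               n_runs=2, seed=1)
        assert len(data) > 0
        p = tmp_path / "hist.jsonl"
        data.save_jsonl(p)
        back = HistoryDataset.load_jsonl(p)
        assert [(r.molecule.canonical, tuple(r.counts)) for r in back.records] == [
            (r.molecule.canonical, tuple(r.counts)) for r in data.records
        ]


def _ring_biased_history(mols, n_hits=6):
    """Synthetic history: edits landed only on ring atoms."""
    data = HistoryDataset()
    for mol in mols:
        ring = sorted(mol.ring_atoms())
        if not ring:
            continue
        rec = FrequencyRecord.zeros(mol)
        for k in range(n_hits):
            rec = update_frequency(rec, ring[k % len(ring)])
        data.append(rec)
    return data


@pytest.fixture(scope="module")
def ring_model(bundle):
    mols = [m for m in bundle.all_molecules() if m.ring_atoms()][:8]
    data = _ring_biased_history(mols)
    return train_position_model(data, PositionModelConfig(max_iter=300, seed=0))


class TestTrainAndPredict:
    def test_empty_dataset_rejected(self):
        with pytest.raises(EmptyDatasetError):
            train_position_model(HistoryDataset())

    def test_loss_decreases(self, ring_model):
        curve = ring_model.train_loss_curve
        assert len(curve) > 1 and curve[-1] < curve[0]

    def test_reproducible_weights_hash(self, bundle):
        mols = [m for m in bundle.all_molecules() if m.ring_atoms()][:8]
        data = _ring_biased_history(mols)
        cfg = PositionModelConfig(max_iter=50, seed=3)
        h1 = train_position_model(data, cfg).weights_hash()
        h2 = train_position_model(data, cfg).weights_hash()
        assert h1 == h2

    def test_equivariance_under_renumbering(self, ring_model, druglike_corpus):
        mol = druglike_corpus[0]
        rd = mol.to_rdkit()
        perm = list(range(rd.GetNumAtoms()))[::-1]
        permuted = MolGraph(Chem.RenumberAtoms(rd, perm))
        p_orig = ring_model.predict(mol)
        p_perm = ring_model.predict(permuted)
        # atom i of the permuted molecule is atom perm[i] of the original
        assert np.allclose(p_perm, p_orig[perm], atol=1e-8)

    def test_recovery_ranks_ring_atoms(self, ring_model, druglike_corpus):
        held_out = [m for m in druglike_corpus[:30] if m.ring_atoms()
                    and m.num_atoms > 6]
        hits = 0
        for mol in held_out:
            cands, _ = predict_positions(ring_model, mol, K=3,
                                         rng=np.random.default_rng(0))
            if set(cands) & mol.ring_atoms():
                hits += 1
        assert hits / len(held_out) >= 0.8

    def test_poisson_loss_variant(self, bundle):
        mols = [m for m in bundle.all_molecules() if m.ring_atoms()][:6]
        data = _ring_biased_history(mols)
        model = train_position_model(
            data, PositionModelConfig(loss="poisson", max_iter=60, seed=0)
        )
        preds = model.predict(mols[0])
        assert preds.shape == (mols[0].num_atoms,)


class TestPredictPositions:
    def test_k_covers_all(self, ethanol):
        cands, pick = predict_positions(None, ethanol, K=10,
                                        rng=np.random.default_rng(0))
        assert cands == [0, 1, 2] and pick in cands

    def test_constant_predictions_tiebreak(self, pentane):
        policy = UniformPositionPolicy()

        class Wrapper:
            def predict(self, mol):
                return policy.predict(mol)

        # route constant scores through the top-K path (not the uniform
        # degenerate case) by duck-typing a PositionModel
        from molanneal import position as pos_mod

        model = pos_mod.PositionModel.__new__(pos_mod.PositionModel)
        model.config = PositionModelConfig()
        model.encoder = None
        model.head = None
        model.train_loss_curve = ()
        model.predict = lambda mol: np.zeros(mol.num_atoms)  # type: ignore
        cands, _ = predict_positions(model, pentane, K=3,
                                     rng=np.random.default_rng(0))
        assert cands == [0, 1, 2]

    def test_uniform_mode_statistics(self, pentane):
        rng = np.random.default_rng(11)
        counts = np.zeros(5)
        n = 10_000
        for _ in range(n):
            _, pick = predict_positions(None, pentane, K=5, rng=rng)
            counts[pick] += 1
        from scipy.stats import chisquare

        _, pvalue = chisquare(counts)
        assert pvalue > 1e-3

    def test_k_must_be_positive(self, ethanol):
        with pytest.raises(ValueError):
            predict_positions(None, ethanol, K=0, rng=np.random.default_rng(0))
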