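# molanneal

Adaptive simulated annealing for multi-constraint molecular graph
optimization: a single walker iteratively edits a starting fragment with a
complete four-operator set (atom insertion, atom replacement, atom
deletion, ring-closing cyclization), scores each candidate with a gated
multi-property objective (docking term + synthetic accessibility +
drug-likeness, gated by chemical validity and a similarity constraint to
the start), and decides acceptance with a Metropolis rule under a
reciprocal cooling schedule. Two extensions shape the search:

* **History-guided position prediction** — random-position runs record how
  often each atom (and its neighbors) hosted an accepted edit; a
  message-passing node regressor (GIN-style NumPy encoder + scikit-learn
  head) learns those frequencies, and edit positions are then sampled from
  the model's top-K atoms.
* **Reversible sampling** — a candidate rejected by the Metropolis draw
  gets one secondary edit; if that secondary edit beats the incumbent, the
  *original* candidate is accepted after all.

The operator set is complete: every valence-valid molecule over the
vocabulary is reachable from a single atom, and any molecule can be turned
into any other by deleting down to a common substructure and regrowing —
both properties are verified exhaustively over the ≤4-heavy-atom
{C,N,O} space in the test suite.

## Layout

| Module | Contents |
| --- | --- |
| `molanneal.molgraph` | `MolGraph` data model, valence checking, Morgan/Tanimoto similarity, SMILES/SDF I/O |
| `molanneal.editing` | the four operators, exhaustive single-edit enumeration, proposal sampling, constructive edit-path search |
| `molanneal.scoring` | gated objective (`ObjectiveSpec`, `objective`), surrogate pharmacophore docking stand-in, AutoDock-Vina subprocess adapter |
| `molanneal.position` | frequency records, history harvesting, position-model training and top-K prediction |
| `molanneal.annealer` | temperature schedule, acceptance rule, reversible step, `anneal`, ablation runner |
| `molanneal.cli_io` | campaign config (YAML), fragment-library loading with pairwise-similarity filtering, fixtures, campaign orchestration |
| `molanneal.benchmark` | deterministic offline surrogate benchmarks used by the acceptance battery |

## CLI

```bash
molanneal anneal --smiles CCCCCC --steps 500 --seed 0 --delta 0.1 --out traj.jsonl
molanneal harvest --smiles CCCCCC --runs 10 --steps 200 --out history.jsonl
molanneal train-pos --history history.jsonl --out model.pkl
molanneal anneal --smiles CCCCCC --model model.pkl
molanneal ablate --smiles CCCCC --steps 300 --seeds 0,1,2,3,4
molanneal campaign --config campaign.yaml
molanneal fixtures --out fixtures.smi
```

Campaign YAML keys mirror `molanneal.cli_io.CampaignConfig` (unknown keys
are rejected); every output embeds the config hash and seed. Canonical
SMILES output uses RDKit's default canonicalization.

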