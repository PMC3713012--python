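# crossreact3d

Grid-based molecular-field similarity and genetic-neural-network (GNN) QSAR
for predicting cross-recognition of HLA-A2-bound peptides by antigen-specific
cytotoxic T lymphocytes.

The pipeline takes a set of peptide(-MHC) structures superposed in one common
reference frame and a per-peptide cross-reactivity score, and:

1. **conformer selection** — ranks precomputed conformer clusters by
   conformational free energy `G = <W> - T*S` (Boltzmann-weighted mean
   effective energy minus temperature times the Gibbs entropy of the
   within-cluster member probabilities) and picks the cluster centre;
2. **grid fields** — evaluates a binary shape field and an electrostatic
   field (unit positive probe, distance-dependent dielectric `eps = 4r`,
   zero inside the van der Waals surface, truncated at ±5 kcal/mol) on one
   shared peptide-centred grid (0.5 Å spacing, ≥6 Å margin);
3. **similarity** — builds the double similarity matrix: Carbó index on
   shape fields (binary counting form), Hodgkin index on electrostatic
   fields;
4. **GNN QSAR** — a genetic algorithm (250 individuals × 75 generations by
   default) selects 4 similarity descriptors; a 4-1-1 sigmoid network with
   7 adjustable parameters maps them to activity; leave-one-out
   cross-validated q² is the fitness; repeated seeded runs are merged and
   consensus predictions averaged over the best models;
5. **validation** — activity-ranked train/test partitioning, external-test
   regression statistics, per-descriptor functional-dependence scans, and
   y-randomization;
6. **activity scoring** — per-clone recognition categories (+1/+2/+3/+4/−1
   from specific-lysis thresholds), cross-reactivity sums, clone counts,
   EC50 from titration curves and log10 relative functional avidities;
7. **synthetic data** — seeded generators for superposed peptide-like
   structure sets with planted structure–activity relationships, conformer
   ensembles with a planted best cluster, and clone recognition profiles, so
   the whole pipeline is testable offline.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` implements the acceptance criteria; the full run
takes a few minutes (GA-vs-exhaustive enumeration and the planted-recovery /
y-randomization checks dominate). Two reproduction tests are skipped unless
the deposited structure files are placed under `data/reproduction/`
(`peptides_dock4.pdb`, `hla_a2_1jf1.pdb`); they are not bundled.

## CLI

The console script `crossreact3d` exposes the pipeline stages:

```bash
crossreact3d synth --preset paperlike --n 23 --seed 1 --out work/      # synthetic set
crossreact3d io --pdb work/structures.pdb --list                       # inspect structures
crossreact3d similarity --pdb work/structures.pdb --out shape.csv,elec.csv
crossreact3d train --similarity shape.csv,elec.csv \
    --activities work/activities.csv --runs 10 --seed 1 --out models.json
crossreact3d predict --models models.json --query-similarity query.csv
crossreact3d validate --models models.json --similarity shape.csv,elec.csv \
    --activities work/activities.csv --yrand 10x5 --seed 7
crossreact3d rank-conformers --energies W.csv --rmsd rmsd.csv --threshold 1.0
crossreact3d fields --pdb work/structures.pdb --out fields/            # OpenDX export
crossreact3d score --profiles profiles.csv --mode sum                  # clone profiles → scores
```

Structure input is plain PDB text; dock4-style concatenated multi-entry
files are split on `MODEL`/`END` records. Similarity matrices, activity
tables, conformer energies and RMSD matrices are CSV; models are JSON.

## Package layout

```
src/crossreact3d/
  molecular_io.py      PDB I/O, parameter assignment, no-refit RMSD
  conformers.py        cluster free-energy ranking (Boltzmann/entropy)
  grid_fields.py       shared grid, shape + electrostatic fields
  similarity.py        Hodgkin / Carbó / Meyer indices, double matrix
  gnn_qsar.py          descriptor pool, 4-1-1 net, LOO q², GA, ensembles
  validation_suite.py  partitioning, external test, y-randomization
  activity_scoring.py  clone categories, scores, EC50, relative avidity
  synthetic_data.py    planted-truth generators
  cli.py               click command group
  data/                bundled activity-score fixture and default radii
```
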