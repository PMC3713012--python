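"""Shared fixtures: synthetic structure sets and derived similarity pools.

The heavier planted data sets are session-scoped so the GNN recovery,
validation and acceptance tests share one generation pass.
"""

from __future__ import annotations

import numpy as np
import pytest

from helpers import similarity_from_molecules

from crossreact3d import SyntheticSpec, default_activity_table, generate_structure_set
from crossreact3d.gnn_qsar import ActivityTable, DescriptorPool


@pytest.fixture(scope="session")
def planted_23():
    """23-molecule low-noise planted set + similarity matrix + pool + truth."""
    spec = SyntheticSpec(
        n_molecules=23,
        coordinate_jitter=0.12,
        jitter_heterogeneity=0.7,
        exact_reference=True,
        noise_sigma=0.2,
        seed=3,
    )
    mols, activities, truth = generate_structure_set(spec)
    sim = similarity_from_molecules(mols)
    pool = DescriptorPool.from_similarity(sim)
    return {
        "molecules": mols,
        "activities": activities,
        "truth": truth,
        "similarity": sim,
        "pool": pool,
        "spec": spec,
    }


@pytest.fixture(scope="session")
def planted_12():
    """12-molecule planted set giving a 24-column descriptor pool."""
    spec = SyntheticSpec(
        n_molecules=12,
        coordinate_jitter=0.12,
        jitter_heterogeneity=0.7,
        exact_reference=True,
        noise_sigma=0.2,
        seed=7,
    )
    mols, activities, truth = generate_structure_set(spec)
    sim = similarity_from_molecules(mols)
    pool = DescriptorPool.from_similarity(sim)
    return {
        "molecules": mols,
        "activities": activities,
        "truth": truth,
        "similarity": sim,
        "pool": pool,
    }


@pytest.fixture(scope="session")
def table1_activities() -> ActivityTable:
    """The bundled 23-peptide cross-reactivity score table."""
    return default_activity_table()


@pytest.fixture(scope="session")
def noise_23(planted_23):
    """Same structures but pure-noise activities (negative control)."""
    rng = np.random.default_rng(99)
    ids = planted_23["pool"].molecule_ids
    return ActivityTable(scores=dict(zip(ids, rng.normal(0.0, 10.0, len(ids)))))
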