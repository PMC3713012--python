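"""crossreact3d: grid-based molecular-field similarity and GNN QSAR for
peptide-MHC cross-recognition prediction."""

from importlib import resources

from .activity_scoring import (
    CloneRecognitionProfile,
    TitrationCurve,
    clone_count_score,
    cross_reactivity_score,
    ec50,
    lysis_to_category,
    mean_over_clones,
    relative_avidity_log,
)
from .conformers import (
    ConformerEnsemble,
    boltzmann_weights,
    cluster_by_rmsd,
    cluster_entropy,
    rank_and_select,
)
from .gnn_qsar import (
    ActivityTable,
    DescriptorPool,
    NeuralNet411,
    QsarModel,
    consensus_predict,
    ga_select,
    loo_q2,
    predict,
    run_ensemble,
    scale_activities,
    train_net,
)
from .grid_fields import (
    GridSpec,
    ScalarField,
    build_common_grid,
    electrostatic_field,
    field_stats,
    shape_field,
)
from .molecular_io import Atom, Molecule, ParameterTable, assign_parameters, read_pdb, rmsd, write_pdb
from .similarity import SimilarityMatrix, build_similarity_matrix, carbo, hodgkin, meyer
from .synthetic_data import (
    SyntheticSpec,
    SyntheticTruth,
    generate_clone_profiles,
    generate_conformer_ensemble,
    generate_structure_set,
)
from .validation_suite import (
    Partition,
    external_test_stats,
    functional_dependence,
    partition_by_activity,
    pearson_r,
    y_randomize,
)

__version__ = "0.1.0"

#: The published 6-member external test set of the reference activity table.
PUBLISHED_TEST_INACTIVE = ("100", "104", "108")


def default_activity_table() -> ActivityTable:
    """The bundled 23-peptide cross-reactivity score table."""
    path = resources.files("crossreact3d.data") / "cross_reactivity_scores.csv"
    return ActivityTable.from_csv(str(path))


def default_parameter_table() -> ParameterTable:
    path = resources.files("crossreact3d.data") / "default_params.csv"
    return ParameterTable.from_csv(str(path))
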