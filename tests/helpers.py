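"""Small shared utilities for the test suite."""

from __future__ import annotations

from crossreact3d import build_common_grid, build_similarity_matrix, electrostatic_field, shape_field


def similarity_from_molecules(mols, spacing=1.0, margin=3.0, clamp=5.0):
    grid = build_common_grid(mols, margin=margin, spacing=spacing)
    fields = {
        m.id: {
            "shape": shape_field(m, grid),
            "electrostatic": electrostatic_field(m, grid, clamp=clamp),
        }
        for m in mols
    }
    return build_similarity_matrix(fields)
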