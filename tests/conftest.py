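import numpy as np
import pytest

from stepkin.bonds import BondScheme

THEOPHYLLINE_CIF = """\
data_theophylline_form_ii
_symmetry_space_group_name_H-M   'P n a 21'
_cell_length_a                   24.2655(8)
_cell_length_b                   3.76210(10)
_cell_length_c                   8.4743(2)
_cell_angle_alpha                90
_cell_angle_beta                 90
_cell_angle_gamma                90
_cell_formula_units_Z            4
_chemical_formula_sum            'C7 H8 N4 O2'
"""


@pytest.fixture
def theophylline_cif(tmp_path):
    path = tmp_path / "theophylline.cif"
    path.write_text(THEOPHYLLINE_CIF)
    return path


@pytest.fixture
def demo_scheme():
    """A synthetic bond scheme with a clear pi-stack/vdW hierarchy."""
    return BondScheme.from_energies(
        pi_stack=10e3, h_bond=6e3, vdw_in_plane=2e3, vdw_out_of_plane=1.5e3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
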