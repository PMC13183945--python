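import numpy as np
import pytest

from helixrope import CrystalStructure, HelixSpec, UnitCell, gen_triple_helix

P1_CIF = """\
data_fixture
_cell_length_a 10.0
_cell_length_b 12.0
_cell_length_c 14.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_symmetry_space_group_name_H-M 'P 1'
loop_
_symmetry_equiv_pos_as_xyz
'x, y, z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
N1 N 0.10 0.20 0.30
O1 O 0.40 0.50 0.60
"""

# hexagonal P63-style cell, one atom on a general position -> 6 copies
P63_CIF = """\
data_fixture63
_cell_length_a 14.9474
_cell_length_b 14.9474
_cell_length_c 10.8213
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 120
_symmetry_space_group_name_H-M 'P 63'
loop_
_symmetry_equiv_pos_as_xyz
'x, y, z'
'-y, x-y, z'
'-x+y, -x, z'
'-x, -y, z+1/2'
'y, -x+y, z+1/2'
'x-y, x, z+1/2'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.13 0.29 0.41
"""


@pytest.fixture
def p1_cif(tmp_path):
    path = tmp_path / "p1.cif"
    path.write_text(P1_CIF)
    return path


@pytest.fixture
def p63_cif(tmp_path):
    path = tmp_path / "p63.cif"
    path.write_text(P63_CIF)
    return path


@pytest.fixture
def helix_spec():
    return HelixSpec(n_strands=3, delta_theta=-20.0, delta_z=3.0,
                     radius=7.8, n_layers=8, seed=0)


@pytest.fixture
def helix_structure(helix_spec):
    return gen_triple_helix(helix_spec)


def random_molecular_frame(rng, n_molecules=40, cell=None):
    """Random periodic frame of small rigid N-H/O/C molecules.

    Used by the brute-force oracle comparisons: each molecule carries a
    donor N with one H at 1.0 Å, an acceptor O and two C atoms at
    random nearby offsets, placed at random fractional positions of a
    triclinic cell.
    """
    from helixrope import Atom

    if cell is None:
        cell = UnitCell(16.0, 15.0, 17.0, 80.0, 95.0, 105.0)
    atoms = []
    aid = 0
    m = cell.frac_to_cart_matrix
    for mol in range(n_molecules):
        base = m @ rng.uniform(0, 1, 3)
        hdir = rng.normal(size=3)
        hdir /= np.linalg.norm(hdir)
        members = [("N", "N", base),
                   ("H", "H", base + hdir),
                   ("O", "O", base + rng.normal(scale=1.2, size=3)),
                   ("C", "C1", base + rng.normal(scale=1.5, size=3)),
                   ("C", "C2", base + rng.normal(scale=1.5, size=3))]
        for el, name, p in members:
            atoms.append(Atom(aid, el, name, "MOL", mol, p))
            aid += 1
    return CrystalStructure(atoms, cell)
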