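"""Read a crystal structure from file and analyse a supercell.

Writes a synthetic bundle to PDB (standing in for a deposited
structure), reads it back keeping the file's residue-based molecule
grouping, replicates it into a supercell and reports per-crystal-unit
H-bond counts.
"""

import tempfile
from pathlib import Path

from helixrope import (HelixSpec, build_supercell, detect_hbonds,
                       gen_triple_helix, per_unit, read_structure,
                       write_structure)

structure, _ = gen_triple_helix(HelixSpec(n_layers=6, seed=2))
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "bundle.pdb"
    write_structure(structure, path)
    back = read_structure(path, molecule_mode="residue")
    print(f"PDB round trip: {len(back)} atoms, cell a = {back.cell.a:.3f} Å, "
          f"{back.n_molecules} molecules")

    sc = build_supercell(back, (2, 2, 1))
    print(f"2x2x1 supercell: {len(sc)} atoms, {sc.n_molecules} molecules, "
          f"n_cells = {sc.n_cells}")
    hbonds = detect_hbonds(sc)
    print(f"{len(hbonds)} H-bonds -> {per_unit(len(hbonds), sc.n_cells):.1f} "
          "per crystal unit")
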