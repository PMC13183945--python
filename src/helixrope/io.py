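"""Reading and writing crystal structures and trajectory frames.

Small-molecule CIF and PDB parsing is delegated to gemmi; an extended-XYZ
dialect (with a ``Lattice="..."`` comment line) is provided for fixtures
and round trips, in both single-structure and multi-frame trajectory
form.  Binary trajectory formats (XTC/TRR/DCD) are read through
MDAnalysis when that package is installed.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import gemmi

from .structures import Atom, CrystalStructure, Trajectory, UnitCell, assign_molecules

__all__ = [
    "ParseError", "StructureError", "TopologyError",
    "read_structure", "write_structure", "read_trajectory", "write_trajectory",
]


class ParseError(ValueError):
    """File could not be parsed in the expected dialect."""


class StructureError(ValueError):
    """File parsed but lacks required structural content (e.g. no cell)."""


class TopologyError(ValueError):
    """Coordinate data inconsistent with the supplied topology."""


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("cif", "pdb", "xyz"):
        return suffix
    head = path.read_text(errors="replace")[:4000]
    if "_cell_length_a" in head or head.lstrip().startswith("data_"):
        return "cif"
    if head.startswith(("ATOM", "HETATM", "CRYST1", "HEADER")):
        return "pdb"
    return "xyz"


def read_structure(path, format_hint: str = "auto", expand: bool = True,
                   molecule_mode: str = "connectivity") -> CrystalStructure:
    """Read a crystal structure and return the symmetry-expanded cell.

    Molecule ids are assigned by covalent connectivity (bond when the
    interatomic distance is below 1.2 × the covalent-radius sum); with
    ``molecule_mode="residue"`` the file's own residue numbering (PDB)
    or explicit molecule column (XYZ) is kept instead, for inputs whose
    "molecules" are rigid model fragments rather than covalent units.
    With ``expand=False`` the asymmetric unit and its operator list are
    returned unexpanded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint if format_hint != "auto" else _sniff_format(path)
    if fmt == "cif":
        struct = _read_cif(path)
    elif fmt == "pdb":
        struct = _read_pdb(path)
    elif fmt == "xyz":
        struct = _read_xyz(path)
    else:
        raise ParseError(f"unsupported format {fmt!r}")
    if getattr(struct, "_explicit_molecules", False):
        # the fixture XYZ dialect carries authoritative molecule ids
        return struct
    if molecule_mode == "residue":
        if not getattr(struct, "_residue_molecules", False):
            raise ValueError(
                f"molecule_mode='residue' needs per-residue numbering ({fmt})")
        return struct
    if expand:
        struct = struct.expand_symmetry()
    else:
        assign_molecules(struct)
    return struct


def _read_cif(path: Path) -> CrystalStructure:
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError with line info
        raise ParseError(f"cannot parse CIF {path}: {exc}") from exc
    if block.find_value("_cell_length_a") is None:
        raise StructureError(f"{path}: CIF has no _cell_length_a block")
    try:
        small = gemmi.read_small_structure(str(path))
    except Exception as exc:
        raise ParseError(f"cannot interpret CIF {path}: {exc}") from exc
    c = small.cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    triplets = list(small.symops)
    if not triplets and small.spacegroup is not None:
        triplets = [op.triplet() for op in small.spacegroup.operations()]
    if not triplets:
        triplets = ["x, y, z"]
    ops = []
    for trip in triplets:
        op = gemmi.Op(trip)
        ops.append((np.array(op.rot, float) / op.DEN,
                    np.array(op.tran, float) / op.DEN))
    atoms = []
    m = cell.frac_to_cart_matrix
    for i, site in enumerate(small.sites):
        frac = np.array([site.fract.x, site.fract.y, site.fract.z])
        el = site.element.name if site.element.name else site.type_symbol
        atoms.append(Atom(i, el, site.label, site.label.rstrip("0123456789"),
                          0, m @ frac))
    if not atoms:
        raise StructureError(f"{path}: CIF contains no atom sites")
    return CrystalStructure(atoms, cell, ops, provenance=str(path))


def _read_pdb(path: Path) -> CrystalStructure:
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:
        raise ParseError(f"cannot parse PDB {path}: {exc}") from exc
    c = st.cell
    if not c.is_crystal() and c.a <= 1.0:
        raise StructureError(f"{path}: PDB lacks a CRYST1 cell")
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    atoms = []
    i = 0
    mol = -1
    for model in st:
        for chain in model:
            for res in chain:
                mol += 1        # one residue = one molecule candidate
                for at in res:
                    atoms.append(Atom(i, at.element.name, at.name, res.name,
                                      mol,
                                      np.array([at.pos.x, at.pos.y, at.pos.z])))
                    i += 1
        break  # first model only
    if not atoms:
        raise StructureError(f"{path}: PDB contains no atoms")
    out = CrystalStructure(atoms, cell, [(np.eye(3), np.zeros(3))],
                           provenance=str(path))
    out._residue_molecules = True
    return out


def _parse_lattice_comment(comment: str) -> UnitCell | None:
    if "Lattice=" not in comment:
        return None
    frag = comment.split("Lattice=", 1)[1]
    quote = frag[0] if frag[:1] in "\"'" else None
    body = frag[1:].split(quote, 1)[0] if quote else frag.split()[0]
    vals = np.array([float(x) for x in body.split()])
    if vals.size != 9:
        raise ParseError("Lattice comment must contain 9 numbers")
    vecs = vals.reshape(3, 3)
    a, b, c = np.linalg.norm(vecs, axis=1)
    cosg = vecs[0] @ vecs[1] / (a * b)
    cosb = vecs[0] @ vecs[2] / (a * c)
    cosa = vecs[1] @ vecs[2] / (b * c)
    return UnitCell(a, b, c, float(np.degrees(np.arccos(np.clip(cosa, -1, 1)))),
                    float(np.degrees(np.arccos(np.clip(cosb, -1, 1)))),
                    float(np.degrees(np.arccos(np.clip(cosg, -1, 1)))))


def _parse_xyz_frame(lines: list[str], start: int, path: Path
                     ) -> tuple[int, list[Atom], UnitCell | None, float | None, bool]:
    try:
        n = int(lines[start].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}:{start + 1}: expected atom count") from exc
    if start + 2 + n > len(lines) + 0:
        raise IOError(f"{path}: truncated frame starting at line {start + 1}")
    comment = lines[start + 1]
    cell = _parse_lattice_comment(comment)
    time = None
    if "Time=" in comment:
        time = float(comment.split("Time=", 1)[1].split()[0])
    atoms = []
    explicit_mols = False
    for i in range(n):
        parts = lines[start + 2 + i].split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{start + 3 + i}: short atom line")
        el, x, y, z = parts[0], *map(float, parts[1:4])
        name = parts[4] if len(parts) > 4 else el
        residue = parts[5] if len(parts) > 5 else "UNK"
        if len(parts) > 6:
            mol = int(parts[6])
            explicit_mols = True
        else:
            mol = 0
        atoms.append(Atom(i, el, name, residue, mol, np.array([x, y, z])))
    return start + 2 + n, atoms, cell, time, explicit_mols


def _read_xyz(path: Path) -> CrystalStructure:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    _, atoms, cell, _, explicit_mols = _parse_xyz_frame(lines, 0, path)
    if cell is None:
        # a generous padded box so minimum-image never wraps the cluster
        pos = np.array([a.position for a in atoms])
        span = pos.max(0) - pos.min(0) + 100.0
        cell = UnitCell(*span)
    out = CrystalStructure(atoms, cell, [(np.eye(3), np.zeros(3))],
                           provenance=str(path))
    out._explicit_molecules = explicit_mols
    return out


def write_structure(structure: CrystalStructure, path, format: str = "auto") -> Path:
    """Write to PDB, XYZ (extended, with lattice) or P1 CIF."""
    path = Path(path)
    if len(structure) == 0:
        raise StructureError("refusing to write an empty structure")
    fmt = format if format != "auto" else _sniff_format_name(path)
    if fmt == "xyz":
        text = _format_xyz_frame(structure, time=None)
    elif fmt == "pdb":
        text = _format_pdb(structure)
    elif fmt == "cif":
        text = _format_cif(structure)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    path.write_text(text)
    return path


def _sniff_format_name(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in ("cif", "pdb", "xyz"):
        raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    return suffix


def _lattice_comment(cell: UnitCell) -> str:
    flat = " ".join(f"{x:.8f}" for x in cell.lattice_vectors.ravel())
    return f'Lattice="{flat}"'


def _format_xyz_frame(structure: CrystalStructure, time: float | None) -> str:
    lines = [str(len(structure))]
    comment = _lattice_comment(structure.cell)
    if time is not None:
        comment += f" Time={time:.6f}"
    lines.append(comment)
    for a in structure.atoms:
        lines.append(f"{a.element:2s} {a.position[0]:.6f} {a.position[1]:.6f} "
                     f"{a.position[2]:.6f} {a.name} {a.residue} {a.molecule_id}")
    return "\n".join(lines) + "\n"


def _format_pdb(structure: CrystalStructure) -> str:
    c = structure.cell
    lines = [f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
             f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} P 1"]
    for i, a in enumerate(structure.atoms, 1):
        name = a.name[:4]
        res = (a.residue or "UNK")[:3]
        x, y, z = a.position
        lines.append(
            f"HETATM{i % 100000:5d} {name:<4s}{res:>4s} A{(a.molecule_id + 1) % 10000:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _format_cif(structure: CrystalStructure) -> str:
    c = structure.cell
    minv = c.cart_to_frac_matrix
    lines = [
        "data_helixrope",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.6f}",
        f"_cell_angle_beta {c.beta:.6f}",
        f"_cell_angle_gamma {c.gamma:.6f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "'x, y, z'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for a in structure.atoms:
        frac = minv @ a.position
        label = a.name if a.name else f"{a.element}{a.atom_id}"
        lines.append(f"{label} {a.element} {frac[0]:.6f} {frac[1]:.6f} {frac[2]:.6f}")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write the plain multi-frame extended-XYZ trajectory dialect."""
    path = Path(path)
    chunks = []
    for i in range(traj.n_frames):
        chunks.append(_format_xyz_frame(traj.frame(i), time=float(traj.times[i])))
    path.write_text("".join(chunks))
    return path


def read_trajectory(coords_path, topology: CrystalStructure) -> Trajectory:
    """Read a coordinate series against a fixed topology.

    Plain multi-frame XYZ-with-lattice is always supported; XTC/TRR/DCD
    are handled through MDAnalysis when installed.
    """
    path = Path(coords_path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("xtc", "trr", "dcd"):
        return _read_binary_trajectory(path, topology)
    lines = path.read_text().splitlines()
    if not lines:
        raise IOError(f"{path}: trajectory contains zero frames")
    times, frames, cells = [], [], []
    cursor = 0
    idx = 0
    while cursor < len(lines):
        if not lines[cursor].strip():
            cursor += 1
            continue
        try:
            cursor, atoms, cell, time, _ = _parse_xyz_frame(lines, cursor, path)
        except IOError:
            raise IOError(f"{path}: truncated frame {idx}")
        if len(atoms) != len(topology):
            raise TopologyError(
                f"frame {idx} has {len(atoms)} atoms, topology has {len(topology)}")
        frames.append([a.position for a in atoms])
        cells.append(cell if cell is not None else topology.cell)
        times.append(time if time is not None else float(idx))
        idx += 1
    if not frames:
        raise IOError(f"{path}: trajectory contains zero frames")
    return Trajectory(np.array(times), np.array(frames), cells, topology.atoms)


def _read_binary_trajectory(path: Path, topology: CrystalStructure) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:
        raise IOError("binary trajectory formats require MDAnalysis") from exc
    u = mda.Universe.empty(len(topology), trajectory=True)
    u.load_new(str(path))
    times, frames, cells = [], [], []
    for ts in u.trajectory:
        if ts.n_atoms != len(topology):
            raise TopologyError(
                f"frame {ts.frame} has {ts.n_atoms} atoms, topology has {len(topology)}")
        frames.append(ts.positions.copy())
        a, b, c, al, be, ga = ts.dimensions
        cells.append(UnitCell(a, b, c, al, be, ga) if a > 0 else topology.cell)
        times.append(float(ts.time))
    times = np.array(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(len(times), dtype=float)
    return Trajectory(times, np.array(frames), cells, topology.atoms)
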