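"""Core coordinate model: atoms, unit cells, crystal structures, trajectories.

All lengths are in ångström and all angles in degrees throughout the
package; cutoffs quoted in nm elsewhere are converted once at the
configuration layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "COVALENT_RADII",
    "Atom",
    "UnitCell",
    "CrystalStructure",
    "Trajectory",
    "assign_molecules",
]

# Covalent radii (Å), Cordero et al. consensus values; enough elements for
# peptide crystals with solvent.  Unknown elements fall back to 0.8 Å.
COVALENT_RADII = {
    "H": 0.31, "D": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "NA": 1.66, "MG": 1.41, "P": 1.07, "S": 1.05, "CL": 1.02,
    "K": 2.03, "CA": 1.76, "BR": 1.20, "I": 1.39, "FE": 1.32, "ZN": 1.22,
}

_VALID_ELEMENTS = set(COVALENT_RADII)


@dataclass
class Atom:
    """One atom with its chemical identity and grouping labels."""

    atom_id: int
    element: str
    name: str
    residue: str
    molecule_id: int
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        if self.molecule_id < 0:
            raise ValueError(f"atom {self.atom_id}: molecule_id must be >= 0")
        el = self.element.strip().upper()
        if not el or not el.isalpha():
            raise ValueError(f"atom {self.atom_id}: invalid element {self.element!r}")
        self.element = self.element.strip().capitalize()

    @property
    def covalent_radius(self) -> float:
        return COVALENT_RADII.get(self.element.upper(), 0.8)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class UnitCell:
    """Crystallographic unit cell.

    The fractional→Cartesian matrix follows the standard convention with
    the a vector along x and the b vector in the xy-plane.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cx = self.c * np.cos(be)
        cy = self.c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz_sq = self.c**2 - cx**2 - cy**2
        if cz_sq <= 0:
            raise ValueError("cell angles do not define a valid 3-D lattice")
        self._m = np.array([
            [self.a, self.b * np.cos(ga), cx],
            [0.0, self.b * np.sin(ga), cy],
            [0.0, 0.0, np.sqrt(cz_sq)],
        ])
        self._minv = np.linalg.inv(self._m)

    @property
    def frac_to_cart_matrix(self) -> np.ndarray:
        return self._m.copy()

    @property
    def cart_to_frac_matrix(self) -> np.ndarray:
        return self._minv.copy()

    @property
    def lattice_vectors(self) -> np.ndarray:
        """Rows are the a, b, c lattice vectors in Cartesian Å."""
        return self._m.T.copy()

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self._m)))

    def min_height(self) -> float:
        """Smallest perpendicular distance between opposite cell faces."""
        vecs = self.lattice_vectors
        heights = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            normal = np.cross(vecs[j], vecs[k])
            heights.append(abs(vecs[i] @ normal) / np.linalg.norm(normal))
        return float(min(heights))

    def scaled(self, na: int, nb: int, nc: int) -> "UnitCell":
        return UnitCell(self.a * na, self.b * nb, self.c * nc,
                        self.alpha, self.beta, self.gamma)


@dataclass
class CrystalStructure:
    """A set of atoms with a periodic cell and (optional) symmetry operators.

    ``symmetry_ops`` are (3×3 rotation, translation) pairs acting in
    fractional space.  After :meth:`expand_symmetry` the atom list covers
    the full unit cell and the operator list collapses to identity.
    """

    atoms: list[Atom]
    cell: UnitCell
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(
        default_factory=lambda: [(np.eye(3), np.zeros(3))])
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def molecule_ids(self) -> np.ndarray:
        return np.array([a.molecule_id for a in self.atoms], dtype=int)

    @property
    def n_molecules(self) -> int:
        return len(set(a.molecule_id for a in self.atoms))

    def molecules(self) -> dict[int, list[Atom]]:
        out: dict[int, list[Atom]] = {}
        for atom in self.atoms:
            out.setdefault(atom.molecule_id, []).append(atom)
        return out

    def with_positions(self, positions: np.ndarray) -> "CrystalStructure":
        positions = np.asarray(positions, float)
        if positions.shape != (len(self.atoms), 3):
            raise ValueError("position array shape mismatch")
        atoms = [replace(a, position=p.copy()) for a, p in zip(self.atoms, positions)]
        return CrystalStructure(atoms, self.cell, list(self.symmetry_ops), self.provenance)

    def expand_symmetry(self, duplicate_tol: float = 0.1) -> "CrystalStructure":
        """Apply all symmetry operators, dropping duplicates within
        ``duplicate_tol`` Å after wrapping (special-position handling).

        Idempotent: expanding an already-expanded structure adds nothing.
        """
        m = self.cell.frac_to_cart_matrix
        minv = self.cell.cart_to_frac_matrix
        new_atoms: list[Atom] = []
        kept_frac: list[np.ndarray] = []
        kept_el: list[str] = []
        aid = 0
        for rot, trans in self.symmetry_ops:
            for atom in self.atoms:
                frac = minv @ atom.position
                new_frac = (rot @ frac + trans) % 1.0
                dup = False
                for f_prev, el_prev in zip(kept_frac, kept_el):
                    if el_prev != atom.element:
                        continue
                    d = new_frac - f_prev
                    d -= np.round(d)
                    if np.linalg.norm(m @ d) < duplicate_tol:
                        dup = True
                        break
                if dup:
                    continue
                kept_frac.append(new_frac)
                kept_el.append(atom.element)
                new_atoms.append(Atom(aid, atom.element, atom.name, atom.residue,
                                      0, m @ new_frac))
                aid += 1
        out = CrystalStructure(new_atoms, self.cell,
                               [(np.eye(3), np.zeros(3))], self.provenance)
        assign_molecules(out)
        return out


def assign_molecules(structure: CrystalStructure, scale: float = 1.2) -> None:
    """Partition atoms into covalent molecules in place.

    Two atoms are bonded when their minimum-image distance is below
    ``scale`` × the sum of covalent radii; connected components define
    molecules.  Each molecule is then made whole (unwrapped) so that
    centroids and intramolecular distances are meaningful even when the
    cell wraps a molecule across a boundary.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(structure.atoms)
    if n == 0:
        return
    pos = structure.positions
    radii = np.array([a.covalent_radius for a in structure.atoms])
    max_bond = scale * 2 * radii.max()

    # pair search over the 27 minimum-image shifts
    vecs = structure.cell.lattice_vectors
    shifts = np.array([i * vecs[0] + j * vecs[1] + k * vecs[2]
                       for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    rows, cols = [], []
    bond_shift: dict[tuple[int, int], np.ndarray] = {}
    from scipy.spatial import cKDTree
    tree = cKDTree(pos)
    for shift in shifts:
        pairs = tree.query_ball_point(pos + shift, max_bond)
        for i, nbrs in enumerate(pairs):
            for j in nbrs:
                if j == i and np.allclose(shift, 0):
                    continue
                d = np.linalg.norm(pos[i] + shift - pos[j])
                if d < scale * (radii[i] + radii[j]) and d > 1e-9:
                    rows.append(i)
                    cols.append(j)
                    key = (i, j)
                    if key not in bond_shift or d < np.linalg.norm(
                            pos[i] + bond_shift[key] - pos[j]):
                        bond_shift[key] = shift

    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    for atom, lab in zip(structure.atoms, labels):
        atom.molecule_id = int(lab)

    # unwrap: BFS within each molecule applying the bond image shifts,
    # carrying the accumulated displacement of the atom already placed
    neighbor: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(n)}
    for (i, j), shift in bond_shift.items():
        neighbor[j].append((i, shift))      # i's bonded image is at pos[i] + shift
        neighbor[i].append((j, -shift))
    disp = np.zeros((n, 3))
    visited = np.zeros(n, bool)
    for start in range(n):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        while stack:
            i = stack.pop()
            for j, offset in neighbor[i]:
                if visited[j]:
                    continue
                disp[j] = disp[i] + offset
                structure.atoms[j].position = structure.atoms[j].position + disp[j]
                visited[j] = True
                stack.append(j)


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology."""

    times: np.ndarray              # ps
    positions: np.ndarray          # (n_frames, n_atoms, 3) Å
    cells: list[UnitCell]
    atom_table: list[Atom]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.positions.shape[0] or len(self.cells) != len(self.times):
            raise ValueError("frame count mismatch between times, positions and cells")
        if self.positions.shape[1] != len(self.atom_table):
            raise ValueError("atom count differs from topology")
        if len(self.times) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> CrystalStructure:
        struct = CrystalStructure(
            [replace(a, position=p.copy()) for a, p in zip(self.atom_table, self.positions[i])],
            self.cells[i])
        return struct

    def window(self, t0: float | None = None, t1: float | None = None,
               last_fraction: float | None = None) -> "Trajectory":
        """Sub-trajectory in [t0, t1] ps, or the final ``last_fraction``."""
        if last_fraction is not None:
            k = max(1, int(round(self.n_frames * last_fraction)))
            idx = np.arange(self.n_frames - k, self.n_frames)
        else:
            lo = -np.inf if t0 is None else t0
            hi = np.inf if t1 is None else t1
            idx = np.where((self.times >= lo) & (self.times <= hi))[0]
        if len(idx) == 0:
            raise ValueError("requested window lies outside the trajectory")
        return Trajectory(self.times[idx], self.positions[idx],
                          [self.cells[i] for i in idx], self.atom_table)
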