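"""Periodic-boundary geometry: fractional transforms, supercells,
minimum-image distances and stacking-layer assignment."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .structures import Atom, CrystalStructure, UnitCell

__all__ = [
    "frac_to_cart", "cart_to_frac", "build_supercell", "min_image",
    "min_image_many", "LayerAssignment", "assign_layers",
]

MAX_SUPERCELL_ATOMS = 2_000_000


def frac_to_cart(cell: UnitCell, frac) -> np.ndarray:
    """Fractional → Cartesian (Å), a along x and b in the xy-plane."""
    return np.asarray(frac, float) @ cell.frac_to_cart_matrix.T


def cart_to_frac(cell: UnitCell, cart) -> np.ndarray:
    return np.asarray(cart, float) @ cell.cart_to_frac_matrix.T


def build_supercell(structure: CrystalStructure, n: tuple[int, int, int]
                    ) -> CrystalStructure:
    """Replicate the cell ``na × nb × nc`` times with lattice translations.

    Molecule ids are re-indexed uniquely per replica; the result records
    ``n_cells`` for per-crystal-unit normalisation.
    """
    na, nb, nc = (int(x) for x in n)
    if min(na, nb, nc) < 1:
        raise ValueError("supercell multipliers must be >= 1")
    if len(structure) * na * nb * nc > MAX_SUPERCELL_ATOMS:
        raise ResourceWarning(
            f"supercell would exceed {MAX_SUPERCELL_ATOMS} atoms")
    vecs = structure.cell.lattice_vectors
    n_mol = max((a.molecule_id for a in structure.atoms), default=-1) + 1
    atoms: list[Atom] = []
    aid = 0
    rep = 0
    for ia in range(na):
        for ib in range(nb):
            for ic in range(nc):
                shift = ia * vecs[0] + ib * vecs[1] + ic * vecs[2]
                for a in structure.atoms:
                    atoms.append(Atom(aid, a.element, a.name, a.residue,
                                      a.molecule_id + rep * n_mol,
                                      a.position + shift))
                    aid += 1
                rep += 1
    out = CrystalStructure(atoms, structure.cell.scaled(na, nb, nc),
                           [(np.eye(3), np.zeros(3))],
                           structure.provenance + f" [{na}x{nb}x{nc} supercell]")
    out.n_cells = na * nb * nc
    return out


def min_image(cell: UnitCell, p, q) -> tuple[np.ndarray, float]:
    """Shortest displacement q→p over the 27 neighbour images.

    Exact for separations below half the smallest cell height.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    vecs = cell.lattice_vectors
    d0 = p - q
    # reduce to the home cell first so the 27-image search is exact
    frac = np.round(cart_to_frac(cell, d0))
    d0 = d0 - frac @ vecs
    best = d0
    best_r2 = d0 @ d0
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                if i == j == k == 0:
                    continue
                d = d0 + i * vecs[0] + j * vecs[1] + k * vecs[2]
                r2 = d @ d
                if r2 < best_r2:
                    best, best_r2 = d, r2
    return best, float(np.sqrt(best_r2))


def min_image_many(cell: UnitCell, disp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised minimum-image reduction of an (n, 3) displacement array."""
    disp = np.atleast_2d(np.asarray(disp, float))
    vecs = cell.lattice_vectors
    frac = np.round(disp @ cell.cart_to_frac_matrix.T)
    d0 = disp - frac @ vecs
    shifts = np.array([i * vecs[0] + j * vecs[1] + k * vecs[2]
                       for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    cand = d0[:, None, :] + shifts[None, :, :]          # (n, 27, 3)
    r2 = np.einsum("nkd,nkd->nk", cand, cand)
    best = np.argmin(r2, axis=1)
    idx = np.arange(len(d0))
    return cand[idx, best], np.sqrt(r2[idx, best])


@dataclass
class LayerAssignment:
    """Stacking layers of molecules along the helical axis."""

    molecule_layer: dict[int, int]
    layer_spacing: float
    axis: np.ndarray
    projections: dict[int, float]

    @property
    def n_layers(self) -> int:
        return max(self.molecule_layer.values()) + 1 if self.molecule_layer else 0

    def members(self, layer: int) -> list[int]:
        return sorted(m for m, l in self.molecule_layer.items() if l == layer)


def assign_layers(structure: CrystalStructure, axis=(0.0, 0.0, 1.0),
                  gap_tol: float | None = None) -> LayerAssignment:
    """Cluster molecule centroids into stacking layers along ``axis``.

    Centroids are projected onto the axis and split by 1-D single linkage:
    a new layer starts wherever the projection gap exceeds ``gap_tol``.
    With ``gap_tol=None`` the threshold is chosen automatically as the
    midpoint between the within-layer and between-layer gap populations
    (half the largest gap), provided the gap spectrum is separable.
    """
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    mols = structure.molecules()
    if not mols:
        raise ValueError("structure contains no molecules")
    proj = {m: float(np.mean([a.position for a in atoms], axis=0) @ axis)
            for m, atoms in mols.items()}
    order = sorted(proj, key=proj.get)
    values = np.array([proj[m] for m in order])
    gaps = np.diff(values)
    if len(values) == 1:
        return LayerAssignment({order[0]: 0}, 0.0, axis, proj)
    if gap_tol is None:
        max_gap = gaps.max()
        med_gap = float(np.median(gaps))
        if max_gap <= 2 * med_gap or max_gap <= 0:
            raise ValueError(
                "layer projections are not separable; supply an explicit gap_tol")
        gap_tol = 0.5 * max_gap
    layers: dict[int, int] = {order[0]: 0}
    current = 0
    for m, gap in zip(order[1:], gaps):
        if gap > gap_tol:
            current += 1
        layers[m] = current
    n_layers = current + 1
    if n_layers > 1:
        centers = [np.mean([proj[m] for m in layers if layers[m] == l])
                   for l in range(n_layers)]
        spacing = float(np.mean(np.diff(centers)))
    else:
        spacing = 0.0
    return LayerAssignment(layers, spacing, axis, proj)
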