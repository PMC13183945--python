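"""Ground-truth-labelled synthetic inputs for every pipeline stage.

The structural generator places rigid model molecules on an S-strand
helical lattice: molecule (s, n) of a bundle sits at azimuth
φ₀ + 2πs/S + nΔθ and height nΔz on a cylinder of radius r, and each
molecule is rotated about the axis by its own azimuth so that the
donor→acceptor geometry co-rotates.  The handedness of the lattice is
the sign of Δθ (negative → S, positive → Z) and the pitch is
360/|Δθ| · Δz.  Each molecule carries a donor N–H, an acceptor O placed
so that the zero-jitter consecutive-layer N···O distance is exactly the
requested H-bond length (collinear N–H···O), a planar indole-like ring
and a Cα marker; the atom names follow the packaged cyclo-Trp-Pro group
table, so the interlayer bonds come out as W_mc–W_mc.

This emulates the helical-lattice geometry of the real crystals, not
their chemistry: there is no Pro residue, no thermal physics and no
force field, so tests against it validate geometric bookkeeping, not
molecular energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mechanics import ForceCurve, TensileCurve, hertz_force
from .structures import Atom, CrystalStructure, Trajectory, UnitCell

__all__ = [
    "HelixSpec", "gen_triple_helix", "mirror_structure",
    "gen_jitter_trajectory", "gen_indent_curve", "gen_tensile_curve",
]

# planar indole-like ring template (p, q) in the ring plane, Å: a regular
# hexagon fused to a regular pentagon on the CD2–CE2 edge, bond length 1.39
_RING_TEMPLATE = {
    "CZ2": (1.39, 0.0),
    "CE2": (0.695, 1.2037),
    "CD2": (-0.695, 1.2037),
    "CE3": (-1.39, 0.0),
    "CZ3": (-0.695, -1.2037),
    "CH2": (0.695, -1.2037),
    "NE1": (1.124, 2.525),
    "CD1": (0.0, 3.342),
    "CG": (-1.124, 2.525),
}


@dataclass
class HelixSpec:
    """Parameters of one synthetic helical-bundle crystal."""

    n_strands: int = 3
    delta_theta: float = -20.0      # degrees/layer; sign = handedness (neg → S)
    delta_z: float = 3.0            # Å/layer
    radius: float = 7.8             # Å, donor-N cylinder radius
    n_layers: int = 8
    phi0: float = 0.0               # degrees
    hbond_length: float = 2.9       # Å, zero-jitter N···O
    hbond_tilt: float = 20.0        # degrees off-axis tilt of the N-H···O line
    ring_offset: float = 4.5        # Å, ring attachment radially outward
    ca_offset: float = -2.0         # Å, Cα marker radial offset from N
    n_bundles: int = 1
    bundle_spacing: float = 30.0    # Å, hexagonal packing
    include_water: bool = False
    jitter: float = 0.0             # Å, Gaussian placement disorder
    jitter_mode: str = "molecule"   # rigid per-molecule shifts, or "atom"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strands < 1 or self.n_layers < 1 or self.n_bundles < 1:
            raise ValueError("n_strands, n_layers, n_bundles must be >= 1")
        if self.delta_z <= 0 or self.radius <= 0 or self.hbond_length <= 0:
            raise ValueError("delta_z, radius and hbond_length must be positive")

    @property
    def handedness(self) -> str:
        return "S" if self.delta_theta < 0 else "Z"

    @property
    def pitch(self) -> float:
        return 360.0 / abs(self.delta_theta) * self.delta_z if self.delta_theta else float("inf")


def _molecule_template(spec: HelixSpec) -> list[tuple[str, str, np.ndarray]]:
    """(name, element, local position) with the donor N at the origin.

    Local x points radially outward, z along the bundle axis.  The
    acceptor O is placed so that, after the next layer's rotation by Δθ
    and rise Δz, the N···O distance equals ``hbond_length`` with the
    donor H exactly on the N→O line.
    """
    tau = np.radians(spec.hbond_tilt)
    dth = np.radians(spec.delta_theta)
    u_local = np.array([np.sin(tau), 0.0, np.cos(tau)])   # H-bond direction
    r, d = spec.radius, spec.hbond_length
    rot = np.array([[np.cos(-dth), -np.sin(-dth), 0.0],
                    [np.sin(-dth), np.cos(-dth), 0.0],
                    [0.0, 0.0, 1.0]])
    o_local = (rot @ np.array([r + d * np.sin(tau), 0.0, 0.0])
               - np.array([r, 0.0, 0.0])
               + np.array([0.0, 0.0, d * np.cos(tau) - spec.delta_z]))
    atoms = [
        ("N", "N", np.zeros(3)),
        ("H", "H", u_local.copy()),
        ("O", "O", o_local),
        ("CA", "C", np.array([spec.ca_offset, 0.0, 0.0])),
    ]
    for name, (p, q) in _RING_TEMPLATE.items():
        el = "N" if name.startswith("N") else "C"
        atoms.append((name, el, np.array([spec.ring_offset + p, 0.0, q])))
    return atoms


def _hex_centers(n: int, spacing: float) -> np.ndarray:
    """First n points of a hexagonal lattice, centre outward."""
    pts = [(0.0, 0.0)]
    shell = 1
    a1 = np.array([spacing, 0.0])
    a2 = np.array([spacing / 2.0, spacing * np.sqrt(3) / 2.0])
    while len(pts) < n:
        for i in range(-shell, shell + 1):
            for j in range(-shell, shell + 1):
                if max(abs(i), abs(j), abs(i + j)) == shell:
                    pts.append(tuple(i * a1 + j * a2))
        shell += 1
    pts = sorted(pts, key=lambda p: (np.hypot(*p), p))[:n]
    return np.array(pts)


def gen_triple_helix(spec: HelixSpec) -> tuple[CrystalStructure, dict]:
    """Build a synthetic helical-bundle crystal and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    template = _molecule_template(spec)
    centers = _hex_centers(spec.n_bundles, spec.bundle_spacing)
    atoms: list[Atom] = []
    aid = 0
    mol = 0
    for bx, by in centers:
        for s in range(spec.n_strands):
            for n in range(spec.n_layers):
                az = np.radians(spec.phi0) + 2 * np.pi * s / spec.n_strands \
                    + n * np.radians(spec.delta_theta)
                ca, sa = np.cos(az), np.sin(az)
                rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
                base = np.array([bx, by, n * spec.delta_z])
                for name, el, local in template:
                    pos = base + rot @ (local + np.array([spec.radius, 0.0, 0.0]))
                    atoms.append(Atom(aid, el, name, "TRP", mol, pos))
                    aid += 1
                mol += 1
        if spec.include_water:
            for n in range(spec.n_layers):
                pos = np.array([bx, by, (n + 0.5) * spec.delta_z])
                atoms.append(Atom(aid, "O", "OW", "HOH", mol, pos))
                aid += 1
                mol += 1

    pos = np.array([a.position for a in atoms])
    if spec.jitter > 0:
        # default: rigid-body placement disorder — the molecules are
        # rigid bodies, so lattice noise displaces each molecule as a
        # whole; "atom" mode adds independent per-atom noise instead
        if spec.jitter_mode == "molecule":
            mol_ids = np.array([a.molecule_id for a in atoms])
            shifts = rng.normal(0.0, spec.jitter, (mol, 3))
            pos = pos + shifts[mol_ids]
        elif spec.jitter_mode == "atom":
            pos = pos + rng.normal(0.0, spec.jitter, pos.shape)
        else:
            raise ValueError(f"unknown jitter_mode {spec.jitter_mode!r}")
        for a, p in zip(atoms, pos):
            a.position = p

    # clash guard: atoms of different molecules closer than 1.5 Å at the
    # requested geometry indicate an unusable spec
    if spec.jitter == 0:
        from scipy.spatial import cKDTree
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(1.5):
            if atoms[i].molecule_id != atoms[j].molecule_id:
                raise ValueError(
                    f"geometric clash: atoms {i} and {j} of different molecules "
                    f"are {np.linalg.norm(pos[i] - pos[j]):.2f} Å apart")

    span = pos.max(axis=0) - pos.min(axis=0)
    cell = UnitCell(*(span + 50.0))
    shift = -pos.min(axis=0) + 25.0
    for a in atoms:
        a.position = a.position + shift
    structure = CrystalStructure(atoms, cell, provenance="synthetic helix")
    truth = {
        "handedness": spec.handedness,
        "pitch": spec.pitch,
        "radius": spec.radius,
        "delta_theta": spec.delta_theta,
        "delta_z": spec.delta_z,
        "n_layers": spec.n_layers,
        "n_strands": spec.n_strands,
        "n_bundles": spec.n_bundles,
        "n_molecules": mol,
        "ca_circle_diameter": 2.0 * (spec.radius + spec.ca_offset),
        "hbond_length": spec.hbond_length,
        # cylinder radius of the molecule centroids (the ring offset pulls
        # the centroid radially outward of the donor-N cylinder)
        "centroid_radius": float(np.hypot(
            spec.radius + np.mean([loc[0] for _, _, loc in template]),
            np.mean([loc[1] for _, _, loc in template]))),
    }
    return structure, truth


def mirror_structure(structure: CrystalStructure) -> CrystalStructure:
    """Reflect through the xz-plane (a plane containing the helix axis).

    An exact involution and isometry; it reverses every handedness in
    the structure while preserving all interatomic distances.
    """
    pos = structure.positions.copy()
    pos[:, 1] = -pos[:, 1]
    out = structure.with_positions(pos)
    out.provenance = structure.provenance + " [mirrored]"
    return out


def gen_jitter_trajectory(structure: CrystalStructure, sigma: float,
                          n_frames: int, seed: int = 0,
                          dt: float = 1.0) -> Trajectory:
    """Frames = structure + iid Gaussian coordinate noise, fixed cell."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    base = structure.positions
    frames = base[None, :, :] + rng.normal(0.0, sigma, (n_frames, *base.shape)) \
        if sigma > 0 else np.repeat(base[None, :, :], n_frames, axis=0)
    times = np.arange(n_frames, dtype=float) * dt
    return Trajectory(times, frames, [structure.cell] * n_frames, structure.atoms)


def gen_indent_curve(E: float, nu: float = 0.3, tip_radius: float = 10e-9,
                     delta_max: float = 50e-9, spring_constant: float = 200.0,
                     noise_frac: float = 0.0, seed: int = 0,
                     n_points: int = 200, pre_contact: float = 20e-9,
                     contact_point: float = 0.0) -> tuple[ForceCurve, dict]:
    """Synthetic Hertzian approach curve with multiplicative force noise.

    The piezo coordinate includes the cantilever deflection, z = z₀ + δ
    + F/k_c, so the deflection correction in the analysis is exercised.
    """
    if min(E, tip_radius, delta_max, spring_constant) <= 0 or noise_frac < 0:
        raise ValueError("generator parameters must be positive, noise_frac >= 0")
    rng = np.random.default_rng(seed)
    n_pre = max(2, int(n_points * pre_contact / (pre_contact + delta_max)))
    n_post = n_points - n_pre
    z_pre = np.linspace(contact_point - pre_contact, contact_point, n_pre,
                        endpoint=False)
    delta = np.linspace(0.0, delta_max, n_post)
    F_post = hertz_force(E, nu, tip_radius, delta)
    z_post = contact_point + delta + F_post / spring_constant
    z = np.concatenate([z_pre, z_post])
    F = np.concatenate([np.zeros(n_pre), F_post])
    if noise_frac > 0:
        F = F * (1.0 + rng.normal(0.0, noise_frac, F.shape))
    curve = ForceCurve(z, F, tip_radius, nu, spring_constant)
    truth = {"E": E, "nu": nu, "tip_radius": tip_radius,
             "contact_point": contact_point, "delta_max": delta_max,
             "spring_constant": spring_constant}
    return curve, truth


def gen_tensile_curve(modulus: float, fracture_strain: float = 0.01,
                      noise_frac: float = 0.0, seed: int = 0,
                      n_points: int = 400) -> tuple[TensileCurve, dict]:
    """Linear-elastic stress–strain curve truncated at fracture."""
    if modulus <= 0 or fracture_strain <= 0 or noise_frac < 0:
        raise ValueError("modulus and fracture_strain must be positive")
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, fracture_strain, n_points)
    stress = modulus * strain
    if noise_frac > 0:
        stress = stress * (1.0 + rng.normal(0.0, noise_frac, stress.shape))
    fracture_stress = modulus * fracture_strain
    truth = {"modulus": modulus, "fracture_strain": fracture_strain,
             "fracture_stress": fracture_stress,
             "work_of_rupture": 0.5 * fracture_stress * fracture_strain}
    return TensileCurve(strain, stress), truth
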