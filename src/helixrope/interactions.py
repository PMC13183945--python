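"""Intermolecular interaction detection and statistics.

Implements the geometric criteria used throughout the analysis:

* hydrogen bond — donor–acceptor distance ≤ 3.5 Å and D-H···A angle
  ≥ 150° (vertex at the hydrogen), donors N/O carrying ≥1 hydrogen,
  acceptors any N/O, with a heavy-atom fallback for unmodelled water H;
* contact — non-hydrogen atom pair within 5.4 Å (C–C) or 4.6 Å (other);
* π–π stacking — ring-centroid separation ≤ 6.5 Å, with the three
  packing patterns (I/II inter-helix, III intra-helix) classified by
  distance bands;
* free-energy landscape — G = −RT ln P over binned (distance, angle)
  observations.

All distances honour the minimum-image convention of the frame's cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .lattice import cart_to_frac, min_image_many
from .structures import CrystalStructure, Trajectory, UnitCell

logger = logging.getLogger("helixrope")

R_GAS = 8.3145e-3  # kJ mol^-1 K^-1

__all__ = [
    "R_GAS", "HBondCriteria", "HBond", "ContactCriteria", "ContactMap",
    "PiPair", "FELGrid", "periodic_pairs", "detect_hbonds", "contact_map",
    "detect_pipi", "classify_pipi", "per_unit", "free_energy_landscape",
    "rmsd_series",
]


# ---------------------------------------------------------------- criteria

@dataclass
class HBondCriteria:
    donor_acceptor_max: float = 3.5       # Å  (0.35 nm)
    dha_angle_min: float = 150.0          # degrees
    donor_elements: tuple[str, ...] = ("N", "O")
    acceptor_elements: tuple[str, ...] = ("N", "O")
    # opt-in: accept D···A distance alone for molecules whose hydrogens
    # are not modelled (e.g. water in a riding-model CIF)
    heavy_atom_fallback: bool = False
    include_intramolecular: bool = False

    def __post_init__(self) -> None:
        if self.donor_acceptor_max <= 0:
            raise ValueError("donor_acceptor_max must be positive")
        if not 0.0 <= self.dha_angle_min <= 180.0:
            raise ValueError("dha_angle_min must lie in [0, 180]")


@dataclass
class ContactCriteria:
    cc_cutoff: float = 5.4                # Å  (0.54 nm, carbon–carbon)
    other_cutoff: float = 4.6             # Å  (0.46 nm, any other pair)

    def __post_init__(self) -> None:
        if min(self.cc_cutoff, self.other_cutoff) <= 0:
            raise ValueError("contact cutoffs must be positive")

    @property
    def max_cutoff(self) -> float:
        return max(self.cc_cutoff, self.other_cutoff)


@dataclass
class HBond:
    donor_atom: int
    hydrogen_atom: int | None
    acceptor_atom: int
    da_distance: float
    dha_angle: float | None
    donor_molecule: int
    acceptor_molecule: int
    image_shift: tuple[int, int, int]
    layer_index: int | None = None
    fallback: bool = False


@dataclass
class PiPair:
    ring_a: int
    ring_b: int
    centroid_distance: float
    interplanar_angle: float
    same_helix: bool | None = None
    pattern: str = "unclassified"


@dataclass
class ContactMap:
    labels: list[str]
    mean_counts: np.ndarray     # mean intermolecular pairs in contact / frame
    probability: np.ndarray     # fraction of frames with >= 1 contact
    n_frames: int
    n_cells: int = 1

    def entry(self, g1: str, g2: str) -> tuple[float, float]:
        i, j = self.labels.index(g1), self.labels.index(g2)
        return float(self.mean_counts[i, j]), float(self.probability[i, j])


@dataclass
class FELGrid:
    distance_edges: np.ndarray
    angle_edges: np.ndarray
    probability: np.ndarray     # ΣP = 1 over occupied bins
    free_energy: np.ndarray     # kJ/mol, NaN where P = 0
    temperature: float
    gas_constant: float = R_GAS


# ------------------------------------------------------- neighbour search

def periodic_pairs(cell: UnitCell, pos: np.ndarray, cutoff: float,
                   pos_b: np.ndarray | None = None):
    """All pairs within ``cutoff`` under minimum image.

    Returns ``(i, j, dvec, dist)`` arrays; with one point set, pairs are
    unique with i < j.  Candidate pairs come from a KD-tree over the 27
    periodic images, then distances are reduced to the true minimum
    image.
    """
    pos = np.asarray(pos, float)
    self_pairs = pos_b is None
    qos = pos if self_pairs else np.asarray(pos_b, float)
    if len(pos) == 0 or len(qos) == 0:
        empty = np.empty(0, int)
        return empty, empty, np.empty((0, 3)), np.empty(0)
    vecs = cell.lattice_vectors
    tree = cKDTree(qos)
    seen: set[tuple[int, int]] = set()
    ii: list[int] = []
    jj: list[int] = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                shift = a * vecs[0] + b * vecs[1] + c * vecs[2]
                hits = tree.query_ball_point(pos + shift, cutoff + 1e-9)
                for i, nbrs in enumerate(hits):
                    for j in nbrs:
                        if self_pairs:
                            if i == j:
                                continue
                            key = (min(i, j), max(i, j))
                        else:
                            key = (i, j)
                        if key not in seen:
                            seen.add(key)
                            ii.append(key[0])
                            jj.append(key[1])
    ii = np.array(ii, int)
    jj = np.array(jj, int)
    if len(ii) == 0:
        return ii, jj, np.empty((0, 3)), np.empty(0)
    dvec, dist = min_image_many(cell, qos[jj] - pos[ii])
    keep = dist <= cutoff
    return ii[keep], jj[keep], dvec[keep], dist[keep]


def _covalent_hydrogens(structure: CrystalStructure) -> dict[int, list[int]]:
    """heavy atom_id → bonded hydrogen atom_ids (within molecules)."""
    out: dict[int, list[int]] = {}
    for atoms in structure.molecules().values():
        heavies = [a for a in atoms if not a.is_hydrogen]
        hydros = [a for a in atoms if a.is_hydrogen]
        if not hydros:
            continue
        hp = np.array([h.position for h in hydros])
        for a in heavies:
            d = np.linalg.norm(hp - a.position, axis=1)
            cut = 1.2 * (a.covalent_radius + 0.31)
            for k in np.where(d < cut)[0]:
                out.setdefault(a.atom_id, []).append(hydros[k].atom_id)
    return out


def _image_shift(cell: UnitCell, direct: np.ndarray, mindisp: np.ndarray
                 ) -> tuple[int, int, int]:
    shift = cart_to_frac(cell, mindisp - direct)
    return tuple(int(round(x)) for x in shift)


def detect_hbonds(structure: CrystalStructure, criteria: HBondCriteria | None = None,
                  cell: UnitCell | None = None) -> list[HBond]:
    """Detect hydrogen bonds in one frame under minimum image.

    Donors are N/O atoms covalently bound to at least one hydrogen;
    acceptors are any N/O.  When a donor candidate carries no hydrogen
    and ``heavy_atom_fallback`` is set, the bond is accepted on the
    D···A distance alone and flagged ``fallback=True``.
    """
    criteria = criteria or HBondCriteria()
    cell = cell or structure.cell
    atoms = structure.atoms
    pos = structure.positions
    byid = {a.atom_id: k for k, a in enumerate(atoms)}
    hyd = _covalent_hydrogens(structure)

    # the fallback targets molecules whose hydrogens are not modelled at
    # all (typically water in a CIF); molecules that do carry hydrogens
    # keep the strict D-H···A criterion for every donor
    mols_with_h = {a.molecule_id for a in atoms if a.is_hydrogen}
    donor_ids = [a.atom_id for a in atoms
                 if a.element.upper() in criteria.donor_elements
                 and (a.atom_id in hyd
                      or (criteria.heavy_atom_fallback
                          and a.molecule_id not in mols_with_h))]
    acceptor_ids = [a.atom_id for a in atoms
                    if a.element.upper() in criteria.acceptor_elements]
    if not donor_ids or not acceptor_ids:
        return []
    dpos = pos[[byid[i] for i in donor_ids]]
    apos = pos[[byid[i] for i in acceptor_ids]]
    di, aj, dvec, dist = periodic_pairs(cell, dpos, criteria.donor_acceptor_max,
                                        pos_b=apos)
    bonds: list[HBond] = []
    for k in range(len(di)):
        d_id = donor_ids[di[k]]
        a_id = acceptor_ids[aj[k]]
        if d_id == a_id:
            continue
        donor = atoms[byid[d_id]]
        acceptor = atoms[byid[a_id]]
        shift = _image_shift(cell, acceptor.position - donor.position, dvec[k])
        # a bond to a periodic image of the same molecule is intermolecular
        intermol = donor.molecule_id != acceptor.molecule_id or shift != (0, 0, 0)
        if not intermol and not criteria.include_intramolecular:
            continue
        a_image = donor.position + dvec[k]
        h_ids = hyd.get(d_id, [])
        if h_ids:
            best_angle, best_h = -1.0, None
            for h_id in h_ids:
                hpos = pos[byid[h_id]]
                v1 = donor.position - hpos
                v2 = a_image - hpos
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 < 1e-9 or n2 < 1e-9:
                    continue
                ang = float(np.degrees(np.arccos(
                    np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))))
                if ang > best_angle:
                    best_angle, best_h = ang, h_id
            if best_h is None or best_angle < criteria.dha_angle_min:
                continue
            bonds.append(HBond(d_id, best_h, a_id, float(dist[k]), best_angle,
                               donor.molecule_id, acceptor.molecule_id, shift))
        elif criteria.heavy_atom_fallback:
            bonds.append(HBond(d_id, None, a_id, float(dist[k]), None,
                               donor.molecule_id, acceptor.molecule_id, shift,
                               fallback=True))
    return bonds


# -------------------------------------------------------------- contacts

def _frame_contacts(frame: CrystalStructure, groups: dict[int, str],
                    criteria: ContactCriteria):
    """(group_i, group_j, count) contact tallies for one frame."""
    atoms = [a for a in frame.atoms if not a.is_hydrogen]
    if not atoms:
        return {}
    pos = np.array([a.position for a in atoms])
    ii, jj, _, dist = periodic_pairs(frame.cell, pos, criteria.max_cutoff)
    tallies: dict[tuple[str, str], int] = {}
    for k in range(len(ii)):
        a, b = atoms[ii[k]], atoms[jj[k]]
        if a.molecule_id == b.molecule_id:
            continue
        is_cc = a.element.upper() == "C" and b.element.upper() == "C"
        cutoff = criteria.cc_cutoff if is_cc else criteria.other_cutoff
        if dist[k] > cutoff:
            continue
        g1, g2 = sorted((groups[a.atom_id], groups[b.atom_id]))
        tallies[(g1, g2)] = tallies.get((g1, g2), 0) + 1
    return tallies


def contact_map(frames: Trajectory | list[CrystalStructure],
                groups: dict[int, str],
                criteria: ContactCriteria | None = None,
                window: tuple[float, float] | None = None,
                last_fraction: float | None = None,
                labels: list[str] | None = None,
                n_cells: int = 1) -> ContactMap:
    """Group-pair contact statistics over trajectory frames.

    For every group pair, reports the mean number of intermolecular atom
    pairs in contact per frame and the contact probability (fraction of
    frames with at least one contact).  ``window`` restricts to an
    absolute time range (ps); ``last_fraction`` to the final fraction of
    frames (the analysis default is the second half of the trajectory).
    """
    criteria = criteria or ContactCriteria()
    if isinstance(frames, Trajectory):
        traj = frames
        if window is not None:
            traj = traj.window(*window)
        elif last_fraction is not None:
            traj = traj.window(last_fraction=last_fraction)
        frame_list = [traj.frame(i) for i in range(traj.n_frames)]
    else:
        frame_list = list(frames)
    if not frame_list:
        raise ValueError("no frames to analyse")
    if labels is None:
        labels = sorted(set(groups.values()))
    index = {g: i for i, g in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n))
    hits = np.zeros((n, n))
    for frame in frame_list:
        tallies = _frame_contacts(frame, groups, criteria)
        for (g1, g2), c in tallies.items():
            i, j = index[g1], index[g2]
            counts[i, j] += c
            counts[j, i] += c if i != j else 0
            hits[i, j] += 1
            hits[j, i] += 1 if i != j else 0
    n_frames = len(frame_list)
    return ContactMap(labels, counts / n_frames, hits / n_frames, n_frames, n_cells)


# ----------------------------------------------------------------- π–π

def detect_pipi(rings, cell: UnitCell, cutoff: float = 6.5) -> list[PiPair]:
    """Ring pairs (different molecules) with centroid separation ≤ cutoff.

    The interplanar angle between the unsigned ring normals is folded to
    [0°, 90°]; 0° is cofacial stacking, 90° a T-shaped contact.
    """
    pairs: list[PiPair] = []
    if len(rings) < 2:
        return pairs
    cents = np.array([r.centroid for r in rings])
    ii, jj, _, dist = periodic_pairs(cell, cents, cutoff)
    for k in range(len(ii)):
        ra, rb = rings[ii[k]], rings[jj[k]]
        if ra.molecule_id == rb.molecule_id:
            continue
        cosang = abs(float(ra.normal @ rb.normal))
        angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
        pairs.append(PiPair(ii[k], jj[k], float(dist[k]), angle))
    return pairs


DEFAULT_PIPI_BANDS = {"I_II_edge": 6.5, "II_III_edge": 8.0}


def classify_pipi(pairs: list[PiPair], rings, strand_membership: dict[int, int],
                  bands: dict[str, float] | None = None,
                  cutoff: float | None = None) -> list[PiPair]:
    """Label ring pairs with the packing patterns I / II / III.

    Patterns I and II are inter-helix stackings (centroid distance below
    and above ``I_II_edge``); pattern III is intra-helix stacking beyond
    ``II_III_edge``.  ``strand_membership`` maps molecule_id → helix id.
    """
    bands = {**DEFAULT_PIPI_BANDS, **(bands or {})}
    edge1 = bands["I_II_edge"]
    edge2 = bands["II_III_edge"]
    for pair in pairs:
        ma = rings[pair.ring_a].molecule_id
        mb = rings[pair.ring_b].molecule_id
        if ma not in strand_membership or mb not in strand_membership:
            raise ValueError(f"molecule {ma if ma not in strand_membership else mb} "
                             "has no helix membership")
        same = strand_membership[ma] == strand_membership[mb]
        pair.same_helix = same
        d = pair.centroid_distance
        if not same and d < edge1:
            pair.pattern = "I"
        elif not same and edge1 <= d <= edge2:
            pair.pattern = "II"
        elif same and d >= edge2:
            pair.pattern = "III"
        else:
            pair.pattern = "unclassified"
    return pairs


def per_unit(count: float, n_cells: int) -> float:
    """Normalise an extensive tally to one crystal unit cell."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return count / n_cells


# ------------------------------------------------------------------ FEL

def free_energy_landscape(observations, distance_bins=30, angle_bins=30,
                          temperature: float = 300.0,
                          distance_range=None, angle_range=None) -> FELGrid:
    """Boltzmann-inverted 2-D histogram: G = −RT ln P (distance, angle).

    P is normalised over all observations, so the global minimum of G is
    at the most-populated bin and G ≥ 0 everywhere it is defined; empty
    bins are masked as NaN.
    """
    obs = np.asarray(list(observations), float)
    if obs.size == 0:
        raise ValueError("no observations for the free-energy landscape")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    d, a = obs[:, 0], obs[:, 1]
    H, d_edges, a_edges = np.histogram2d(
        d, a, bins=[distance_bins, angle_bins],
        range=None if distance_range is None and angle_range is None
        else [distance_range or (d.min(), d.max()),
              angle_range or (a.min(), a.max())])
    P = H / H.sum()
    with np.errstate(divide="ignore"):
        G = np.where(P > 0, -R_GAS * temperature * np.log(P), np.nan)
    return FELGrid(d_edges, a_edges, P, G, temperature)


# ----------------------------------------------------------------- RMSD

def rmsd_series(traj: Trajectory, superpose: bool = True) -> np.ndarray:
    """All-atom RMSD of each frame against the first frame (Å).

    With ``superpose`` the optimal rigid-body rotation+translation
    (Kabsch) is applied before the deviation is measured.
    """
    from scipy.spatial.transform import Rotation

    ref = traj.positions[0]
    ref_c = ref - ref.mean(axis=0)
    out = np.zeros(traj.n_frames)
    for i in range(traj.n_frames):
        cur = traj.positions[i]
        if superpose:
            cur_c = cur - cur.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, cur_c)
            cur_c = rot.apply(cur_c)
            diff = cur_c - ref_c
        else:
            diff = cur - ref
        out[i] = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
    return out
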