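"""Supramolecular-chirality analysis: strand tracing, H-bond rotation
profiles, S/Z twist calls, helix fitting and inner diameters.

Sign convention, fixed once for the whole package: angles in the plane
perpendicular to the stacking axis are measured counterclockwise
positive when viewed from the +axis tip (right-handed frame).  A
rotation-angle profile that decreases layer by layer is a clockwise
rotation and is called S (left-handed rope twist); an increasing
profile is counterclockwise and is called Z (right-handed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .interactions import HBond, HBondCriteria, detect_hbonds
from .lattice import LayerAssignment, assign_layers, build_supercell
from .structures import CrystalStructure

logger = logging.getLogger("helixrope")

__all__ = [
    "RotationProfile", "TwistCall", "Strand", "HelixFit",
    "trace_strands", "rotation_profile", "classify_twist", "fit_helix",
    "circumcircle_diameter", "triple_helix_metrics",
]


@dataclass
class RotationProfile:
    """Unwrapped signed H-bond rotation angle per stacking layer."""

    layers: np.ndarray          # layer indices with data
    theta: np.ndarray           # degrees, theta[0] = 0, unwrapped
    axis: np.ndarray
    spread: np.ndarray          # per-layer std across strands, degrees
    reference: str = ""

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, int)
        self.theta = np.asarray(self.theta, float)
        self.spread = np.asarray(self.spread, float)


@dataclass
class TwistCall:
    verdict: str                # "S", "Z" or "undetermined"
    slope: float                # degrees / layer
    slope_stderr: float
    threshold: float


@dataclass
class Strand:
    molecule_ids: list[int]     # ordered by increasing axis projection
    helix_id: int = -1


@dataclass
class HelixFit:
    axis_point: np.ndarray
    axis_direction: np.ndarray  # unit vector, oriented so rise > 0
    radius: float
    pitch: float
    delta_theta: float          # degrees / step, signed
    delta_z: float              # Å / step
    handedness: str             # "S" (left) or "Z" (right)
    rms_residual: float


# ------------------------------------------------------------- strands

def trace_strands(hbonds: list[HBond], structure: CrystalStructure,
                  layers: LayerAssignment, merge_radius: float = 4.0
                  ) -> list[Strand]:
    """Chain molecules linked by H-bonds between consecutive layers.

    Molecules are graph nodes and intermolecular H-bonds whose donor and
    acceptor sit in adjacent layers are edges.  A molecule H-bonded to
    more than one partner in the next layer keeps only the shortest
    D···A edge (logged).  Strands whose fitted axes lie within
    ``merge_radius`` of each other share one ``helix_id`` (a bundle).
    """
    lay = layers.molecule_layer
    # best (shortest) upward edge per molecule
    up: dict[int, tuple[int, float]] = {}
    for hb in hbonds:
        lm, la = lay.get(hb.donor_molecule), lay.get(hb.acceptor_molecule)
        if lm is None or la is None or abs(la - lm) != 1:
            continue
        lo, hi = ((hb.donor_molecule, hb.acceptor_molecule) if la > lm
                  else (hb.acceptor_molecule, hb.donor_molecule))
        if lo == hi:
            continue
        if lo not in up or hb.da_distance < up[lo][1]:
            if lo in up and up[lo][0] != hi:
                logger.debug("molecule %d branches upward; keeping shortest edge", lo)
            up[lo] = (hi, hb.da_distance)
    succ = {lo: hi for lo, (hi, _) in up.items()}
    has_pred = set(succ.values())
    strands: list[Strand] = []
    visited: set[int] = set()
    for start in sorted(succ):
        if start in has_pred or start in visited:
            continue
        chain = [start]
        visited.add(start)
        cur = start
        while cur in succ:
            nxt = succ[cur]
            if nxt in visited:
                raise ValueError("cycle detected while tracing strands")
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        strands.append(Strand(chain))
    leftovers = set(succ) - visited
    if leftovers:
        raise ValueError("cycle detected while tracing strands")

    # bundle assignment: cluster the strands' fitted axis points in the
    # plane perpendicular to the layer axis
    axis = layers.axis
    centers = []
    for strand in strands:
        pts = _molecule_centroids(structure, strand.molecule_ids)
        try:
            fit = fit_helix(pts, axis_hint=axis, fix_axis=True)
            c = fit.axis_point
        except ValueError:
            c = pts.mean(axis=0)
        centers.append(c - (c @ axis) * axis)
    helix_id = [-1] * len(strands)
    next_id = 0
    for i in range(len(strands)):
        if helix_id[i] >= 0:
            continue
        helix_id[i] = next_id
        stack = [i]
        while stack:
            k = stack.pop()
            for j in range(len(strands)):
                if helix_id[j] < 0 and np.linalg.norm(centers[k] - centers[j]) <= merge_radius:
                    helix_id[j] = next_id
                    stack.append(j)
        next_id += 1
    for strand, hid in zip(strands, helix_id):
        strand.helix_id = hid
    return strands


def _molecule_centroids(structure: CrystalStructure, mol_ids,
                        atom_name: str | None = None) -> np.ndarray:
    """Per-molecule centroid, or the position of one named atom."""
    mols = structure.molecules()
    out = []
    for m in mol_ids:
        if atom_name is None:
            out.append(np.mean([a.position for a in mols[m]], axis=0))
        else:
            sel = [a.position for a in mols[m] if a.name.upper() == atom_name.upper()]
            out.append(sel[0] if sel
                       else np.mean([a.position for a in mols[m]], axis=0))
    return np.array(out)


# ----------------------------------------------------- rotation profile

def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    axis = axis / np.linalg.norm(axis)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ axis) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    u = trial - (trial @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _hbond_vector(hb: HBond, structure: CrystalStructure) -> np.ndarray:
    byid = {a.atom_id: a for a in structure.atoms}
    d = byid[hb.donor_atom].position
    a = byid[hb.acceptor_atom].position
    shift = np.array(hb.image_shift, float) @ structure.cell.lattice_vectors
    return (a + shift) - d


def rotation_profile(hbonds: list[HBond], structure: CrystalStructure,
                     layers: LayerAssignment,
                     axis: np.ndarray | None = None,
                     strands: list[Strand] | None = None) -> RotationProfile:
    """Signed rotation angle of H-bond projections per stacking layer.

    Each H-bond's donor→acceptor vector is projected onto the plane
    perpendicular to the axis.  The angle of layer n is measured against
    the reference projection of the first populated layer, positive
    counterclockwise viewed from the +axis tip, and unwrapped
    cumulatively (nearest branch, assuming |Δθ| < 180°/layer).

    When strands are supplied, each strand contributes its own profile
    against its own first-layer reference and layers are averaged across
    strands (per-layer spread reported); this is required whenever the
    bundle's strands are rotated copies of each other, since their
    absolute projections differ by the strand azimuth.
    """
    axis = layers.axis if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    u, v = _plane_basis(axis)
    lay = layers.molecule_layer

    def bond_angle(hb: HBond) -> tuple[int, float] | None:
        vec = _hbond_vector(hb, structure)
        p = np.array([vec @ u, vec @ v])
        if np.linalg.norm(p) < 1e-6 * np.linalg.norm(vec):
            logger.warning("H-bond %d→%d parallel to axis; skipped",
                           hb.donor_atom, hb.acceptor_atom)
            return None
        layer = lay.get(hb.donor_molecule)
        if layer is None:
            return None
        return layer, float(np.degrees(np.arctan2(p[1], p[0])))

    if strands:
        groups = []
        for strand in strands:
            members = set(strand.molecule_ids)
            groups.append([hb for hb in hbonds if hb.donor_molecule in members
                          and hb.acceptor_molecule in members])
        reference = "per-strand first-layer H-bond"
    else:
        groups = [list(hbonds)]
        reference = "first-layer H-bond (smallest D···A)"

    # per group: circular-mean angle per layer, then consecutive-layer
    # increments; increments are pooled across groups so that strand
    # fragments with different (arbitrary) references still agree
    increments: dict[int, list[float]] = {}
    for bonds in groups:
        angles: dict[int, list[float]] = {}
        for hb in bonds:
            res = bond_angle(hb)
            if res is None:
                continue
            angles.setdefault(res[0], []).append(res[1])
        layer_ids = sorted(angles)
        mean_angle = {}
        for l in layer_ids:
            a = np.radians(angles[l])
            mean_angle[l] = float(np.degrees(np.arctan2(np.sin(a).mean(),
                                                        np.cos(a).mean())))
        for l0, l1 in zip(layer_ids, layer_ids[1:]):
            if l1 - l0 != 1:
                continue    # gap: no increment measurable across it
            d = mean_angle[l1] - mean_angle[l0]
            d = (d + 180.0) % 360.0 - 180.0    # nearest branch, |Δθ| < 180°
            increments.setdefault(l0, []).append(d)

    if not increments:
        raise ValueError("rotation profile needs H-bonds in at least two layers")
    start = min(increments)
    layers_out = [start]
    theta_out = [0.0]
    spread_out = [0.0]
    cur = 0.0
    for l in range(start, max(increments) + 1):
        if l not in increments:
            continue    # gap recorded implicitly: the layer index jumps
        cur += float(np.mean(increments[l]))
        layers_out.append(l + 1)
        theta_out.append(cur)
        spread_out.append(float(np.std(increments[l])))
    if len(layers_out) < 2:
        raise ValueError("rotation profile needs H-bonds in at least two layers")
    return RotationProfile(np.array(layers_out), np.array(theta_out), axis,
                           np.array(spread_out), reference)


def classify_twist(profile: RotationProfile, threshold: float = 1.0) -> TwistCall:
    """S/Z verdict from the least-squares slope of θ against layer index.

    Decreasing angles (slope < −threshold) are a clockwise rotation →
    S twist; increasing (slope > +threshold) → Z; otherwise
    undetermined.
    """
    if len(profile.layers) < 3:
        raise ValueError("twist classification needs at least three layers")
    x = profile.layers.astype(float)
    y = profile.theta
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    n = len(x)
    if n > 2:
        resid = y - A @ coef
        s2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        stderr = float(np.sqrt(s2 / sxx)) if sxx > 0 else float("nan")
    else:
        stderr = float("nan")
    if slope < -threshold:
        verdict = "S"
    elif slope > threshold:
        verdict = "Z"
    else:
        verdict = "undetermined"
    return TwistCall(verdict, slope, stderr, threshold)


# ------------------------------------------------------------ helix fit

def _helix_model(params, n, fixed_axis=None):
    # params: ox, oy, oz, [th, ph,] phi0, r, dtheta, dz
    if fixed_axis is None:
        ox, oy, oz, th, ph, phi0, r, dth, dz = params
        w = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    else:
        ox, oy, oz, phi0, r, dth, dz = params
        w = fixed_axis
    u, v = _plane_basis(w)
    ang = phi0 + n * dth
    return (np.array([ox, oy, oz])[None, :]
            + r * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
            + (n * dz)[:, None] * w)


def fit_helix(points: np.ndarray, axis_hint: np.ndarray | None = None,
              fix_axis: bool = False, residual_warn: float = 1.0) -> HelixFit:
    """Fit an ideal helix to ordered points.

    Initialisation: axis from the principal component of the points (or
    ``axis_hint``), circle fit of the projected points for the radius
    and axis position, consecutive-point averages for the angular step
    Δθ and rise Δz; then joint nonlinear least squares over all eight
    parameters.  The axis is oriented so the rise is positive along the
    point order; handedness is Z (right) for Δθ > 0, S (left) for
    Δθ < 0.

    With ``fix_axis`` the axis direction is held at ``axis_hint`` (e.g.
    the crystallographic c axis from the layer analysis) instead of
    being refined; this removes the tilt–radius–rise degeneracy that
    makes free-axis fits ill-conditioned on short, shallow arcs.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("helix fit needs at least 4 ordered 3-D points")
    center = pts.mean(axis=0)
    centered = pts - center
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate helix: points are collinear")
    if axis_hint is not None:
        w = np.asarray(axis_hint, float)
        w = w / np.linalg.norm(w)
    else:
        w = vt[0]
    # orient along increasing point order
    z = centered @ w
    if z[-1] < z[0]:
        w = -w
        z = -z
    u, v = _plane_basis(w)
    xy = np.column_stack([centered @ u, centered @ v])
    # Kåsa algebraic circle fit
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r0 = float(np.sqrt(max(sol[2] + cx**2 + cy**2, 1e-12)))
    rel = xy - [cx, cy]
    phi = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    n = np.arange(len(pts), dtype=float)
    dth0 = float(np.mean(np.diff(phi)))
    dz0 = float(np.mean(np.diff(z)))
    if abs(dz0) < 1e-10:
        raise ValueError("degenerate helix: no rise along the axis")
    origin = center + cx * u + cy * v
    th0 = float(np.arccos(np.clip(w[2], -1, 1)))
    ph0 = float(np.arctan2(w[1], w[0]))
    # the model uses _plane_basis(w), which differs from (u, v) only by
    # an in-plane rotation absorbed into phi0
    o0 = origin + z[0] * w      # axis point at the first point's height
    um, vm = _plane_basis(w)
    first = pts[0] - o0
    phi0_m = float(np.arctan2(first @ vm, first @ um))
    if fix_axis:
        if axis_hint is None:
            raise ValueError("fix_axis requires an axis_hint")
        x0 = [o0[0], o0[1], o0[2], phi0_m, r0, dth0, dz0]
        fixed = w.copy()
    else:
        x0 = [o0[0], o0[1], o0[2], th0, ph0, phi0_m, r0, dth0, dz0]
        fixed = None

    def residuals(params):
        return (_helix_model(params, n, fixed) - pts).ravel()

    fit = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if fix_axis:
        ox, oy, oz, phi0, r, dth, dz = fit.x
        w_fit = fixed
    else:
        ox, oy, oz, th, ph, phi0, r, dth, dz = fit.x
        w_fit = np.array([np.sin(th) * np.cos(ph),
                          np.sin(th) * np.sin(ph), np.cos(th)])
    r = abs(float(r))
    # canonical orientation: positive rise
    if dz < 0:
        w_fit, dth, dz = -w_fit, -dth, -dz
    dth_deg = float(np.degrees(dth))
    rms = float(np.sqrt(np.mean(np.sum(
        (_helix_model(fit.x, n, fixed) - pts) ** 2, axis=1))))
    if rms > residual_warn:
        logger.warning("helix fit residual %.3f Å exceeds %.1f Å", rms, residual_warn)
    pitch = float(360.0 / abs(dth_deg) * dz) if dth_deg != 0 else float("inf")
    handedness = "Z" if dth_deg > 0 else "S"
    return HelixFit(np.array([ox, oy, oz]), w_fit, r, pitch, dth_deg,
                    float(dz), handedness, rms)


def circumcircle_diameter(p1, p2, p3) -> float:
    """Diameter of the circle through three points, in their own plane."""
    p1, p2, p3 = (np.asarray(p, float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    cross = np.linalg.norm(np.cross(p2 - p1, p3 - p1))  # = 2 × triangle area
    if cross < 1e-12 * max(a * b, 1.0):
        raise ValueError("points are collinear; no circumscribed circle")
    return float(a * b * c / cross)


# --------------------------------------------------------------- driver

def triple_helix_metrics(structure: CrystalStructure,
                         supercell: tuple[int, int, int] | None = None,
                         axis=(0.0, 0.0, 1.0),
                         gap_tol: float | None = None,
                         hbond_criteria: HBondCriteria | None = None,
                         restrict_to_wmc: bool = True,
                         groups: dict[int, str] | None = None,
                         twist_threshold: float = 1.0,
                         ca_name: str = "CA", ca_residue: str = "TRP",
                         merge_radius: float = 4.0,
                         fit_atom: str | None = None) -> dict:
    """End-to-end helix metrics for one crystal structure.

    Pipeline: (optional) supercell → layer assignment → H-bond
    detection (optionally restricted to Trp-mainchain W_mc–W_mc bonds)
    → strand tracing → per-strand helix fits → rotation profile and S/Z
    twist call → per-layer Cα inner diameters.  The "diameter" is
    reported both as 2 × fitted strand radius and as the Cα circumcircle
    diameter, which are distinct observables.
    """
    from .groups import assign_groups

    if supercell is not None:
        structure = build_supercell(structure, supercell)
    n_cells = getattr(structure, "n_cells", 1)
    layers = assign_layers(structure, axis=axis, gap_tol=gap_tol)
    hbonds = detect_hbonds(structure, hbond_criteria)
    if restrict_to_wmc:
        g = groups or assign_groups(structure)
        wmc = [hb for hb in hbonds
               if g.get(hb.donor_atom) == "W_mc" and g.get(hb.acceptor_atom) == "W_mc"]
        if wmc:
            hbonds_used = wmc
        else:
            logger.warning("no W_mc–W_mc H-bonds found; using all intermolecular bonds")
            hbonds_used = hbonds
    else:
        hbonds_used = hbonds
    strands = trace_strands(hbonds_used, structure, layers, merge_radius)
    fits: list[HelixFit] = []
    weights: list[int] = []
    for strand in strands:
        if len(strand.molecule_ids) < 4:
            continue
        pts = _molecule_centroids(structure, strand.molecule_ids, atom_name=fit_atom)
        try:
            fits.append(fit_helix(pts, axis_hint=layers.axis, fix_axis=True))
            weights.append(len(strand.molecule_ids))
        except ValueError as exc:
            logger.warning("strand helix fit skipped: %s", exc)
    profile = rotation_profile(hbonds_used, structure, layers, strands=strands or None)
    twist = classify_twist(profile, threshold=twist_threshold)

    # per-layer Cα circumcircle diameters within each bundle
    mols = structure.molecules()
    strand_of = {m: s.helix_id for s in strands for m in s.molecule_ids}
    inner: list[float] = []
    for layer in range(layers.n_layers):
        members = layers.members(layer)
        by_bundle: dict[int, list[int]] = {}
        for m in members:
            hid = strand_of.get(m)
            if hid is not None:
                by_bundle.setdefault(hid, []).append(m)
        for hid, ms in by_bundle.items():
            cas = []
            for m in ms:
                for a in mols[m]:
                    if a.name.upper() == ca_name.upper() and \
                            a.residue.upper() == ca_residue.upper():
                        cas.append(a.position)
                        break
            if len(cas) == 3:
                try:
                    inner.append(circumcircle_diameter(*cas))
                except ValueError:
                    pass
    # longer strands carry proportionally more signal, and a weighted
    # median keeps one badly-conditioned short fragment (a shallow arc
    # after H-bond loss) from poisoning the aggregate
    def weighted_median(values, w):
        order = np.argsort(values)
        cw = np.cumsum(np.asarray(w, float)[order])
        return float(np.asarray(values)[order][np.searchsorted(cw, 0.5 * cw[-1])])

    if fits:
        pitch_strand = weighted_median([f.pitch for f in fits], weights)
        radius_strand = weighted_median([f.radius for f in fits], weights)
    else:
        pitch_strand = radius_strand = float("nan")

    # headline pitch: strand fits use molecule positions, whose azimuth
    # is levered by the helix radius, so they beat the (short-arm)
    # H-bond-direction profile; the profile slope is the fallback
    if np.isfinite(pitch_strand):
        pitch = pitch_strand
    elif twist.slope != 0 and np.isfinite(twist.slope) and layers.layer_spacing > 0:
        pitch = float(360.0 / abs(twist.slope) * layers.layer_spacing)
    else:
        pitch = float("nan")
    # radius: pooled circle fit of all strand points per bundle gives
    # full azimuthal coverage even for shallow twists
    bundle_pts: dict[int, list[np.ndarray]] = {}
    for strand in strands:
        pts = _molecule_centroids(structure, strand.molecule_ids, atom_name=fit_atom)
        bundle_pts.setdefault(strand.helix_id, []).append(pts)
    radii, nums = [], []
    u, v = _plane_basis(layers.axis)
    for pts_list in bundle_pts.values():
        pts = np.vstack(pts_list)
        if len(pts) < 4:
            continue
        xy = np.column_stack([pts @ u, pts @ v])
        A = np.column_stack([2 * xy, np.ones(len(xy))])
        b = (xy ** 2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        radii.append(float(np.sqrt(max(sol[2] + sol[0]**2 + sol[1]**2, 0.0))))
        nums.append(len(pts))
    # weighted median again: a stray fragment clustered as its own
    # "bundle" contributes a partial-arc circle fit that must not drag
    # the aggregate
    radius = weighted_median(radii, nums) if radii else radius_strand
    return {
        "twist": twist,
        "profile": profile,
        "strands": strands,
        "helix_fits": fits,
        "pitch_A": pitch,
        "radius_A": radius,
        "diameter_A": 2.0 * radius,
        "pitch_strand_A": pitch_strand,
        "radius_strand_A": radius_strand,
        "inner_diameter_A": inner,
        "n_strands": len(strands),
        "n_layers": layers.n_layers,
        "n_hbonds": len(hbonds),
        "n_hbonds_used": len(hbonds_used),
        "n_cells": n_cells,
        "layers": layers,
    }
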