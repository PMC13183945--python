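# Methods

This note records the models, conventions and design choices behind
helixrope, in the package's own words. It states no empirical number
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model and units

All internal lengths are ångström, angles degrees; mechanics is SI.
Criteria quoted in nm in the literature are converted once at the
configuration layer (0.35 nm → 3.5 Å, etc.). Unit cells follow the
standard crystallographic convention with the **a** vector along x and
**b** in the xy-plane; the fractional→Cartesian matrix is derived from
(a, b, c, α, β, γ) and inverted for the reverse transform.

Molecules are defined by covalent connectivity: two atoms bond when
their minimum-image distance is below 1.2 × the sum of covalent radii
(Cordero consensus values), and connected components are molecules.
After assignment each molecule is made whole across periodic
boundaries by walking the bond graph and accumulating image shifts, so
centroids and intramolecular distances are meaningful in wrapped
cells. For inputs whose "molecules" are rigid model fragments rather
than covalent units (the synthetic generator's dummies), the XYZ
fixture dialect carries explicit molecule ids and the PDB reader can
keep residue numbering (`molecule_mode="residue"`).

Symmetry expansion applies all fractional-space operators and drops
duplicates within 0.1 Å after wrapping (standard special-position
handling); expanding an expanded cell is a no-op.

## Periodic geometry

Minimum-image displacements are computed by reducing the fractional
difference with rounding and then minimising over the 27 neighbour
images, which is exact for separations below half the smallest cell
height and verified against a 125-image enumeration oracle in the
tests. Neighbour searches (H-bonds, contacts, ring pairs) use a
scipy KD-tree over the 27 shifted copies rather than cell lists; the
brute-force oracle comparisons in the test suite establish exact set
equality at the problem sizes used.

Stacking layers are found by projecting molecule centroids onto the
helix axis (default: crystallographic c) and splitting the sorted
projections wherever the gap exceeds `gap_tol`. The automatic
threshold is the midpoint of the gap spectrum (half the largest gap),
accepted only when the largest gap exceeds twice the median — i.e.
when within-layer scatter and between-layer spacing are actually
separable; otherwise an explicit `gap_tol` is required. A
median-based default would fail here because most nearest-neighbour
gaps are within-layer and near zero.

## Interaction criteria

* **Hydrogen bond**: donor–acceptor distance ≤ 3.5 Å and D-H···A angle
  ≥ 150°, with the angle measured at the hydrogen. Donors are N/O
  carrying at least one covalently bound H; acceptors any N/O. When a
  molecule has no modelled hydrogens at all (typically water refined
  without H), an opt-in heavy-atom fallback accepts the distance
  criterion alone and flags the bond. The fallback is restricted to
  hydrogen-free molecules so that carbonyl oxygens in ordinary
  molecules never act as phantom donors.
* **Contact**: non-hydrogen atoms within 5.4 Å for C–C pairs, 4.6 Å
  otherwise. Contact maps report, per group pair, both the mean number
  of intermolecular atom pairs in contact per frame and the contact
  probability (fraction of frames with ≥ 1 contact); the normalisation
  of published contact maps is ambiguous, so both are carried.
* **π–π stacking**: ring-centroid separation ≤ 6.5 Å, interplanar
  angle from unsigned ring normals folded to [0°, 90°]. Rings are
  located from per-residue member-atom definitions (indole as separate
  5- and 6-membered rings by default; a fused 9-atom mode exists);
  the normal is the smallest principal axis of the members. Packing
  patterns: inter-helix pairs below 6.5 Å → I, inter-helix 6.5–8.0 Å →
  II, intra-helix ≥ 8.0 Å → III. The band edges are midpoints between
  the characteristic distances (~5, ~7.5, ~8.5 Å) of the three
  patterns and are exposed in configuration.
* **Free-energy landscape**: G = −RT ln P on a 2-D histogram of
  (centroid distance, interplanar angle), R = 8.3145×10⁻³ kJ mol⁻¹ K⁻¹,
  T = 300 K default. P is normalised over all observations, so G ≥ 0
  with its minimum at the most-populated bin; empty bins are NaN.

Group labels (W_aro, W_NH, W_sc, W_mc, P_mc, P_sc, water, other) come
from an ordered rule table shipped as YAML; rules are first-match-wins,
which resolves the chemical overlap between the indole labels and the
broader Trp side chain into an exclusive partition. Other naming
schemes plug in by supplying a different table.

## Chirality pipeline

The driver runs: (optional) supercell → layers → H-bond detection
(restricted to W_mc–W_mc bonds by default, configurable) → strand
tracing → helix fits → rotation profile → twist call → per-layer Cα
circumcircle diameters.

**Sign convention (fixed once).** In-plane angles are measured
counterclockwise positive viewed from the +axis tip (right-handed
frame). A decreasing rotation profile is therefore a clockwise
rotation and is called S = left-handed rope twist; increasing is Z =
right-handed. Mirror reflection through any plane containing the axis
negates the profile exactly, so verdicts are antisymmetric under
mirroring — a property the tests check exactly, with no tolerance.

**Strand tracing.** Molecules are nodes; intermolecular H-bonds
between adjacent layers are edges. Branches keep the shortest D···A
edge; cycles are an error. Strands are grouped into bundles
(helix ids) by clustering their fitted axis points within
`merge_radius` (default 4 Å).

**Rotation profile.** Each H-bond's donor→acceptor vector is projected
onto the plane perpendicular to the axis. Angles are aggregated as
layer-to-layer *increments* (circular mean per layer within a strand,
nearest-branch difference across layers, pooled over strands, then
integrated). Increments rather than absolute angles are essential for
two reasons: the strands of a bundle are rotated copies of one another
(their absolute projections differ by the strand azimuth), and noise
can delete individual H-bonds, fragmenting strands — a fragment's
absolute reference is arbitrary, its increments are not. Unwrapping
assumes |Δθ| < 180°/layer. The twist call is the least-squares slope
of the profile with a ±1°/layer dead band (`undetermined` within it).

**Helix fits.** An ideal helix (axis point, axis direction, phase,
radius, Δθ, Δz) is fitted to ordered per-molecule points by nonlinear
least squares, initialised from the principal axis, an algebraic
circle fit and consecutive-point averages. In the pipeline the axis
direction is *fixed* to the stacking axis from the layer analysis:
free-axis fits on short shallow arcs are ill-conditioned because an
axis tilt trades against radius and rise. Pitch = 360/|Δθ| · Δz;
handedness is Z for Δθ > 0 about the axis oriented with positive rise.

**Aggregation.** Reported pitch is the strand-length-weighted *median*
of per-strand fits (robust to one badly conditioned short fragment);
reported radius comes from per-bundle circle fits of all pooled strand
points — full azimuthal coverage (S strands 2π/S apart) conditions the
circle even when each strand's own arc is shallow — again aggregated
by weighted median. 2 × radius and the per-layer Cα circumcircle
diameter are reported separately: they are different observables (the
strand-centroid cylinder versus the inner channel), and published
"diameter" figures do not always say which is meant.

## Synthetic data

`gen_triple_helix` places rigid model molecules on the helical lattice:
strand s, layer n sits at azimuth φ₀ + 2πs/S + nΔθ and height nΔz on a
cylinder of radius r, each molecule rotated by its own azimuth.
The molecule carries a donor N–H, an acceptor O positioned so the
zero-jitter consecutive-layer N···O distance is exactly 2.9 Å with the
H collinear on the N→O line (tilted 20° off-axis so the acceptor does
not collide with its own donor), a planar indole-like ring 4.5 Å
radially outward, and a Cα marker 2 Å inward. Atom names follow the
cyclo-Trp-Pro group table, so the designed interlayer bonds are
W_mc–W_mc. Ground truth (handedness = sign Δθ, pitch = 360/|Δθ|·Δz,
radius, layer count, Cα circle diameter) is returned alongside.
Hexagonal bundle packing and core water sites are optional.

**Disorder model.** Default jitter displaces each molecule rigidly by
one Gaussian 3-vector (σ per coordinate): the generator's molecules
are rigid bodies, and independent per-atom noise of realistic
magnitude on a 1.0 Å N–H bond would produce tens of degrees of
spurious D-H···A angular noise — a property of the noise model, not of
any crystal. Per-atom mode remains available (`jitter_mode="atom"`),
and `gen_jitter_trajectory` uses iid per-coordinate noise by design
(frames emulate uncorrelated thermal snapshots for RMSD/contact
statistics). What passing tests on these synthetics demonstrate is
the geometric bookkeeping — detection criteria, sign conventions,
estimator accuracy — not force-field realism, hydration structure or
thermodynamics.

The recovery study in the tests and acceptance script draws Δθ from
±[5°, 90°] and σ from [0, 0.2] Å, with n_layers =
min(48, max(36, ⌈360/|Δθ|⌉+1)) so every strand covers at least about a
full turn where the twist permits; shallower twists need longer arcs
for a conditioned fit, and the floor keeps the per-case estimator
variance a few times below the 1 % acceptance band.

## Mechanics

Tensile: modulus is the least-squares slope of stress over the initial
linear window (default strain 0–0.2 %); fracture is the maximum-stress
point; work of rupture is the trapezoidal ∫σ dε to fracture.

Hertz indentation: F = (4/3)·E/(1−ν²)·√R·δ^{3/2} with δ = (z − z₀) −
F/k_c (cantilever-deflection corrected). E and z₀ are fitted jointly;
z₀ initialises at the first point exceeding 3× the pre-contact noise
SD. Residuals are weighted relative to the model force with a 2 %
floor: AFM force noise is predominantly multiplicative, and absolute
residuals let the high-force tail dominate while z₀ — determined near
contact — drifts, biasing E by a few percent. Robust soft-L1 loss is
the default (snap-in artifacts); plain least squares is available.
Point stiffness is F_max divided by the corrected sample deformation
at maximum load (a local-slope variant is provided).

Defaults follow the usual AFM setup for these crystals: ν = 0.3,
R = 10 nm, k_c = 200 N/m.

## Numerical notes and limitations

* Helix-fit refinement tolerances 1e-12 (scipy `least_squares`); the
  in-plane basis is rebuilt per axis candidate, with the induced phase
  absorbed into φ₀.
* Degenerate inputs raise informative errors: collinear points (no
  helix, no circumcircle), < 3 profile layers (no twist call), empty
  observation sets (no FEL), zero post-contact data (no Hertz fit).
* The unwrapping limit |Δθ| < 180°/layer is inherent to single-frame
  profiles; screw symmetries beyond that alias.
* Contact/H-bond exactness guarantees hold for cutoffs below half the
  smallest cell height (guarded); extremely oblique cells should be
  niggli-reduced upstream, which this package does not do.
* The CIF reader targets the small-molecule dialect
  (`_symmetry_equiv`/`_space_group_symop` loops, riding hydrogens read
  as ordinary atoms); disorder models and anisotropic displacement
  parameters are out of scope.
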