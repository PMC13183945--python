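# helixrope

Structural analysis of supramolecular helical ropes built from small
cyclic dipeptides — the crystals in which stacked cyclo-Trp-Pro
molecules wind into three-stranded helices whose handedness (an S or Z
rope twist) is set by the stereochemistry of a single residue.

Given a crystal structure (CIF/PDB), an MD-style coordinate series, or
force curves from tensile/AFM measurements, the package computes:

* **supramolecular chirality** — trace the H-bonded strands, measure the
  rotation angle of the Trp-mainchain H-bonds layer by layer along the
  stacking axis, and call the twist: a *decreasing* (clockwise) angle
  profile is an **S** (left-handed) rope, an *increasing*
  (counterclockwise) one is **Z** (right-handed);
* **helix geometry** — per-strand helix fits (pitch = 360°/|Δθ| · Δz,
  radius, handedness) and the inner diameter as the circumcircle of the
  three Trp Cα atoms in one stacking layer;
* **interaction statistics** — hydrogen bonds (D···A ≤ 3.5 Å and
  D-H···A ≥ 150°), group–group contact maps (C–C pairs within 5.4 Å,
  any other pair within 4.6 Å), π–π ring stacking (centroid separation
  ≤ 6.5 Å) with the three packing patterns (I/II inter-helix, III
  intra-helix), and free-energy landscapes G = −RT ln P over binned
  (centroid distance, interplanar angle) observations;
* **mechanics** — tensile modulus from the 0–0.2 % strain window,
  fracture stress and work of rupture; AFM nanoindentation via the
  Hertz model F = (4/3)·E/(1−ν²)·√R·δ^{3/2} with a fitted contact
  point and cantilever-deflection correction, plus point stiffness.

A first-class synthetic-data module generates ground-truth-labelled
helical-bundle crystals (azimuth φ₀ + 2πs/S + nΔθ, rise nΔz, radius r,
handedness = sign Δθ), mirrored enantiomers, jittered trajectories and
noisy mechanics curves, so every pipeline stage is testable without
external downloads.

## Worked example

```python
from helixrope import HelixSpec, gen_triple_helix, triple_helix_metrics

spec = HelixSpec(n_strands=3, delta_theta=-20.0, delta_z=3.0,
                 radius=7.8, n_layers=8, jitter=0.05, seed=7)
structure, truth = gen_triple_helix(spec)
m = triple_helix_metrics(structure, fit_atom="N")
print(m["twist"].verdict, m["twist"].slope, m["pitch_A"], m["radius_A"])
```

prints

```
S -20.08 53.97 7.80
```

a left-handed (S) twist call from the rotation slope of −20.08°/layer
(negative = clockwise), with the fitted pitch 53.97 Å and radius
7.80 Å recovering the generator's ground truth (pitch 360/20×3 = 54 Å,
radius 7.8 Å) to a fraction of a percent despite 0.05 Å placement
noise. The `examples/` directory has one short narrative script per
capability (twist calls, interaction maps and FELs, supercell analysis
of structure files, mechanics curves, trajectory windows); each prints
the numbers it computes and what they mean. A thin command-line
interface (`helixrope --help`) exposes the same pipelines for shell
use, including `helixrope selftest`.

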