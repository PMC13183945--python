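# Default chemical-group table and aromatic-ring definitions for
# cyclo-Trp-Pro (diketopiperazine) crystals.
#
# Rules are applied in order; the first match wins, which makes the
# indole labels (W_NH, W_aro) take precedence over the generic Trp side
# chain (W_sc).  Atom-name patterns are fnmatch globs.
group_rules:
  - {residue: "HOH|SOL|WAT", atoms: "*", label: water}
  - {residue: "TRP", atoms: "NE1|HE1", label: W_NH}
  - {residue: "TRP", atoms: "CG|CD1|CD2|CE2|CE3|CZ2|CZ3|CH2|HD1|HE3|HZ2|HZ3|HH2", label: W_aro}
  - {residue: "TRP", atoms: "CB|HB*", label: W_sc}
  - {residue: "TRP", atoms: "N|CA|C|O|H|HN|HA", label: W_mc}
  - {residue: "PRO", atoms: "N|CA|C|O|HA", label: P_mc}
  - {residue: "PRO", atoms: "CB|CG|CD|HB*|HG*|HD*", label: P_sc}

ring_definitions:
  - {residue: "TRP", kind: indole5, atoms: [CG, CD1, NE1, CE2, CD2]}
  - {residue: "TRP", kind: indole6, atoms: [CD2, CE2, CZ2, CH2, CZ3, CE3]}

# one 9-atom centroid instead of the two fused rings
fused_ring_definitions:
  - {residue: "TRP", kind: generic, atoms: [CG, CD1, NE1, CE2, CD2, CZ2, CH2, CZ3, CE3]}
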