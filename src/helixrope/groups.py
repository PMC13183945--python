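"""Chemical-group assignment and aromatic-ring location.

Each molecule's atoms are partitioned into the six functional groups of
a cyclo-Trp-Pro molecule — Trp aromatic (W_aro), indole NH (W_NH), Trp
side chain (W_sc), Trp main chain (W_mc), Pro main chain (P_mc), Pro
side chain (P_sc) — plus water and a catch-all "other".  The concrete
atom-name mapping ships as a YAML config so other naming schemes can be
plugged in.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .structures import CrystalStructure

logger = logging.getLogger("helixrope")

GROUP_LABELS = ("W_aro", "W_NH", "W_sc", "W_mc", "P_mc", "P_sc", "water", "other")

__all__ = ["GROUP_LABELS", "GroupTable", "AromaticRing",
           "assign_groups", "find_rings", "default_group_table"]


def _match(pattern: str, value: str) -> bool:
    return any(fnmatch.fnmatchcase(value.upper(), alt.upper())
               for alt in pattern.split("|"))


@dataclass
class GroupTable:
    """Ordered (residue pattern, atom-name pattern) → label rules.

    Rules are applied first-match-wins, so earlier rules take precedence;
    this is how the overlap between W_aro/W_NH and the chemically wider
    W_sc is resolved into exclusive labels.
    """

    rules: list[tuple[str, str, str]]
    ring_definitions: list[dict]
    fused_ring_definitions: list[dict]

    @classmethod
    def from_yaml(cls, path) -> "GroupTable":
        data = yaml.safe_load(Path(path).read_text())
        return cls._from_dict(data)

    @classmethod
    def _from_dict(cls, data: dict) -> "GroupTable":
        rules = []
        for rule in data.get("group_rules", []):
            label = rule["label"]
            if label not in GROUP_LABELS:
                raise ValueError(f"unknown group label {label!r}")
            rules.append((rule["residue"], rule["atoms"], label))
        return cls(rules, data.get("ring_definitions", []),
                   data.get("fused_ring_definitions", []))

    def label_of(self, residue: str, atom_name: str) -> str:
        for res_pat, atom_pat, label in self.rules:
            if _match(res_pat, residue) and _match(atom_pat, atom_name):
                return label
        return "other"

    def labels_of(self, residue: str, atom_name: str) -> list[str]:
        """All matching labels (overlapping mode, e.g. W_aro ⊂ W_sc)."""
        out = [label for res_pat, atom_pat, label in self.rules
               if _match(res_pat, residue) and _match(atom_pat, atom_name)]
        return out or ["other"]


def default_group_table() -> GroupTable:
    with resources.files("helixrope.data").joinpath("groups.yaml").open() as fh:
        return GroupTable._from_dict(yaml.safe_load(fh))


def assign_groups(structure: CrystalStructure, table: GroupTable | None = None
                  ) -> dict[int, str]:
    """Map every atom_id to its exclusive group label.

    The result is a partition: every atom gets exactly one label, and
    atoms matched by no rule are labelled ``other`` with a warning.
    """
    table = table or default_group_table()
    out: dict[int, str] = {}
    n_other = 0
    for atom in structure.atoms:
        label = table.label_of(atom.residue, atom.name)
        if label == "other":
            n_other += 1
        out[atom.atom_id] = label
    if n_other:
        logger.warning("%d atoms matched no group rule; labelled 'other'", n_other)
    return out


@dataclass
class AromaticRing:
    member_atom_ids: list[int]
    centroid: np.ndarray
    normal: np.ndarray
    molecule_id: int
    ring_kind: str
    planarity_rms: float


def find_rings(structure: CrystalStructure, table: GroupTable | None = None,
               fused: bool = False, planarity_tol: float = 0.15
               ) -> list[AromaticRing]:
    """Locate aromatic rings from the per-residue member-atom definitions.

    The centroid is the unweighted mean of member positions and the
    normal is the smallest-variance principal axis of the members, with
    its sign chosen toward the +c hemisphere.  Molecules missing a
    member atom skip that ring with a warning; non-planar rings beyond
    ``planarity_tol`` Å RMS are kept with a warning.
    """
    table = table or default_group_table()
    defs = table.fused_ring_definitions if fused else table.ring_definitions
    rings: list[AromaticRing] = []
    for mol_id, atoms in structure.molecules().items():
        by_name: dict[tuple[str, str], list] = {}
        for a in atoms:
            by_name.setdefault((a.residue.upper(), a.name.upper()), []).append(a)
        for ring_def in defs:
            res_pat = ring_def["residue"]
            members = []
            ok = True
            for name in ring_def["atoms"]:
                cands = [a for (res, nm), lst in by_name.items()
                         if _match(res_pat, res) and nm == name.upper()
                         for a in lst]
                if not cands:
                    ok = False
                    break
                members.append(cands[0])
            if not ok:
                if any(_match(res_pat, a.residue) for a in atoms):
                    logger.warning("molecule %d: ring %s missing member; skipped",
                                   mol_id, ring_def.get("kind"))
                continue
            pos = np.array([a.position for a in members])
            centroid = pos.mean(axis=0)
            centered = pos - centroid
            _, s, vt = np.linalg.svd(centered, full_matrices=False)
            normal = vt[-1]
            if normal[2] < 0 or (normal[2] == 0 and normal[0] < 0):
                normal = -normal
            rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
            if rms > planarity_tol:
                logger.warning("molecule %d: ring %s non-planar (%.3f Å RMS)",
                               mol_id, ring_def.get("kind"), rms)
            rings.append(AromaticRing([a.atom_id for a in members], centroid,
                                      normal, mol_id, ring_def.get("kind", "generic"),
                                      rms))
    return rings
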