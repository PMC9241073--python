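"""Common-core / softcore atom partitions for single-residue mutations.

An alchemical residue mutation needs a mapping between the two end-state
topologies: atoms paired between source and target transform linearly,
while atoms unique to either side appear or vanish through softcore
potentials.  Two schemes are provided:

* ``default`` — only the backbone is paired; every side-chain atom is
  unique.  Robust, but the reconstructed side chain may fail to recover
  specific interactions (a hydroxyl coordinating a catalytic Mg²⁺, an
  aromatic ring stacking on a nucleotide).
* ``mcs`` — a maximal common connected substructure anchored at the
  backbone, grown outward from CA with element matching.  For THR→SER
  this keeps the −CβHOH group common (only the Thr methyl and one Ser
  β-hydrogen are softcore); for PHE↔TYR the whole ring is common and
  only −OH vs −H differ.  Minimizing unique atoms preserves key
  interactions through the transformation.

Residue topologies use AMBER-style atom naming (HB2/HB3 β-hydrogens,
HE2 on the ε-protonated neutral histidine, etc.).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "ResidueTemplate",
    "AtomMapping",
    "load_template",
    "default_mapping",
    "mcs_mapping",
    "validate_mapping",
]

# side-chain atoms and bonds per residue; backbone added programmatically.
# Atom elements follow from the leading letter of the AMBER atom name.
_SIDECHAINS: dict[str, tuple[list[str], list[tuple[str, str]]]] = {
    "ALA": (
        ["CB", "HB1", "HB2", "HB3"],
        [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")],
    ),
    "ARG": (
        ["CB", "HB2", "HB3", "CG", "HG2", "HG3", "CD", "HD2", "HD3",
         "NE", "HE", "CZ", "NH1", "HH11", "HH12", "NH2", "HH21", "HH22"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "HD2"),
         ("CD", "HD3"), ("CD", "NE"), ("NE", "HE"), ("NE", "CZ"),
         ("CZ", "NH1"), ("NH1", "HH11"), ("NH1", "HH12"),
         ("CZ", "NH2"), ("NH2", "HH21"), ("NH2", "HH22")],
    ),
    "ASN": (
        ["CB", "HB2", "HB3", "CG", "OD1", "ND2", "HD21", "HD22"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "OD1"), ("CG", "ND2"), ("ND2", "HD21"), ("ND2", "HD22")],
    ),
    "ASP": (
        ["CB", "HB2", "HB3", "CG", "OD1", "OD2"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "OD1"), ("CG", "OD2")],
    ),
    "CYS": (
        ["CB", "HB2", "HB3", "SG", "HG"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "SG"), ("SG", "HG")],
    ),
    "GLN": (
        ["CB", "HB2", "HB3", "CG", "HG2", "HG3", "CD", "OE1", "NE2",
         "HE21", "HE22"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "OE1"),
         ("CD", "NE2"), ("NE2", "HE21"), ("NE2", "HE22")],
    ),
    "GLU": (
        ["CB", "HB2", "HB3", "CG", "HG2", "HG3", "CD", "OE1", "OE2"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "OE1"),
         ("CD", "OE2")],
    ),
    "GLY": ([], []),
    # neutral ε-protonated histidine (no charged His occurs at this interface)
    "HIS": (
        ["CB", "HB2", "HB3", "CG", "ND1", "CE1", "HE1", "NE2", "HE2",
         "CD2", "HD2"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "HE1"), ("CE1", "NE2"),
         ("NE2", "HE2"), ("NE2", "CD2"), ("CD2", "HD2"), ("CD2", "CG")],
    ),
    "ILE": (
        ["CB", "HB", "CG2", "HG21", "HG22", "HG23", "CG1", "HG12",
         "HG13", "CD1", "HD11", "HD12", "HD13"],
        [("CA", "CB"), ("CB", "HB"), ("CB", "CG2"), ("CG2", "HG21"),
         ("CG2", "HG22"), ("CG2", "HG23"), ("CB", "CG1"), ("CG1", "HG12"),
         ("CG1", "HG13"), ("CG1", "CD1"), ("CD1", "HD11"), ("CD1", "HD12"),
         ("CD1", "HD13")],
    ),
    "LEU": (
        ["CB", "HB2", "HB3", "CG", "HG", "CD1", "HD11", "HD12", "HD13",
         "CD2", "HD21", "HD22", "HD23"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "HG"), ("CG", "CD1"), ("CD1", "HD11"), ("CD1", "HD12"),
         ("CD1", "HD13"), ("CG", "CD2"), ("CD2", "HD21"), ("CD2", "HD22"),
         ("CD2", "HD23")],
    ),
    "LYS": (
        ["CB", "HB2", "HB3", "CG", "HG2", "HG3", "CD", "HD2", "HD3",
         "CE", "HE2", "HE3", "NZ", "HZ1", "HZ2", "HZ3"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "HD2"),
         ("CD", "HD3"), ("CD", "CE"), ("CE", "HE2"), ("CE", "HE3"),
         ("CE", "NZ"), ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
    ),
    "MET": (
        ["CB", "HB2", "HB3", "CG", "HG2", "HG3", "SD", "CE", "HE1",
         "HE2", "HE3"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "HG2"), ("CG", "HG3"), ("CG", "SD"), ("SD", "CE"),
         ("CE", "HE1"), ("CE", "HE2"), ("CE", "HE3")],
    ),
    "PHE": (
        ["CB", "HB2", "HB3", "CG", "CD1", "HD1", "CE1", "HE1", "CZ",
         "HZ", "CE2", "HE2", "CD2", "HD2"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "CD1"), ("CD1", "HD1"), ("CD1", "CE1"), ("CE1", "HE1"),
         ("CE1", "CZ"), ("CZ", "HZ"), ("CZ", "CE2"), ("CE2", "HE2"),
         ("CE2", "CD2"), ("CD2", "HD2"), ("CD2", "CG")],
    ),
    "PRO": (
        ["CB", "HB2", "HB3", "CG", "HG2", "HG3", "CD", "HD2", "HD3"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "HG2"), ("CG", "HG3"), ("CG", "CD"), ("CD", "HD2"),
         ("CD", "HD3"), ("CD", "N")],
    ),
    "SER": (
        ["CB", "HB2", "HB3", "OG", "HG"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "OG"), ("OG", "HG")],
    ),
    "THR": (
        ["CB", "HB", "CG2", "HG21", "HG22", "HG23", "OG1", "HG1"],
        [("CA", "CB"), ("CB", "HB"), ("CB", "CG2"), ("CG2", "HG21"),
         ("CG2", "HG22"), ("CG2", "HG23"), ("CB", "OG1"), ("OG1", "HG1")],
    ),
    "TRP": (
        ["CB", "HB2", "HB3", "CG", "CD1", "HD1", "NE1", "HE1", "CE2",
         "CZ2", "HZ2", "CH2", "HH2", "CZ3", "HZ3", "CE3", "HE3", "CD2"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "CD1"), ("CD1", "HD1"), ("CD1", "NE1"), ("NE1", "HE1"),
         ("NE1", "CE2"), ("CE2", "CZ2"), ("CZ2", "HZ2"), ("CZ2", "CH2"),
         ("CH2", "HH2"), ("CH2", "CZ3"), ("CZ3", "HZ3"), ("CZ3", "CE3"),
         ("CE3", "HE3"), ("CE3", "CD2"), ("CD2", "CE2"), ("CD2", "CG")],
    ),
    "TYR": (
        ["CB", "HB2", "HB3", "CG", "CD1", "HD1", "CE1", "HE1", "CZ",
         "OH", "HH", "CE2", "HE2", "CD2", "HD2"],
        [("CA", "CB"), ("CB", "HB2"), ("CB", "HB3"), ("CB", "CG"),
         ("CG", "CD1"), ("CD1", "HD1"), ("CD1", "CE1"), ("CE1", "HE1"),
         ("CE1", "CZ"), ("CZ", "OH"), ("OH", "HH"), ("CZ", "CE2"),
         ("CE2", "HE2"), ("CE2", "CD2"), ("CD2", "HD2"), ("CD2", "CG")],
    ),
    "VAL": (
        ["CB", "HB", "CG1", "HG11", "HG12", "HG13", "CG2", "HG21",
         "HG22", "HG23"],
        [("CA", "CB"), ("CB", "HB"), ("CB", "CG1"), ("CG1", "HG11"),
         ("CG1", "HG12"), ("CG1", "HG13"), ("CB", "CG2"), ("CG2", "HG21"),
         ("CG2", "HG22"), ("CG2", "HG23")],
    ),
}


def _element(name: str) -> str:
    """Element from the leading letter of a standard amino-acid atom name."""
    return name[0]


@dataclass(frozen=True)
class ResidueTemplate:
    """Atom/bond topology of one standard residue, AMBER naming."""

    code: str
    atoms: tuple
    bonds: frozenset

    def neighbors(self, name: str) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return sorted(out)

    @property
    def atom_names(self) -> tuple:
        return tuple(a for a, _ in self.atoms)

    @property
    def elements(self) -> dict:
        return dict(self.atoms)


@dataclass(frozen=True)
class AtomMapping:
    """Partition of two templates into paired core and unique atoms."""

    source: str
    target: str
    pairs: tuple
    unique_source: frozenset
    unique_target: frozenset
    scheme: str


def load_template(code: str) -> ResidueTemplate:
    """Topology of a standard residue (backbone + side chain)."""
    key = code.upper()
    if key not in _SIDECHAINS:
        raise KeyError(f"unknown residue code {code!r}")
    side_atoms, side_bonds = _SIDECHAINS[key]
    names = ["N", "CA", "C", "O"]
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    if key != "PRO":  # proline's ring nitrogen carries no amide H
        names.insert(1, "H")
        bonds.append(("N", "H"))
    if key == "GLY":
        names += ["HA2", "HA3"]
        bonds += [("CA", "HA2"), ("CA", "HA3")]
    else:
        names.append("HA")
        bonds.append(("CA", "HA"))
    names += side_atoms
    bonds += side_bonds
    atoms = tuple((n, _element(n)) for n in names)
    bondset = frozenset(frozenset(b) for b in bonds)
    g = nx.Graph(tuple(b) for b in bondset)
    g.add_nodes_from(names)
    if not nx.is_connected(g):
        raise AssertionError(f"template {key} graph is not connected")
    return ResidueTemplate(
        code=key, atoms=atoms, bonds=frozenset(tuple(sorted(b)) for b in bondset)
    )


def _bonded(template: ResidueTemplate, a: str, b: str) -> bool:
    return tuple(sorted((a, b))) in template.bonds


def _backbone_pairs(src: ResidueTemplate, tgt: ResidueTemplate):
    """Pair backbone atoms by role; return (pairs, leftovers per side)."""
    pairs = []
    left_s, left_t = [], []
    for role in ("N", "CA", "C", "O", "H"):
        has_s, has_t = role in src.atom_names, role in tgt.atom_names
        if has_s and has_t:
            pairs.append((role, role))
        elif has_s:
            left_s.append(role)
        elif has_t:
            left_t.append(role)
    ha_s = [n for n in ("HA", "HA2", "HA3") if n in src.atom_names]
    ha_t = [n for n in ("HA", "HA2", "HA3") if n in tgt.atom_names]
    for a, b in zip(ha_s, ha_t):
        pairs.append((a, b))
    left_s += ha_s[len(ha_t):]
    left_t += ha_t[len(ha_s):]
    return pairs, left_s, left_t


def default_mapping(src: ResidueTemplate, tgt: ResidueTemplate) -> AtomMapping:
    """Backbone-only pairing; the whole side chain is softcore on each side."""
    pairs, left_s, left_t = _backbone_pairs(src, tgt)
    paired_s = {a for a, _ in pairs}
    paired_t = {b for _, b in pairs}
    return AtomMapping(
        source=src.code,
        target=tgt.code,
        pairs=tuple(pairs),
        unique_source=frozenset(set(src.atom_names) - paired_s),
        unique_target=frozenset(set(tgt.atom_names) - paired_t),
        scheme="default",
    )


def mcs_mapping(src: ResidueTemplate, tgt: ResidueTemplate) -> AtomMapping:
    """Maximal common connected substructure anchored at the backbone.

    Growth proceeds breadth-first outward from the paired backbone.
    A source/target candidate pair is accepted when the elements match
    and every already-paired neighbor of one maps to a bonded neighbor
    of the other (bond preservation).  Ties are broken deterministically
    — heavy atoms before hydrogens, then lexicographic atom name — which
    resolves symmetric ring branches (CD1/CD2) consistently on the two
    sides.
    """
    pairs, _, _ = _backbone_pairs(src, tgt)
    fwd = dict(pairs)
    rev = {b: a for a, b in pairs}
    queue = deque(pairs)

    def sort_key(name):
        return (_element(name) == "H", name)

    def consistent(cs: str, ct: str) -> bool:
        for n in src.neighbors(cs):
            if n in fwd and not _bonded(tgt, fwd[n], ct):
                return False
        for n in tgt.neighbors(ct):
            if n in rev and not _bonded(src, rev[n], cs):
                return False
        return True

    while queue:
        a_s, a_t = queue.popleft()
        cand_s = sorted((n for n in src.neighbors(a_s) if n not in fwd), key=sort_key)
        cand_t = sorted((n for n in tgt.neighbors(a_t) if n not in rev), key=sort_key)
        for cs in cand_s:
            for ct in cand_t:
                if (
                    ct not in rev
                    and _element(cs) == _element(ct)
                    and consistent(cs, ct)
                ):
                    fwd[cs] = ct
                    rev[ct] = cs
                    queue.append((cs, ct))
                    break

    ordered = [p for p in pairs]
    ordered += sorted(
        ((a, b) for a, b in fwd.items() if (a, b) not in set(pairs)),
        key=lambda p: sort_key(p[0]),
    )
    return AtomMapping(
        source=src.code,
        target=tgt.code,
        pairs=tuple(ordered),
        unique_source=frozenset(set(src.atom_names) - set(fwd)),
        unique_target=frozenset(set(tgt.atom_names) - set(rev)),
        scheme="mcs",
    )


def validate_mapping(
    mapping: AtomMapping, src: ResidueTemplate, tgt: ResidueTemplate
) -> list[str]:
    """Check partition exactness, element matches and bond isomorphism.

    Returns a list of human-readable violations; empty means valid.
    """
    violations = []
    paired_s = [a for a, _ in mapping.pairs]
    paired_t = [b for _, b in mapping.pairs]
    if len(set(paired_s)) != len(paired_s) or len(set(paired_t)) != len(paired_t):
        violations.append("an atom appears in more than one pair")
    for side, names, paired, unique in (
        ("source", set(src.atom_names), set(paired_s), mapping.unique_source),
        ("target", set(tgt.atom_names), set(paired_t), mapping.unique_target),
    ):
        overlap = paired & unique
        if overlap:
            violations.append(f"{side} atoms both paired and unique: {sorted(overlap)}")
        missing = names - paired - unique
        if missing:
            violations.append(f"{side} atoms unassigned: {sorted(missing)}")
        extra = (paired | unique) - names
        if extra:
            violations.append(f"{side} names not in template: {sorted(extra)}")
    for a, b in mapping.pairs:
        if a in src.elements and b in tgt.elements:
            if src.elements[a] != tgt.elements[b]:
                violations.append(
                    f"element mismatch in pair {a}({src.elements[a]}) ↔ "
                    f"{b}({tgt.elements[b]})"
                )
    fwd = dict(mapping.pairs)
    for (a, b) in mapping.pairs:
        for (c, d) in mapping.pairs:
            if a < c:
                if _bonded(src, a, c) != _bonded(tgt, b, d):
                    violations.append(
                        f"bond mismatch: {a}-{c} ({'bonded' if _bonded(src, a, c) else 'unbonded'} "
                        f"in source) vs {b}-{d} in target"
                    )
    # the paired subgraph must stay connected (one common core)
    core = nx.Graph()
    core.add_nodes_from(paired_s)
    for a, c in ((a, c) for a in paired_s for c in paired_s if a < c):
        if _bonded(src, a, c):
            core.add_edge(a, c)
    if core.number_of_nodes() and not nx.is_connected(core):
        violations.append("paired common core is not a connected subgraph")
    return violations
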