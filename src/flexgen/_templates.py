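"""Static chemistry tables for the 20 standard amino acids.

Heavy-atom connectivity, ring membership, hydrogen-bond donor/acceptor roles,
charged-group membership and van der Waals radii.  All tables are keyed by
PDB residue and atom names; hydrogens never appear (the pipeline strips them).
"""

from __future__ import annotations

# Heavy-atom side-chain bonds per residue.  Backbone bonds (N-CA, CA-C, C-O,
# C-OXT) are shared and added programmatically.
SIDE_CHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (("CA", "CB"),),
    "ARG": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")),
    "GLY": (),
    "HIS": (("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CZ2", "CH2"), ("CH2", "CZ3"), ("CZ3", "CE3")),
    "TYR": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
}

# Atoms belonging to a residue's ring system.  Fused rings (Trp) are treated
# as one set: every intra-set pair is geometrically rigid.
RING_ATOMS: dict[str, frozenset[str]] = {
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3",
                      "CZ2", "CZ3", "CH2"}),
    "PRO": frozenset({"N", "CA", "CB", "CG", "CD"}),
}

# Side-chain bonds with partial double-bond character whose 1-4 dihedrals are
# planar-restricted (amide / guanidinium groups).
DOUBLE_BOND_CENTRAL: dict[str, frozenset[tuple[str, str]]] = {
    "ASN": frozenset({("CG", "ND2")}),
    "GLN": frozenset({("CD", "NE2")}),
    "ARG": frozenset({("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")}),
}

# Hydrogen-bond capable heavy atoms (hydrogens are stripped upstream, so the
# criterion operates on donor/acceptor heavy atoms).
HB_DONORS: dict[str, frozenset[str]] = {
    "*": frozenset({"N"}),  # backbone amide of every residue except Pro
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
}

HB_ACCEPTORS: dict[str, frozenset[str]] = {
    "*": frozenset({"O", "OXT"}),
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}

# Charged groups for salt-bridge detection.
POSITIVE_GROUP: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}
NEGATIVE_GROUP: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "*": frozenset({"OXT"}),  # C-terminal carboxylate
}

VDW_RADII: dict[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}

STANDARD_RESIDUES = frozenset(SIDE_CHAIN_BONDS)

# Canonical within-residue atom order (PDB convention: backbone then side
# chain outward).  Atoms absent from this list sort after it, alphabetically.
_BACKBONE_ORDER = ("N", "CA", "C", "O")
_SIDECHAIN_ORDER: dict[str, tuple[str, ...]] = {
    res: tuple(dict.fromkeys(a for bond in bonds for a in bond
                             if a not in _BACKBONE_ORDER))
    for res, bonds in SIDE_CHAIN_BONDS.items()
}


def atom_sort_rank(residue_name: str, atom_name: str) -> tuple[int, str]:
    """Sort key for atoms within one residue (backbone, side chain, OXT)."""
    if atom_name in _BACKBONE_ORDER:
        return (_BACKBONE_ORDER.index(atom_name), "")
    order = _SIDECHAIN_ORDER.get(residue_name, ())
    if atom_name in order:
        return (4 + order.index(atom_name), "")
    if atom_name == "OXT":
        return (100, "")
    return (50, atom_name)


def donor_atoms(residue_name: str) -> frozenset[str]:
    base = HB_DONORS["*"] if residue_name != "PRO" else frozenset()
    return base | HB_DONORS.get(residue_name, frozenset())


def acceptor_atoms(residue_name: str) -> frozenset[str]:
    return HB_ACCEPTORS["*"] | HB_ACCEPTORS.get(residue_name, frozenset())
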