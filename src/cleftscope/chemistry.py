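"""Residue classification sets and per-atom chemistry dictionaries.

Interaction detection on heavy-atom crystal structures needs to know, per
residue type, which atoms can donate or accept hydrogen bonds, which carry
formal charge, which carbons count as apolar, and which atoms form aromatic
rings.  The tables below cover the 20 standard amino acids plus water; they
are deliberately explicit so that users can extend or override them for
modified residues and ligands.

All dictionaries map a 3-letter residue code to atom-level information.
Donor entries map donor atom name -> antecedent (bonded heavy atom) name;
the antecedent is what lets us evaluate a donor-centred angle when no
hydrogens are present in the model.
"""

from __future__ import annotations

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA1 = set(AA1_TO_3)

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
METAL_ELEMENTS = {"ZN", "MG", "CA", "MN", "FE", "NI", "CU", "CO", "NA", "K", "CD"}

# ---------------------------------------------------------------------------
# Residue category sets (1-letter codes).  The charged set follows the
# convention used in thermostability comparisons of this enzyme family
# (Glu, Arg, Lys); the polar/hydrophobic split is one common convention and
# is overridable wherever it is consumed.
# ---------------------------------------------------------------------------
DEFAULT_RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "proline": frozenset("P"),
    "charged": frozenset("ERK"),
    "polar": frozenset("STNQYCH"),
    "hydrophobic": frozenset("AVLIMFWP"),
}

# ---------------------------------------------------------------------------
# Hydrogen-bond donors: donor atom -> antecedent atom.  Backbone N donates
# for every residue except proline.
# ---------------------------------------------------------------------------
BACKBONE_DONOR = {"N": "CA"}

SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CE1"},
    "LYS": {"NZ": "CE"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TRP": {"NE1": "CD1"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
}

# Weak (C-H...A) donors: alpha carbon for every residue; antecedent is N.
WEAK_DONORS: dict[str, str] = {"CA": "N"}

# Hydrogen-bond acceptors (heavy atoms).  Backbone carbonyl O for all.
BACKBONE_ACCEPTORS = {"O", "OXT"}

SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}

# ---------------------------------------------------------------------------
# Formal charges on side-chain atoms (heavy atoms carrying the charge).
# Histidine is neutral by default; callers may pass charged_his=True.
# ---------------------------------------------------------------------------
NEGATIVE_ATOMS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
POSITIVE_ATOMS: dict[str, set[str]] = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
}
POSITIVE_ATOMS_HIS = {"HIS": {"ND1", "NE2"}}

# ---------------------------------------------------------------------------
# Apolar carbons (side chains of hydrophobic residues).
# ---------------------------------------------------------------------------
APOLAR_CARBONS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG", "CD"},
}

# ---------------------------------------------------------------------------
# Aromatic rings: residue -> list of ring atom-name tuples.
# ---------------------------------------------------------------------------
AROMATIC_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
}


def donors_for(res_name: str) -> dict[str, str]:
    """Donor atom -> antecedent map for one residue type (backbone + side chain)."""
    d = {} if res_name == "PRO" else dict(BACKBONE_DONOR)
    d.update(SIDECHAIN_DONORS.get(res_name, {}))
    return d


def acceptors_for(res_name: str) -> set[str]:
    """Acceptor atom names for one residue type."""
    if res_name in WATER_NAMES:
        return {"O", "OW"}
    return BACKBONE_ACCEPTORS | SIDECHAIN_ACCEPTORS.get(res_name, set())
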