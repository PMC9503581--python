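"""Amino-acid heavy-atom inventories and residue-code translation.

Only carbon and nitrogen atoms are tracked: the supported experiments are
carbon/nitrogen detected. The carbonyl carbon is named ``C`` (NMR-STAR
convention); ``CO`` is accepted as an input alias.
"""

from __future__ import annotations

AA1 = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Backbone N plus every carbon, per residue type (one-letter key).
HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N", "CA", "CB", "C"),
    "R": ("N", "CA", "CB", "CG", "CD", "CZ", "C"),
    "N": ("N", "CA", "CB", "CG", "C"),
    "D": ("N", "CA", "CB", "CG", "C"),
    "C": ("N", "CA", "CB", "C"),
    "E": ("N", "CA", "CB", "CG", "CD", "C"),
    "Q": ("N", "CA", "CB", "CG", "CD", "C"),
    "G": ("N", "CA", "C"),
    "H": ("N", "CA", "CB", "CG", "CD2", "CE1", "C"),
    "I": ("N", "CA", "CB", "CG1", "CG2", "CD1", "C"),
    "L": ("N", "CA", "CB", "CG", "CD1", "CD2", "C"),
    "K": ("N", "CA", "CB", "CG", "CD", "CE", "C"),
    "M": ("N", "CA", "CB", "CG", "CE", "C"),
    "F": ("N", "CA", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "C"),
    "P": ("N", "CA", "CB", "CG", "CD", "C"),
    "S": ("N", "CA", "CB", "C"),
    "T": ("N", "CA", "CB", "CG2", "C"),
    "W": ("N", "CA", "CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2", "C"),
    "Y": ("N", "CA", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "C"),
    "V": ("N", "CA", "CB", "CG1", "CG2", "C"),
}

BACKBONE_ATOMS = ("N", "CA", "CB", "C")

ATOM_ALIASES = {"CO": "C", "CO-1": "C"}


def canonical_atom(name: str) -> str:
    name = name.upper()
    return ATOM_ALIASES.get(name, name)


def carbons(res: str) -> tuple[str, ...]:
    """All carbon atoms of a residue type, including CA and the carbonyl C."""
    return tuple(a for a in HEAVY_ATOMS[res] if a != "N")


def cx_atoms(res: str) -> tuple[str, ...]:
    """Carbons at positions A, B, D, E, G and H: everything except the
    carbonyl and zeta-position carbons."""
    return tuple(
        a for a in HEAVY_ATOMS[res]
        if a.startswith("C") and a != "C" and not a.startswith("CZ")
    )


def sidechain_carbons(res: str) -> tuple[str, ...]:
    """Carbons beyond the backbone set (CB counts as backbone here)."""
    return tuple(a for a in carbons(res) if a not in ("CA", "CB", "C"))


def nucleus(atom: str) -> str:
    """'13C' or '15N' for a canonical atom name."""
    return "15N" if atom.startswith("N") else "13C"
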