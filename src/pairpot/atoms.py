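"""Residue-specific heavy-atom type alphabet.

Distance-dependent atom-pair potentials describe atoms residue-specifically:
the CA of lysine is a different type from the CA of leucine.  Enumerating the
canonical heavy atoms of the 20 standard amino acids yields 167 atom types and
hence 167^2 = 27,889 ordered atom-type pairs (the sequence has distinct N and C
termini, so (i, j) and (j, i) are distinct pairs).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

# Canonical heavy atoms per residue, in PDB record order: the backbone
# (N, CA, C, O) followed by the side chain in remoteness order.  OXT is a
# terminal artifact, not an atom type; hydrogens are never typed.
BACKBONE: Tuple[str, ...] = ("N", "CA", "C", "O")

SIDE_CHAINS: Dict[str, Tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

STANDARD_RESIDUES: Tuple[str, ...] = tuple(sorted(SIDE_CHAINS))

N_ATOM_TYPES = 167
N_ORDERED_PAIRS = N_ATOM_TYPES * N_ATOM_TYPES


def residue_heavy_atoms(residue_name: str) -> Tuple[str, ...]:
    """Canonical heavy atoms of one residue, backbone first."""
    return BACKBONE + SIDE_CHAINS[residue_name]


def build_atom_type_table() -> Dict[Tuple[str, str], int]:
    """Map each (residue_name, atom_name) pair to its type id in [0, 166].

    Deterministic: residues alphabetical by 3-letter code, atoms in canonical
    PDB order (N, CA, C, O, then side chain).  The mapping is a bijection onto
    range(167).
    """
    table: Dict[Tuple[str, str], int] = {}
    for res in STANDARD_RESIDUES:
        for atom in residue_heavy_atoms(res):
            table[(res, atom)] = len(table)
    if len(table) != N_ATOM_TYPES:  # pragma: no cover - structural guarantee
        raise AssertionError(f"atom type table has {len(table)} entries")
    return table


ATOM_TYPES: Dict[Tuple[str, str], int] = build_atom_type_table()

TYPE_NAMES: List[Tuple[str, str]] = sorted(ATOM_TYPES, key=ATOM_TYPES.get)


def atom_type_id(residue_name: str, atom_name: str) -> int:
    """Type id of one residue-specific atom; KeyError if not a canonical type."""
    return ATOM_TYPES[(residue_name, atom_name)]
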