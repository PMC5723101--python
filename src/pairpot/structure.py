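"""PDB ingestion into a canonical single-chain heavy-atom model.

The model is the unit every other module works on: an ordered list of typed
heavy atoms with 0-based residue indices over a sequence-continuous chain.
Residue intervals are computed from these positional indices, not author
numbering; chains with gaps in author numbering are rejected in strict mode
because the two numberings then disagree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.PDB import PDBParser

from .atoms import ATOM_TYPES, SIDE_CHAINS, residue_heavy_atoms

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AtomSite:
    """One typed heavy atom of a standard residue."""

    residue_index: int  # 0-based position in the continuous chain
    residue_name: str  # 3-letter code
    atom_name: str
    type_id: int  # index into the 167-type alphabet
    coords: np.ndarray  # (3,) float64, Angstrom

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coords", np.asarray(self.coords, dtype=np.float64).reshape(3)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, AtomSite):
            return NotImplemented
        return (
            self.residue_index == other.residue_index
            and self.residue_name == other.residue_name
            and self.atom_name == other.atom_name
            and self.type_id == other.type_id
            and np.array_equal(self.coords, other.coords)
        )

    def __hash__(self) -> int:
        return hash(
            (self.residue_index, self.residue_name, self.atom_name, self.type_id)
        )


@dataclass
class StructureModel:
    """Single protein chain as an ordered list of typed heavy atoms.

    Atoms are sorted by (residue_index, canonical atom order within the
    residue); residue indices are consecutive integers starting at 0.
    """

    chain_id: str
    atoms: List[AtomSite]
    sequence: List[str]
    source_path: str = ""
    is_native: bool = False
    _arrays: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _build_arrays(self) -> tuple:
        if self._arrays is None or self._arrays[0].shape[0] != len(self.atoms):
            coords = np.array([a.coords for a in self.atoms], dtype=np.float64)
            type_ids = np.array([a.type_id for a in self.atoms], dtype=np.intp)
            res_idx = np.array([a.residue_index for a in self.atoms], dtype=np.intp)
            self._arrays = (coords, type_ids, res_idx)
        return self._arrays

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in atom order."""
        return self._build_arrays()[0]

    @property
    def type_ids(self) -> np.ndarray:
        return self._build_arrays()[1]

    @property
    def residue_indices(self) -> np.ndarray:
        return self._build_arrays()[2]

    def ca_coords(self) -> np.ndarray:
        """(L, 3) CA coordinates ordered by residue index."""
        ca = {a.residue_index: a.coords for a in self.atoms if a.atom_name == "CA"}
        if len(ca) != len(self.sequence):
            missing = sorted(set(range(len(self.sequence))) - set(ca))
            raise ValueError(f"missing CA atoms at residue indices {missing}")
        return np.array([ca[i] for i in range(len(self.sequence))])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy of the model with coordinates rigidly moved (x -> R x + t)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        atoms = [
            replace(a, coords=rotation @ a.coords + translation) for a in self.atoms
        ]
        return StructureModel(
            chain_id=self.chain_id,
            atoms=atoms,
            sequence=list(self.sequence),
            source_path=self.source_path,
            is_native=self.is_native,
        )

    def validate(self) -> None:
        """Raise ValueError if the model breaks its invariants."""
        if sorted(set(a.residue_index for a in self.atoms)) != list(
            range(len(self.sequence))
        ):
            raise ValueError("residue indices are not consecutive from 0")
        order = []
        for a in self.atoms:
            res = self.sequence[a.residue_index]
            if a.residue_name != res:
                raise ValueError(
                    f"atom residue {a.residue_name} != sequence {res} "
                    f"at index {a.residue_index}"
                )
            canon = residue_heavy_atoms(res)
            if a.atom_name not in canon:
                raise ValueError(f"{a.atom_name} not canonical for {res}")
            if a.type_id != ATOM_TYPES[(res, a.atom_name)]:
                raise ValueError("type_id inconsistent with atom type table")
            order.append((a.residue_index, canon.index(a.atom_name)))
        if order != sorted(order):
            raise ValueError("atoms not in (residue, canonical) order")


def _select_altloc(bio_atom):
    """Resolve a possibly disordered atom: highest occupancy, tie -> altloc 'A'."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = list(bio_atom.child_dict.values())
    return max(children, key=lambda a: (a.get_occupancy() or 0.0, a.get_altloc() == "A"))


def read_structure(
    path, chain: Optional[str] = None, strict: bool = True, is_native: bool = False
) -> StructureModel:
    """Read one chain of a PDB file into a typed heavy-atom model.

    Hydrogens, OXT, waters, ligands and nonstandard residues are skipped (with
    a logged warning for unexpected atom names).  Alternate locations keep the
    highest-occupancy conformer (ties prefer altloc 'A').  Only the first MODEL
    of multi-model files is read.

    Parameters
    ----------
    chain : str, optional
        Chain id to extract; default is the first chain containing standard
        residues.
    strict : bool
        If True, raise on chains whose author residue numbering is not
        consecutive (insertion codes or numbering gaps).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    try:
        model0 = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no models in file")

    chains = {c.id: c for c in model0}
    if chain is None:
        for cid, c in chains.items():
            if any(r.id[0] == " " and r.get_resname() in SIDE_CHAINS for r in c):
                chain = cid
                break
        if chain is None:
            raise ValueError(f"{path}: no chain with standard residues")
    if chain not in chains:
        raise ValueError(f"{path}: chain {chain!r} not found")

    residues = [
        r
        for r in chains[chain]
        if r.id[0] == " " and r.get_resname() in SIDE_CHAINS
    ]
    if not residues:
        raise ValueError(f"{path}: chain {chain!r} has no standard residues")

    numbering = [(r.id[1], r.id[2]) for r in residues]
    continuous = all(icode == " " for _, icode in numbering) and all(
        numbering[k + 1][0] == numbering[k][0] + 1 for k in range(len(numbering) - 1)
    )
    if strict and not continuous:
        raise ValueError(f"{path}: chain {chain!r} is sequence-discontinuous")

    atoms: List[AtomSite] = []
    sequence: List[str] = []
    for idx, res in enumerate(residues):
        res_name = res.get_resname()
        sequence.append(res_name)
        present = {}
        for bio_atom in res:
            a = _select_altloc(bio_atom)
            name = a.get_name()
            if (res_name, name) in ATOM_TYPES:
                present[name] = a
            elif name != "OXT" and a.element != "H" and not name.startswith("H"):
                logger.warning("%s: skipping atom %s in %s %s", path, name, res_name, idx)
        # canonical order within the residue
        for name in residue_heavy_atoms(res_name):
            if name in present:
                atoms.append(
                    AtomSite(
                        residue_index=idx,
                        residue_name=res_name,
                        atom_name=name,
                        type_id=ATOM_TYPES[(res_name, name)],
                        # PDB stores 3 decimals; rounding recovers the exact
                        # written value from Biopython's float32 coordinates
                        coords=np.round(present[name].get_coord().astype(np.float64), 3),
                    )
                )

    return StructureModel(
        chain_id=chain,
        atoms=atoms,
        sequence=sequence,
        source_path=str(path),
        is_native=is_native,
    )


def trim_to_native(model: StructureModel, native: StructureModel) -> StructureModel:
    """Cut a predicted model down to the native's sequence span.

    The native sequence must occur as a contiguous subsequence of the model's
    sequence (predictions shorter than the experimental structure are
    rejected).  Residues outside the matched span are dropped and indices are
    renumbered from 0.
    """
    if model.sequence == native.sequence:
        return model
    m, n = model.sequence, native.sequence
    if len(m) < len(n):
        raise ValueError(
            f"model ({len(m)} residues) shorter than native ({len(n)}); decoy rejected"
        )
    start = next(
        (k for k in range(len(m) - len(n) + 1) if m[k : k + len(n)] == n), None
    )
    if start is None:
        raise ValueError("native sequence not a contiguous subsequence of model")
    atoms = [
        replace(a, residue_index=a.residue_index - start)
        for a in model.atoms
        if start <= a.residue_index < start + len(n)
    ]
    return StructureModel(
        chain_id=model.chain_id,
        atoms=atoms,
        sequence=list(n),
        source_path=model.source_path,
        is_native=model.is_native,
    )


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:<4s}{altloc:1s}{res:<3s} {chain:1s}"
    "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_structure(model: StructureModel, path) -> None:
    """Write a model as minimal legal PDB ATOM records (v3.3 columns)."""
    with open(path, "w") as fh:
        for serial, a in enumerate(model.atoms, start=1):
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name}"
            fh.write(
                _PDB_ATOM.format(
                    serial=serial,
                    name=name,
                    altloc=" ",
                    res=a.residue_name,
                    chain=model.chain_id or "A",
                    resseq=a.residue_index + 1,
                    icode=" ",
                    x=a.coords[0],
                    y=a.coords[1],
                    z=a.coords[2],
                    occ=1.0,
                    b=0.0,
                    element=a.atom_name[0],
                )
            )
        fh.write("TER\nEND\n")


def read_structures(paths: Iterable, **kwargs) -> List[StructureModel]:
    """Read several PDB files, skipping unparseable ones with a warning."""
    models = []
    for p in paths:
        try:
            models.append(read_structure(p, **kwargs))
        except ValueError as exc:
            logger.warning("skipping %s: %s", p, exc)
    return models
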