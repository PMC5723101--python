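"""Distance binning and ordered atom-pair counting.

The binning scheme follows the convention of distance-dependent atom-pair
potentials: a first bin [0, 3.0) Angstrom, then 0.5-Angstrom bins up to the
cutoff; pairs at or beyond the cutoff are ignored.  Counting is restricted by
a residue interval s: only pairs whose residues are at least s apart in
sequence qualify (s = 0 admits intra-residue pairs).

Each unordered geometric pair increments exactly one ordered (i, j) cell: the
type of the atom in the N-terminally earlier residue comes first (the chain is
asymmetric, so (i, j) and (j, i) are distinct pair types); within a residue,
canonical atom order breaks the tie.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .atoms import N_ATOM_TYPES
from .structure import StructureModel

FIRST_BIN_UPPER = 3.0
BIN_WIDTH = 0.5


@dataclass(frozen=True)
class BinningScheme:
    """Half-open distance bins [lo, hi) from 0 to the cutoff."""

    cutoff: float
    first_bin_upper: float = FIRST_BIN_UPPER
    bin_width: float = BIN_WIDTH

    def __post_init__(self) -> None:
        n = (self.cutoff - self.first_bin_upper) / self.bin_width
        if self.cutoff < self.first_bin_upper + self.bin_width or abs(
            n - round(n)
        ) > 1e-9:
            raise ValueError(
                f"cutoff {self.cutoff} must be >= {self.first_bin_upper + self.bin_width} "
                f"and first_bin_upper + a multiple of {self.bin_width}"
            )

    @property
    def n_bins(self) -> int:
        return 1 + round((self.cutoff - self.first_bin_upper) / self.bin_width)

    @property
    def edges(self) -> np.ndarray:
        """Bin edges: [0, 3.0, 3.5, ..., cutoff]."""
        return np.concatenate(
            [
                [0.0],
                self.first_bin_upper
                + self.bin_width * np.arange(self.n_bins, dtype=float),
            ]
        )

    @property
    def midpoints(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)


def make_scheme(cutoff: float) -> BinningScheme:
    """Binning scheme for a cutoff in {3.5, 4.0, ...}; 5 A -> 5 bins, 22 A -> 39."""
    return BinningScheme(cutoff=float(cutoff))


def bin_index(r, scheme: BinningScheme):
    """Bin of distance r, or -1 if r >= cutoff.  Vectorized; negative r raises."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative distance")
    b = np.where(
        r < scheme.first_bin_upper,
        0,
        1 + np.floor((r - scheme.first_bin_upper) / scheme.bin_width).astype(int),
    ).astype(int)
    b = np.where(r >= scheme.cutoff - 1e-12, -1, b)
    b = np.minimum(b, scheme.n_bins - 1)  # guard float edge just below cutoff
    return b if b.ndim else int(b)


@dataclass
class PairHistogram:
    """Ordered atom-type-pair x distance-bin count tensor with provenance.

    Also carries the side statistics later reference states need: the
    sequence-separation profile of the counted pairs (random-walk reference)
    and per-type atom totals (mole fractions for the quasi-chemical
    reference).
    """

    scheme: BinningScheme
    s_min: int
    counts: np.ndarray = None  # (167, 167, n_bins) int64
    separation_weights: Dict[int, int] = field(default_factory=dict)
    atom_counts: np.ndarray = None  # (167,) int64
    n_structures: int = 0

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(
                (N_ATOM_TYPES, N_ATOM_TYPES, self.scheme.n_bins), dtype=np.int64
            )
        if self.atom_counts is None:
            self.atom_counts = np.zeros(N_ATOM_TYPES, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def bin_totals(self) -> np.ndarray:
        """N_tot(b): counts summed over all ordered pair types."""
        return self.counts.sum(axis=(0, 1))


def qualifying_pairs(
    model: StructureModel, cutoff: float, s_min: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Atom pairs with |res(a)-res(b)| >= s_min and distance < cutoff.

    Returns (type_i, type_j, distance, separation) arrays with the ordered-pair
    convention already applied: because model atoms are sorted by (residue,
    canonical atom order), the lower atom index is the N-terminally earlier
    partner (or the canonically earlier atom within a residue).
    """
    coords = model.coords
    if coords.shape[0] < 2:
        z = np.zeros(0)
        return z.astype(int), z.astype(int), z, z.astype(int)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")  # i < j, d <= cutoff
    if pairs.size == 0:
        z = np.zeros(0)
        return z.astype(int), z.astype(int), z, z.astype(int)
    i, j = pairs[:, 0], pairs[:, 1]
    res = model.residue_indices
    sep = res[j] - res[i]  # >= 0 by atom ordering
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    keep = (sep >= s_min) & (d < cutoff)
    i, j, d, sep = i[keep], j[keep], d[keep], sep[keep]
    t = model.type_ids
    return t[i], t[j], d, sep


def count_pairs(
    model: StructureModel, scheme: BinningScheme, s_min: int
) -> PairHistogram:
    """Histogram one structure's qualifying atom pairs.

    Each unordered pair increments exactly one ordered cell.  Side statistics:
    separation_weights tallies qualifying pairs by sequence separation;
    atom_counts tallies every atom of the structure (pairing-independent).
    """
    hist = PairHistogram(scheme=scheme, s_min=int(s_min))
    ti, tj, d, sep = qualifying_pairs(model, scheme.cutoff, s_min)
    if d.size:
        b = bin_index(d, scheme)
        flat = (ti * N_ATOM_TYPES + tj) * scheme.n_bins + b
        np.add.at(hist.counts.reshape(-1), flat, 1)
        uniq, cnt = np.unique(sep, return_counts=True)
        hist.separation_weights = {int(u): int(c) for u, c in zip(uniq, cnt)}
    hist.atom_counts += np.bincount(model.type_ids, minlength=N_ATOM_TYPES).astype(
        np.int64
    )
    hist.n_structures = 1
    return hist


def accumulate(contributions: Iterable[PairHistogram]) -> Optional[PairHistogram]:
    """Element-wise sum of per-structure histograms sharing scheme and s_min."""
    total: Optional[PairHistogram] = None
    for h in contributions:
        if total is None:
            total = PairHistogram(scheme=h.scheme, s_min=h.s_min)
        if h.scheme != total.scheme or h.s_min != total.s_min:
            raise ValueError("mismatched scheme or residue interval")
        total.counts += h.counts
        total.atom_counts += h.atom_counts
        total.n_structures += h.n_structures
        for k, v in h.separation_weights.items():
            total.separation_weights[k] = total.separation_weights.get(k, 0) + v
    if total is None:
        total = PairHistogram(scheme=make_scheme(5.0), s_min=0)
    return total


def histogram_structures(
    models: Sequence[StructureModel], scheme: BinningScheme, s_min: int
) -> PairHistogram:
    """Count and accumulate over a training set."""
    return accumulate(count_pairs(m, scheme, s_min) for m in models)


def mole_fractions(hist: PairHistogram) -> np.ndarray:
    """chi_i: share of atoms of type i among all atoms of the training set."""
    total = hist.atom_counts.sum()
    if total == 0:
        raise ValueError("empty histogram: no atoms counted")
    return hist.atom_counts / total


def save_histogram(hist: PairHistogram, path) -> None:
    """Bit-exact serialization (npz container with a JSON metadata entry)."""
    meta = {
        "cutoff": hist.scheme.cutoff,
        "first_bin_upper": hist.scheme.first_bin_upper,
        "bin_width": hist.scheme.bin_width,
        "s_min": hist.s_min,
        "n_structures": hist.n_structures,
        "separation_weights": {str(k): v for k, v in hist.separation_weights.items()},
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        counts=hist.counts,
        atom_counts=hist.atom_counts,
    )


def load_histogram(path) -> PairHistogram:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        scheme = BinningScheme(
            cutoff=meta["cutoff"],
            first_bin_upper=meta["first_bin_upper"],
            bin_width=meta["bin_width"],
        )
        return PairHistogram(
            scheme=scheme,
            s_min=meta["s_min"],
            counts=data["counts"].copy(),
            atom_counts=data["atom_counts"].copy(),
            separation_weights={
                int(k): v for k, v in meta["separation_weights"].items()
            },
            n_structures=meta["n_structures"],
        )
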