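"""Reference states: the denominator of the inverse-Boltzmann energy.

A statistical potential compares the observed pair-distance distribution in
native structures against the distribution expected in the absence of
specific interactions — the reference state.  Six classic choices are
implemented:

ave    averaging: one pooled distance distribution shared by all pair types
kbp    quasi-chemical approximation: the pooled distribution scaled by the
       mole fractions chi_i * chi_j of the two atom types
dfire  finite ideal gas: bin probability grows as r**alpha with alpha < 2
dope   spherical non-interacting: two points uniform in a ball whose radius
       is set per training structure
rw     ideal random-walk (Gaussian) chain of rigid step length L, mixed over
       the training set's sequence-separation profile
srs    atom-shuffled: atom identities are randomly permuted over the fixed
       atomic positions of each training structure, then pairs are recounted

Count-based references (ave, kbp, srs) receive the same per-bin pseudocount
as the observed distribution, so identical counts give exactly zero energy.
Analytic references (dfire, dope, rw) are identical across pair types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
from scipy.special import erf

from .atoms import N_ATOM_TYPES, N_ORDERED_PAIRS
from .histogram import BinningScheme, PairHistogram, count_pairs, mole_fractions
from .structure import StructureModel

REFERENCE_KINDS = ("ave", "kbp", "dfire", "dope", "rw", "srs")

DEFAULT_ALPHA = 1.61  # finite-ideal-gas exponent; must stay below 2
DEFAULT_STEP_LENGTH = 3.8  # CA-CA virtual bond length, Angstrom
DEFAULT_PSEUDOCOUNT = 1.0

_FLOOR = 1e-12  # probability floor guarding log of empty analytic bins


@dataclass
class ReferenceSpec:
    """Parameters of a reference state."""

    kind: str
    alpha: float = DEFAULT_ALPHA
    sphere_radius_rule: str = "gyration"  # R_s = sqrt(5/3) * radius of gyration
    step_length: float = DEFAULT_STEP_LENGTH
    shuffle_seed: int = 0
    n_shuffles: int = 1
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.kind not in REFERENCE_KINDS:
            raise ValueError(f"unknown reference state {self.kind!r}")
        if self.alpha >= 2:
            raise ValueError("finite-ideal-gas exponent alpha must be < 2")
        if self.step_length <= 0:
            raise ValueError("step length must be positive")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class ReferenceModel:
    """Per-pair reference probabilities f_ref (rows sum to 1 over bins).

    f_ref may be stored broadcastable (1, 1, n_bins) when the reference is
    identical across pair types.  For the quasi-chemical reference the mole
    fractions and pooled bin totals are retained so the potential can use the
    un-normalized expected-count form.
    """

    kind: str
    f_ref: np.ndarray
    scheme: BinningScheme
    s_min: int
    spec: Optional[ReferenceSpec] = None
    chi: Optional[np.ndarray] = None  # (167,) mole fractions (kbp)
    bin_totals: Optional[np.ndarray] = None  # pooled N_tot(b) (kbp)

    @property
    def full(self) -> np.ndarray:
        """f_ref broadcast to the full (167, 167, n_bins) tensor."""
        return np.broadcast_to(
            self.f_ref, (N_ATOM_TYPES, N_ATOM_TYPES, self.scheme.n_bins)
        )


def observed_distribution(hist: PairHistogram, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """f_obs: per-pair distance distributions with per-bin pseudocount.

    With pseudocount 0, pairs with no counts at all are flagged unusable
    (NaN rows) rather than given an arbitrary distribution.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c = hist.counts.astype(float) + pseudocount
    totals = c.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(totals > 0, c / np.where(totals > 0, totals, 1.0), np.nan)
    return f


def _normalize_shared(mass: np.ndarray, scheme: BinningScheme, kind: str, **kw) -> ReferenceModel:
    mass = np.clip(np.asarray(mass, float), _FLOOR, None)
    f = (mass / mass.sum()).reshape(1, 1, -1)
    return ReferenceModel(kind=kind, f_ref=f, scheme=scheme, **kw)


def ave_reference(
    hist: PairHistogram, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ReferenceModel:
    """Averaging reference: the pooled distance distribution for every pair.

    The pseudocount enters exactly as in the observed distribution (one per
    pair type per bin, i.e. 167^2 per pooled bin), so a dataset in which every
    pair type already follows the pooled distribution is a fixed point.
    """
    if hist.total == 0 and pseudocount == 0:
        raise ValueError("empty histogram")
    pooled = hist.bin_totals().astype(float) + pseudocount * N_ORDERED_PAIRS
    return _normalize_shared(pooled, hist.scheme, "ave", s_min=hist.s_min)


def kbp_reference(
    hist: PairHistogram, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ReferenceModel:
    """Quasi-chemical reference: pooled distribution + mole-fraction factors.

    Expected counts E_ij(b) = chi_i * chi_j * N_tot(b); normalized over bins
    this equals the pooled distance distribution for every pair, but chi and
    N_tot are retained for the un-normalized expected-count energy form.
    """
    chi = mole_fractions(hist)
    pooled = hist.bin_totals().astype(float)
    ref = _normalize_shared(
        pooled + pseudocount * N_ORDERED_PAIRS, hist.scheme, "kbp", s_min=hist.s_min
    )
    ref.chi = chi
    ref.bin_totals = pooled
    return ref


def expected_counts_kbp(ref: ReferenceModel) -> np.ndarray:
    """E_ij(b) = chi_i chi_j N_tot(b) for the quasi-chemical reference."""
    if ref.chi is None or ref.bin_totals is None:
        raise ValueError("not a quasi-chemical reference")
    return (
        ref.chi[:, None, None] * ref.chi[None, :, None] * ref.bin_totals[None, None, :]
    )


def dfire_reference(
    scheme: BinningScheme, alpha: float = DEFAULT_ALPHA, s_min: int = 0
) -> ReferenceModel:
    """Finite-ideal-gas reference: bin probability grows as r**alpha.

    Bin masses are the exact integral of r**alpha over each bin (the wide
    first bin makes a midpoint approximation visibly biased there).
    """
    if alpha >= 2:
        raise ValueError("alpha must be < 2")
    if alpha <= -1:
        raise ValueError("alpha must be > -1 for integrable bin masses")
    e = scheme.edges
    mass = (e[1:] ** (alpha + 1) - e[:-1] ** (alpha + 1)) / (alpha + 1)
    spec = ReferenceSpec(kind="dfire", alpha=alpha)
    return _normalize_shared(mass, scheme, "dfire", s_min=s_min, spec=spec)


def fit_alpha(hist: PairHistogram) -> float:
    """Least-squares exponent of the pooled count density vs distance.

    Fits ln(N_tot(b)/dr_b) = alpha * ln(r_b) + c over bins 1..last (bin 0 has
    a different width and mixes hard-core effects); the estimate is clamped to
    (0, 2) — an ideal gas in 3D gives exactly 2, the admissible exponents lie
    strictly below.
    """
    pooled = hist.bin_totals().astype(float)
    r = hist.scheme.midpoints[1:]
    dens = pooled[1:] / hist.scheme.widths[1:]
    ok = dens > 0
    if ok.sum() < 3:
        raise ValueError("need >= 3 non-empty bins beyond the first to fit alpha")
    slope = np.polyfit(np.log(r[ok]), np.log(dens[ok]), 1)[0]
    return float(np.clip(slope, 1e-3, 2 - 1e-3))


def sphere_pair_distance_pdf(r, R: float):
    """Density of the distance between two uniform points in a ball of radius R.

    p(r|R) = (3 r^2 / R^3) (1 - 3r/(4R) + r^3/(16 R^3)) on [0, 2R], else 0.
    """
    r = np.asarray(r, float)
    p = (3 * r**2 / R**3) * (1 - 3 * r / (4 * R) + r**3 / (16 * R**3))
    return np.where((r >= 0) & (r <= 2 * R), p, 0.0)


def _sphere_pair_distance_cdf(r, R: float):
    r = np.clip(np.asarray(r, float), 0.0, 2 * R)
    x = r / R
    return x**3 - 9 * x**4 / 16 + x**6 / 32


def radius_of_gyration(coords: np.ndarray) -> float:
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum(axis=1).mean()))


def sphere_radius(model: StructureModel, rule: str = "gyration") -> float:
    """Per-structure sphere radius; default matches a uniform ball's R_g."""
    if rule == "gyration":
        return math.sqrt(5.0 / 3.0) * radius_of_gyration(model.coords)
    raise ValueError(f"unknown sphere radius rule {rule!r}")


def dope_reference(
    structures: Sequence[StructureModel],
    scheme: BinningScheme,
    sphere_radius_rule: str = "gyration",
    s_min: int = 0,
) -> ReferenceModel:
    """Spherical non-interacting reference.

    Each training structure contributes the pair-distance distribution of a
    uniformly filled ball of its own radius; contributions are weighted by the
    structure's number of atom pairs and the mixture is renormalized over the
    bins below the cutoff.  Bin masses come from the closed-form CDF.
    """
    if not structures:
        raise ValueError("need at least one training structure")
    edges = scheme.edges
    mass = np.zeros(scheme.n_bins)
    for m in structures:
        n = m.n_atoms
        if n < 2:
            raise ValueError(f"{m.source_path or 'structure'} has fewer than 2 atoms")
        R = sphere_radius(m, sphere_radius_rule)
        cdf = _sphere_pair_distance_cdf(edges, R)
        mass += (n * (n - 1) / 2) * np.diff(cdf)
    spec = ReferenceSpec(kind="dope", sphere_radius_rule=sphere_radius_rule)
    return _normalize_shared(mass, scheme, "dope", s_min=s_min, spec=spec)


def gaussian_chain_pdf(r, n: float, step_length: float = DEFAULT_STEP_LENGTH):
    """End-to-end distance density of an ideal chain of n steps of length L.

    P_n(r) = 4 pi r^2 (3 / (2 pi n L^2))^{3/2} exp(-3 r^2 / (2 n L^2)).
    """
    r = np.asarray(r, float)
    a2 = 3.0 / (2.0 * n * step_length**2)
    return 4.0 * np.pi * r**2 * (a2 / np.pi) ** 1.5 * np.exp(-a2 * r**2)


def _gaussian_chain_cdf(r, n: float, step_length: float):
    r = np.asarray(r, float)
    a = math.sqrt(3.0 / (2.0 * n * step_length**2))
    return erf(a * r) - (2.0 / math.sqrt(math.pi)) * a * r * np.exp(-((a * r) ** 2))

def rw_reference(
    hist: PairHistogram, step_length: float = DEFAULT_STEP_LENGTH
) -> ReferenceModel:
    """Random-walk-chain reference.

    The chain connectivity makes the expected pair-distance distribution
    depend on sequence separation; the reference mixes the Gaussian-chain
    density over the training set's separation profile (weights w_n =
    separation_weights[n] / total).  Same-residue pairs (separation 0, only
    present when s_min = 0) are folded into the one-step term.
    """
    if not hist.separation_weights:
        raise ValueError("histogram has no separation weights")
    weights: Dict[int, int] = {}
    for n, w in hist.separation_weights.items():
        weights[max(n, 1)] = weights.get(max(n, 1), 0) + w
    total = sum(weights.values())
    edges = hist.scheme.edges
    mass = np.zeros(hist.scheme.n_bins)
    for n, w in sorted(weights.items()):
        cdf = _gaussian_chain_cdf(edges, n, step_length)
        mass += (w / total) * np.diff(cdf)
    spec = ReferenceSpec(kind="rw", step_length=step_length)
    return _normalize_shared(mass, hist.scheme, "rw", s_min=hist.s_min, spec=spec)


def srs_reference(
    structures: Sequence[StructureModel],
    scheme: BinningScheme,
    s_min: int,
    shuffle_seed: int = 0,
    n_shuffles: int = 1,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    permutation_fn: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
) -> ReferenceModel:
    """Atom-shuffled reference.

    For each structure and shuffle round, atom identities (type ids) are
    permuted uniformly over the structure's fixed atomic positions (residue
    membership of each position is unchanged), pairs are recounted under the
    same scheme and interval, counts are averaged over rounds, and the result
    is normalized per pair exactly like the observed distribution.

    ``permutation_fn(rng, n) -> index array`` overrides the permutation draw
    (e.g. the identity, which reproduces the observed distribution exactly).
    """
    rng = np.random.default_rng(shuffle_seed)
    draw = permutation_fn or (lambda g, n: g.permutation(n))
    counts = np.zeros((N_ATOM_TYPES, N_ATOM_TYPES, scheme.n_bins))
    for _ in range(n_shuffles):
        for m in structures:
            perm = np.asarray(draw(rng, m.n_atoms))
            shuffled = _with_types(m, m.type_ids[perm])
            counts += count_pairs(shuffled, scheme, s_min).counts
    counts /= n_shuffles
    c = counts + pseudocount
    totals = c.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(totals > 0, c / np.where(totals > 0, totals, 1.0), np.nan)
    spec = ReferenceSpec(
        kind="srs",
        shuffle_seed=shuffle_seed,
        n_shuffles=n_shuffles,
        pseudocount=pseudocount,
    )
    return ReferenceModel(kind="srs", f_ref=f, scheme=scheme, s_min=s_min, spec=spec)


class _TypeOverlay:
    """Lightweight stand-in exposing the array surface count_pairs needs."""

    def __init__(self, model: StructureModel, type_ids: np.ndarray):
        self._m = model
        self.type_ids = np.asarray(type_ids, dtype=np.intp)
        self.n_atoms = model.n_atoms

    @property
    def coords(self):
        return self._m.coords

    @property
    def residue_indices(self):
        return self._m.residue_indices


def _with_types(model: StructureModel, type_ids: np.ndarray):
    return _TypeOverlay(model, type_ids)


def build_reference(
    kind: str,
    hist: PairHistogram,
    structures: Optional[Sequence[StructureModel]] = None,
    spec: Optional[ReferenceSpec] = None,
) -> ReferenceModel:
    """Dispatch to the reference builder for ``kind``.

    ``structures`` is required for the dope and srs references, which go back
    to the coordinates rather than the histogram.
    """
    spec = spec or ReferenceSpec(kind=kind)
    if kind == "ave":
        return ave_reference(hist, spec.pseudocount)
    if kind == "kbp":
        return kbp_reference(hist, spec.pseudocount)
    if kind == "dfire":
        return dfire_reference(hist.scheme, spec.alpha, hist.s_min)
    if kind == "rw":
        return rw_reference(hist, spec.step_length)
    if kind in ("dope", "srs"):
        if structures is None:
            raise ValueError(f"{kind} reference requires the training structures")
        if kind == "dope":
            return dope_reference(
                structures, hist.scheme, spec.sphere_radius_rule, hist.s_min
            )
        return srs_reference(
            structures,
            hist.scheme,
            hist.s_min,
            spec.shuffle_seed,
            spec.n_shuffles,
            spec.pseudocount,
        )
    raise ValueError(f"unknown reference state {kind!r}")
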