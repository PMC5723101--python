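"""Energy tables and structure scoring.

The potential is the inverse-Boltzmann log-ratio of observed to reference
pair-distance probabilities,

    u_ij(r) = -kT ln[ f_obs_ij(r) / f_ref_ij(r) ],

tabulated per ordered atom-type pair and distance bin, with kT set to 1: all
the performance measures used downstream (native recognition, Z-score,
energy/TM-score correlation) are invariant to a positive energy scale.

A potential constructed with residue interval s_construct may be *applied*
with any interval s_app: the scored pair set simply shrinks as s_app grows.
This decoupling is first-class here — one table yields one energy per
application interval.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .atoms import N_ATOM_TYPES, N_ORDERED_PAIRS
from .histogram import (
    BinningScheme,
    PairHistogram,
    bin_index,
    histogram_structures,
    make_scheme,
    qualifying_pairs,
)
from .reference import (
    DEFAULT_ALPHA,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_STEP_LENGTH,
    REFERENCE_KINDS,
    ReferenceModel,
    ReferenceSpec,
    build_reference,
    expected_counts_kbp,
    observed_distribution,
)
from .structure import StructureModel

DEFAULT_CUTOFFS: Tuple[float, ...] = tuple(float(c) for c in range(5, 23))
DEFAULT_INTERVALS: Tuple[int, ...] = tuple(range(16))


def format_name(ref_kind: str, cutoff: float, interval: int) -> str:
    """Canonical potential id, e.g. 'ave-6-6' or 'rw-17-3'.

    Cutoffs are named with integers when integral, per the field's convention.
    """
    c = int(cutoff) if float(cutoff).is_integer() else cutoff
    return f"{ref_kind}-{c}-{interval}"


def parse_name(name: str) -> Tuple[str, float, int]:
    """Inverse of :func:`format_name`; validates the reference kind."""
    parts = name.split("-")
    if len(parts) != 3:
        raise ValueError(f"malformed potential name {name!r}")
    ref, cut, interval = parts
    if ref not in REFERENCE_KINDS:
        raise ValueError(f"unknown reference state {ref!r} in {name!r}")
    try:
        cutoff = float(cut)
        s = int(interval)
    except ValueError as exc:
        raise ValueError(f"malformed potential name {name!r}") from exc
    if not 5.0 <= cutoff <= 22.0:
        import warnings

        warnings.warn(f"cutoff {cutoff} outside the usual 5-22 A range")
    return ref, cutoff, s


@dataclass
class PotentialTable:
    """Energy lookup u_ij(bin) with full provenance."""

    u: np.ndarray  # (167, 167, n_bins) float64, kT units
    scheme: BinningScheme
    s_construct: int
    ref_kind: str
    spec: Optional[ReferenceSpec] = None
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def name(self) -> str:
        return format_name(self.ref_kind, self.scheme.cutoff, self.s_construct)


def build_potential(
    hist: PairHistogram,
    ref: ReferenceModel,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PotentialTable:
    """Assemble the energy table from observed counts and a reference.

    The quasi-chemical (kbp) reference uses the expected-count form
    u = -ln[(N_ij(b)+pc) / (chi_i chi_j (N_tot(b) + pc * 167^2))]; all other
    references use the normalized-probability ratio.
    """
    if hist.scheme != ref.scheme:
        raise ValueError("histogram and reference use different binning schemes")
    if ref.kind == "kbp":
        obs = hist.counts.astype(float) + pseudocount
        exp = (
            ref.chi[:, None, None]
            * ref.chi[None, :, None]
            * (ref.bin_totals + pseudocount * N_ORDERED_PAIRS)[None, None, :]
        )
        with np.errstate(divide="ignore"):
            u = -np.log(obs / np.clip(exp, 1e-300, None))
    else:
        f_obs = observed_distribution(hist, pseudocount)
        u = -np.log(f_obs / ref.full)
    if not np.all(np.isfinite(u)):
        raise ValueError(
            "non-finite energies; use a positive pseudocount for sparse data"
        )
    return PotentialTable(
        u=u,
        scheme=hist.scheme,
        s_construct=hist.s_min,
        ref_kind=ref.kind,
        spec=ref.spec,
        pseudocount=pseudocount,
    )


def score_structure(
    model: StructureModel, pot: PotentialTable, s_app: Optional[int] = None
) -> float:
    """Total energy of a structure under a potential (kT units).

    ``s_app`` is the application residue interval; it defaults to the
    construction interval but may be any value — the same table then scores a
    larger (smaller) pair set.
    """
    s = pot.s_construct if s_app is None else int(s_app)
    ti, tj, d, _ = qualifying_pairs(model, pot.scheme.cutoff, s)
    if d.size == 0:
        return 0.0
    b = bin_index(d, pot.scheme)
    return float(pot.u[ti, tj, b].sum())


def grid_names(
    ref_kinds: Sequence[str] = REFERENCE_KINDS,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    intervals: Sequence[int] = DEFAULT_INTERVALS,
) -> List[str]:
    """Enumerate the parameter grid without training anything.

    The default grid is 6 reference states x 18 cutoffs (5..22 A) x 16
    residue intervals (0..15) = 1728 potentials, 288 per reference state.
    """
    return [
        format_name(r, c, s)
        for r, c, s in itertools.product(ref_kinds, cutoffs, intervals)
    ]


def build_grid(
    structures: Sequence[StructureModel],
    ref_kinds: Sequence[str] = REFERENCE_KINDS,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    intervals: Sequence[int] = DEFAULT_INTERVALS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    spec_overrides: Optional[Dict[str, ReferenceSpec]] = None,
) -> Dict[str, PotentialTable]:
    """Train one potential per (reference, cutoff, interval) triple.

    The pair histogram for a given (cutoff, interval) is computed once and
    shared across reference states.  Deterministic for a fixed shuffle seed.
    """
    if not structures:
        raise ValueError("empty training set")
    tables: Dict[str, PotentialTable] = {}
    for cutoff in cutoffs:
        scheme = make_scheme(cutoff)
        for s_min in intervals:
            hist = histogram_structures(structures, scheme, s_min)
            for kind in ref_kinds:
                spec = (spec_overrides or {}).get(kind) or ReferenceSpec(
                    kind=kind, pseudocount=pseudocount
                )
                ref = build_reference(kind, hist, structures=structures, spec=spec)
                table = build_potential(hist, ref, pseudocount)
                tables[table.name] = table
    return tables


def save_potential(pot: PotentialTable, path) -> None:
    """Versioned, bit-exact container (npz with a JSON metadata entry)."""
    spec = pot.spec
    meta = {
        "format_version": 1,
        "ref_kind": pot.ref_kind,
        "cutoff": pot.scheme.cutoff,
        "first_bin_upper": pot.scheme.first_bin_upper,
        "bin_width": pot.scheme.bin_width,
        "s_construct": pot.s_construct,
        "pseudocount": pot.pseudocount,
        "spec": {
            "alpha": spec.alpha,
            "sphere_radius_rule": spec.sphere_radius_rule,
            "step_length": spec.step_length,
            "shuffle_seed": spec.shuffle_seed,
            "n_shuffles": spec.n_shuffles,
            "pseudocount": spec.pseudocount,
        }
        if spec
        else None,
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), u=pot.u)


def load_potential(path) -> PotentialTable:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported potential file version {meta.get('format_version')}")
        scheme = BinningScheme(
            cutoff=meta["cutoff"],
            first_bin_upper=meta["first_bin_upper"],
            bin_width=meta["bin_width"],
        )
        spec = (
            ReferenceSpec(kind=meta["ref_kind"], **meta["spec"]) if meta["spec"] else None
        )
        return PotentialTable(
            u=data["u"].copy(),
            scheme=scheme,
            s_construct=meta["s_construct"],
            ref_kind=meta["ref_kind"],
            spec=spec,
            pseudocount=meta["pseudocount"],
        )


class DistancePotential(BaseEstimator):
    """Distance-dependent atom-pair potential as a fit/score estimator.

    Parameters
    ----------
    ref_state : {'ave', 'kbp', 'dfire', 'dope', 'rw', 'srs'}
        Reference-state model for the expected pair-distance distribution.
    cutoff : float
        Distance cutoff in Angstrom; pairs at or beyond it are ignored.
    interval : int
        Construction residue interval: minimum sequence separation of counted
        pairs (0 admits intra-residue pairs).
    pseudocount : float
        Per-bin pseudocount shared by observed and count-based reference
        distributions; keeps energies finite on sparse data.
    alpha : float
        Finite-ideal-gas exponent (< 2); 'auto' fits it from the training
        counts.
    step_length : float
        Random-walk-chain rigid step length, Angstrom.
    n_shuffles, random_state
        Rounds and seed of the atom-shuffled reference.

    Attributes
    ----------
    table_ : PotentialTable
        The fitted energy table.
    histogram_ : PairHistogram
        Training pair counts.
    reference_ : ReferenceModel
        The fitted reference distribution.
    name_ : str
        Canonical id, e.g. ``'ave-6-6'``.

    Examples
    --------
    >>> from pairpot.synthetic import generate_training_set
    >>> pot = DistancePotential('ave', cutoff=8, interval=3)
    >>> pot.fit(generate_training_set(10, (15, 25), seed=0))
    DistancePotential(cutoff=8, interval=3)
    >>> e = pot.score_structure(generate_training_set(1, (20, 20), seed=5)[0])
    """

    def __init__(
        self,
        ref_state: str = "ave",
        cutoff: float = 14.0,
        interval: int = 1,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        alpha=DEFAULT_ALPHA,
        step_length: float = DEFAULT_STEP_LENGTH,
        n_shuffles: int = 1,
        random_state: int = 0,
    ):
        self.ref_state = ref_state
        self.cutoff = cutoff
        self.interval = interval
        self.pseudocount = pseudocount
        self.alpha = alpha
        self.step_length = step_length
        self.n_shuffles = n_shuffles
        self.random_state = random_state

    def fit(self, X: Sequence[StructureModel], y=None) -> "DistancePotential":
        """Count pairs over the training structures and build the table."""
        if not X:
            raise ValueError("empty training set")
        scheme = make_scheme(self.cutoff)
        hist = histogram_structures(X, scheme, self.interval)
        alpha = self.alpha
        if alpha == "auto":
            from .reference import fit_alpha

            alpha = fit_alpha(hist)
        spec = ReferenceSpec(
            kind=self.ref_state,
            alpha=alpha,
            step_length=self.step_length,
            shuffle_seed=self.random_state,
            n_shuffles=self.n_shuffles,
            pseudocount=self.pseudocount,
        )
        self.reference_ = build_reference(
            self.ref_state, hist, structures=X, spec=spec
        )
        self.histogram_ = hist
        self.table_ = build_potential(hist, self.reference_, self.pseudocount)
        self.name_ = self.table_.name
        return self

    def score_structure(
        self, model: StructureModel, s_app: Optional[int] = None
    ) -> float:
        """Energy of one structure (kT); lower is more native-like."""
        self._check_fitted()
        return score_structure(model, self.table_, s_app)

    def transform(
        self, X: Sequence[StructureModel], s_app: Optional[int] = None
    ) -> np.ndarray:
        """Energies of a batch of structures, shape (n_structures,)."""
        self._check_fitted()
        return np.array([score_structure(m, self.table_, s_app) for m in X])

    def _check_fitted(self) -> None:
        if not hasattr(self, "table_"):
            raise ValueError("DistancePotential is not fitted; call fit first")
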