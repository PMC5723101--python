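"""Decoy-set benchmarks: native recognition, Z-score, and energy/TM correlation.

A decoy set is one experimental (native) structure plus many alternative
conformations of the same sequence.  Three measures summarize a potential's
performance over a benchmark of such sets:

R1-num   number of sets whose native gets the strictly lowest energy
Z-score  (mean decoy energy - native energy) / std of decoy energies;
         higher means better native separation
PCC      Pearson correlation between energy and TM-score over all structures
         of a set, native included; usually negative, the lower the better

All three are invariant to a positive affine rescaling of the energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .potential import PotentialTable, score_structure
from .similarity import tm_score
from .structure import StructureModel

logger = logging.getLogger(__name__)


@dataclass
class DecoySet:
    """One native structure plus decoys of the same (trimmed) sequence."""

    name: str
    native: StructureModel
    decoys: List[StructureModel]
    decoy_ids: Optional[List[str]] = None
    tm: Optional[Dict[str, float]] = None  # decoy id -> TM-score vs native

    def __post_init__(self) -> None:
        if not self.decoys:
            raise ValueError(f"decoy set {self.name!r} has no decoys")
        if self.decoy_ids is None:
            self.decoy_ids = [f"d{k}" for k in range(len(self.decoys))]

    def tm_scores(self) -> np.ndarray:
        """TM-scores of the decoys, computed on demand and cached."""
        if self.tm is None:
            self.tm = {
                did: tm_score(d, self.native)
                for did, d in zip(self.decoy_ids, self.decoys)
            }
        return np.array([self.tm[did] for did in self.decoy_ids])


@dataclass
class EvalRecord:
    """Measures of one potential on one decoy set at one application interval."""

    set_name: str
    potential_name: str
    s_app: int
    e_native: float
    decoy_energies: np.ndarray
    z: float
    pcc: float
    native_recognized: bool


def z_score(e_native: float, decoy_energies: Sequence[float]) -> float:
    """(mean decoy energy - native energy) / population std of decoy energies.

    NaN when fewer than 2 decoys or zero variance.
    """
    e = np.asarray(decoy_energies, float)
    if e.size < 2:
        return float("nan")
    sd = e.std()  # population (divide-by-n) convention
    if sd == 0:
        return float("nan")
    return float((e.mean() - e_native) / sd)


def native_recognized(e_native: float, decoy_energies: Sequence[float]) -> bool:
    """True iff the native energy is strictly below every decoy energy."""
    e = np.asarray(decoy_energies, float)
    return bool(e.size > 0 and e_native < e.min())


def pcc_energy_tm(energies: Sequence[float], tm_scores: Sequence[float]) -> float:
    """Pearson correlation of energy vs TM-score (native included by caller).

    NaN when either vector is constant or shorter than 3.
    """
    e = np.asarray(energies, float)
    t = np.asarray(tm_scores, float)
    if e.size != t.size:
        raise ValueError("energy and TM-score vectors differ in length")
    if e.size < 3 or e.std() == 0 or t.std() == 0:
        return float("nan")
    return float(stats.pearsonr(e, t).statistic)


def evaluate_set(
    decoy_set: DecoySet, pot: PotentialTable, s_app: Optional[int] = None
) -> EvalRecord:
    """Score one decoy set with one potential at one application interval."""
    s = pot.s_construct if s_app is None else int(s_app)
    e_native = score_structure(decoy_set.native, pot, s)
    e_decoys = np.array([score_structure(d, pot, s) for d in decoy_set.decoys])
    tm = np.concatenate([[1.0], decoy_set.tm_scores()])  # native TM = 1
    energies = np.concatenate([[e_native], e_decoys])
    return EvalRecord(
        set_name=decoy_set.name,
        potential_name=pot.name,
        s_app=s,
        e_native=e_native,
        decoy_energies=e_decoys,
        z=z_score(e_native, e_decoys),
        pcc=pcc_energy_tm(energies, tm),
        native_recognized=native_recognized(e_native, e_decoys),
    )


def evaluate_grid(
    decoy_sets: Sequence[DecoySet],
    potentials: Iterable[PotentialTable],
    s_app_values: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Long-format results table over (set, potential, application interval).

    ``s_app_values=None`` applies each potential at its construction interval
    only (the headline setting); pass e.g. ``range(16)`` for the decoupled
    sweep.
    """
    potentials = list(potentials)
    if not decoy_sets or not potentials:
        raise ValueError("need at least one decoy set and one potential")
    rows = []
    for pot in potentials:
        s_values = [pot.s_construct] if s_app_values is None else list(s_app_values)
        for ds in decoy_sets:
            for s in s_values:
                r = evaluate_set(ds, pot, s)
                rows.append(
                    {
                        "set": r.set_name,
                        "potential": r.potential_name,
                        "s_app": r.s_app,
                        "e_native": r.e_native,
                        "mean_e_decoy": float(np.mean(r.decoy_energies)),
                        "sd_e_decoy": float(np.std(r.decoy_energies)),
                        "z": r.z,
                        "pcc": r.pcc,
                        "recognized": r.native_recognized,
                    }
                )
    return pd.DataFrame(rows)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Per (potential, s_app) aggregates: R1-num, mean Z, mean PCC.

    Sets with undefined (NaN) Z or PCC are dropped from the respective means;
    the dropped counts are logged, never imputed.
    """
    n_bad_z = int(records["z"].isna().sum())
    n_bad_pcc = int(records["pcc"].isna().sum())
    if n_bad_z or n_bad_pcc:
        logger.info(
            "dropping %d undefined Z and %d undefined PCC records from means",
            n_bad_z, n_bad_pcc,
        )
    out = (
        records.groupby(["potential", "s_app"], sort=True)
        .agg(
            r1_num=("recognized", "sum"),
            mean_z=("z", "mean"),  # NaNs skipped, never imputed
            mean_pcc=("pcc", "mean"),
            n_sets=("recognized", "size"),
        )
        .reset_index()
    )
    out["r1_num"] = out["r1_num"].astype(int)
    return out


def set_difficulty(
    decoy_set: DecoySet, potentials: Iterable[PotentialTable]
) -> int:
    """Number of potentials (applied at their construction interval) that
    recognize the set's native structure — a difficulty score per set."""
    return sum(
        evaluate_set(decoy_set, pot).native_recognized for pot in potentials
    )
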