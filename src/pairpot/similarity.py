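"""Structural similarity between sequence-identical models.

Kabsch least-squares superposition, RMSD, and a deterministic TM-score for
same-length CA traces.  Because decoys are trimmed to the native sequence
before scoring, residue correspondence is one-to-one by index and no
alignment search is needed; d0 is always set from the native's length (the
score is therefore asymmetric in its arguments).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np

from .structure import StructureModel


@dataclass(frozen=True)
class Superposition:
    """Proper rotation + translation mapping one point set onto another."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.rotation.T + self.translation


def kabsch(X: np.ndarray, Y: np.ndarray) -> Superposition:
    """Optimal least-squares superposition of X onto Y (proper rotation).

    Minimizes sum |R x_k + t - y_k|^2 over rotations R (det +1) and
    translations t via SVD of the cross-covariance; degenerate (e.g.
    collinear) point sets still return a valid minimizer.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both be (N, 3)")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff**2).sum() / X.shape[0]))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def tm_d0(L: int) -> float:
    """Length-dependent distance scale, clamped at 0.5 A for short chains."""
    return max(0.5, 1.24 * np.cbrt(L - 15.0) - 1.8)


def _tm_from_distances(d: np.ndarray, d0: float, L: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L)


def tm_score(model: StructureModel, native: StructureModel) -> float:
    """TM-score of a model against its native structure, in (0, 1].

    Same-length CA correspondence by residue index (sequences must be
    identical).  The maximization over superpositions uses the standard
    iterative scheme: seed with Kabsch fits of contiguous fragments (lengths
    L, L/2, L/4, all start positions), then alternate between selecting
    residues within d0 of their native position and re-superposing on that
    inlier set until the set repeats.  Deterministic.
    """
    if model.sequence != native.sequence:
        raise ValueError("model and native sequences differ; trim first")
    X = model.ca_coords()
    Y = native.ca_coords()
    L = len(Y)
    if L < 3:
        raise ValueError("need at least 3 residues")
    d0 = tm_d0(L)
    best = 0.0
    frag_lens = sorted({L, max(L // 2, 3), max(L // 4, 3)}, reverse=True)
    for flen in frag_lens:
        for start in range(0, L - flen + 1):
            idx = np.arange(start, start + flen)
            best = max(best, _refine(X, Y, idx, d0, L))
    return best


def _refine(X, Y, seed_idx, d0, L, max_iter: int = 200) -> float:
    """Iterate superpose-on-inliers from one fragment seed; return best TM."""
    idx = seed_idx
    seen = set()
    best = 0.0
    for _ in range(max_iter):
        sup = kabsch(X[idx], Y[idx])
        d = np.linalg.norm(sup.apply(X) - Y, axis=1)
        best = max(best, _tm_from_distances(d, d0, L))
        inliers = np.flatnonzero(d < d0)
        if inliers.size < 3:
            inliers = np.argsort(d)[:3]
        key = inliers.tobytes()
        if key in seen:
            break
        seen.add(key)
        idx = inliers
    return best


def load_tm_table(path) -> Dict[str, float]:
    """Parse a two-column 'decoy-id score' text file (e.g. from the published
    TM-score program); scores must lie in (0, 1]."""
    table: Dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id score', got {line!r}")
        try:
            score = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad score {parts[1]!r}") from exc
        if not 0.0 < score <= 1.0:
            raise ValueError(f"{path}:{lineno}: TM-score {score} outside (0, 1]")
        table[parts[0]] = score
    return table
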