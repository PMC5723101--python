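"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain double loops over atoms (or
exhaustive seed enumeration for the TM-score), sharing no code path with the
package's vectorized/tree-based implementations.
"""

from __future__ import annotations

import numpy as np

N_TYPES = 167


def oracle_bin(r: float, cutoff: float) -> int:
    """Distance bin by explicit edge walking; -1 if out of range."""
    if r >= cutoff:
        return -1
    edges = [0.0, 3.0]
    while edges[-1] < cutoff - 1e-9:
        edges.append(edges[-1] + 0.5)
    for b in range(len(edges) - 1):
        if edges[b] <= r < edges[b + 1]:
            return b
    return -1


def oracle_count(model, cutoff: float, s_min: int) -> np.ndarray:
    """All-against-all double-loop pair counting."""
    n_bins = 1 + round((cutoff - 3.0) / 0.5)
    counts = np.zeros((N_TYPES, N_TYPES, n_bins), dtype=np.int64)
    atoms = model.atoms
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            sa, sb = atoms[a], atoms[b]
            if abs(sa.residue_index - sb.residue_index) < s_min:
                continue
            r = float(np.linalg.norm(sa.coords - sb.coords))
            bin_ = oracle_bin(r, cutoff)
            if bin_ < 0:
                continue
            # atom list order encodes the ordered-pair convention
            counts[sa.type_id, sb.type_id, bin_] += 1
    return counts


def oracle_score(model, u: np.ndarray, cutoff: float, s_app: int) -> float:
    """Brute-force energy summation."""
    total = 0.0
    atoms = model.atoms
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            sa, sb = atoms[a], atoms[b]
            if abs(sa.residue_index - sb.residue_index) < s_app:
                continue
            r = float(np.linalg.norm(sa.coords - sb.coords))
            bin_ = oracle_bin(r, cutoff)
            if bin_ < 0:
                continue
            total += u[sa.type_id, sb.type_id, bin_]
    return total


def _kabsch_np(X, Y):
    xc, yc = X.mean(0), Y.mean(0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, yc - R @ xc


def oracle_tm(X: np.ndarray, Y: np.ndarray, n_iter: int = 50) -> float:
    """Reference TM-score: every fragment seed, fixed refinement rounds."""
    L = len(Y)
    d0 = max(0.5, 1.24 * np.cbrt(L - 15.0) - 1.8)
    best = 0.0
    for flen in {L, max(L // 2, 3), max(L // 4, 3)}:
        for start in range(L - flen + 1):
            idx = np.arange(start, start + flen)
            for _ in range(n_iter):
                R, t = _kabsch_np(X[idx], Y[idx])
                d = np.linalg.norm(X @ R.T + t - Y, axis=1)
                best = max(best, float(np.mean(1.0 / (1.0 + (d / d0) ** 2))))
                idx = np.flatnonzero(d < d0)
                if len(idx) < 3:
                    idx = np.argsort(d)[:3]
    return best
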