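"""Independent reference implementations used only to cross-check the
package (never imported by it)."""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(ref: np.ndarray, mov: np.ndarray) -> float:
    """Minimum RMSD after optimal proper rotation, via Horn's
    quaternion eigenvalue method (no SVD, no shared code path)."""
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    x = ref - ref.mean(axis=0)
    y = mov - mov.mean(axis=0)
    S = y.T @ x
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    n = x.shape[0]
    msd = max(((x**2).sum() + (y**2).sum() - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def daura_reference(matrix: np.ndarray, cutoff: float) -> list[list[int]]:
    """Exhaustive restatement of the greedy neighbor-count clustering:
    recomputes every neighbor list from scratch each round."""
    matrix = np.asarray(matrix, dtype=float)
    remaining = set(range(matrix.shape[0]))
    clusters = []
    while remaining:
        counts = {}
        for i in sorted(remaining):
            counts[i] = sum(
                1 for j in remaining if matrix[i, j] <= cutoff
            )  # includes i itself (d(i,i)=0)
        best = max(sorted(counts), key=lambda i: counts[i])
        # max() keeps the first (lowest) index on ties
        members = sorted(
            j for j in remaining if matrix[best, j] <= cutoff
        )
        clusters.append(members)
        remaining -= set(members)
    return clusters
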