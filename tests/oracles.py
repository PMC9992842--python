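"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's solver path: the NNLS oracle is a
grid search over the feasible box, refined in two stages because a single
1e-3 grid over [0,1]^3 is a billion points.  Any sub-grid minimum
upper-bounds the continuous minimum from above, which is what the
solver-vs-oracle comparison needs.
"""

from __future__ import annotations

import itertools

import numpy as np


def grid_nnls_objective(M: np.ndarray, L: np.ndarray,
                        coarse_step: float = 0.02,
                        fine_step: float = 1e-3,
                        upper: float = 1.0) -> float:
    """Minimum of ||M f - L|| over the step-``fine_step`` grid in [0, upper]^k.

    Two-stage: coarse scan of the whole box, then a fine scan in a
    neighbourhood of the coarse argmin (the objective is convex, so the
    fine-grid minimiser lies near the coarse one).
    """
    k = M.shape[1]

    def scan(axes):
        best_val, best_f = np.inf, None
        # evaluate in chunks to bound memory
        grids = np.meshgrid(*axes, indexing="ij")
        F = np.stack([g.ravel() for g in grids], axis=1)
        r = F @ M.T - L
        vals = np.einsum("ij,ij->i", r, r)
        i = int(np.argmin(vals))
        return float(np.sqrt(vals[i])), F[i]

    coarse_axes = [np.arange(0.0, upper + coarse_step / 2, coarse_step)] * k
    _, f0 = scan(coarse_axes)
    fine_axes = []
    for c in f0:
        lo = max(0.0, c - 2 * coarse_step)
        hi = min(upper, c + 2 * coarse_step)
        fine_axes.append(np.arange(lo, hi + fine_step / 2, fine_step))
    val, _ = scan(fine_axes)
    return val


def exhaustive_grid_objective(M: np.ndarray, L: np.ndarray, step: float,
                              upper: float = 1.0) -> float:
    """Single-stage exhaustive grid minimum, for k <= 2 or coarse steps."""
    k = M.shape[1]
    axis = np.arange(0.0, upper + step / 2, step)
    best = np.inf
    for f in itertools.product(axis, repeat=k):
        r = M @ np.asarray(f) - L
        best = min(best, float(r @ r))
    return float(np.sqrt(best))
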