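"""Independent brute-force oracles used by the estimation tests.

The conditional-MLE oracle maximises the noncentral hypergeometric
likelihood of a 2x2 table by iteratively refined grid search over the log
odds ratio; it shares no code with the implementation under test.
"""

import numpy as np
from scipy.stats import nchypergeom_fisher


def conditional_mle_grid(a: int, b: int, c: int, d: int, *, half_width: float = 25.0,
                         n_points: int = 201, refinements: int = 3) -> float:
    """Grid-search maximiser of the conditional likelihood (odds-ratio scale)."""
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = -half_width, half_width
    best = 0.0
    for _ in range(refinements):
        grid = np.linspace(lo, hi, n_points)
        pmf = nchypergeom_fisher.pmf(a, N, K, n, np.exp(grid))
        i = int(np.argmax(pmf))
        best = grid[i]
        step = grid[1] - grid[0]
        lo, hi = best - step, best + step
    return float(np.exp(best))


def tail_at(psi: float, a: int, b: int, c: int, d: int, side: str) -> float:
    """P(X <= a) (side='upper') or P(X >= a) (side='lower') at odds ratio psi."""
    N, K, n = a + b + c + d, a + b, a + c
    if side == "upper":
        return float(nchypergeom_fisher.cdf(a, N, K, n, psi))
    return float(nchypergeom_fisher.sf(a - 1, N, K, n, psi))
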