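"""Independent brute-force oracles used to check the fitted statistics.

These deliberately avoid lifelines/statsmodels: the Cox oracle maximises
the partial likelihood by grid refinement, so agreement with the package's
fits is a genuine cross-check rather than a tautology.
"""

import numpy as np


def cox_partial_loglik(beta: float, time, event, x) -> float:
    """Breslow partial log-likelihood for a single covariate (no tied event
    times in the fixtures, where Breslow and Efron coincide)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.where(event == 1)[0]:
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def cox_grid_mle(time, event, x, lo=-4.0, hi=4.0, tol=1e-6) -> float:
    """Grid-refinement maximiser of the partial likelihood."""
    for _ in range(12):
        grid = np.linspace(lo, hi, 81)
        ll = [cox_partial_loglik(b, time, event, x) for b in grid]
        j = int(np.argmax(ll))
        lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]
        if hi - lo < tol:
            break
    return float((lo + hi) / 2)
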