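"""Independent brute-force oracles used by the test suite."""

import numpy as np


def grid_search_logistic(x, y, span=8.0, steps=81, zoom_rounds=6):
    """Refine a grid over (intercept, slope) minimizing the Bernoulli
    negative log-likelihood; independent of the IRLS path under test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xs = (x - x.mean()) / x.std()

    def nll(a, b):
        z = a + b * xs
        return float(np.sum(np.log1p(np.exp(z))) - np.dot(y, z))

    a0 = b0 = 0.0
    half = span
    for _ in range(zoom_rounds):
        a_grid = np.linspace(a0 - half, a0 + half, steps)
        b_grid = np.linspace(b0 - half, b0 + half, steps)
        vals = np.array([[nll(a, b) for b in b_grid] for a in a_grid])
        ia, ib = np.unravel_index(vals.argmin(), vals.shape)
        a0, b0 = a_grid[ia], b_grid[ib]
        half /= 8.0
    slope = b0 / x.std()
    intercept = a0 - slope * x.mean()
    return intercept, slope
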