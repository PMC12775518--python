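"""Independent brute-force oracles used only by tests.

These deliberately avoid the code paths they check: rotation search by
grid + simplex polish instead of the SVD solution, and exact
Mann-Whitney p-values by enumerating group assignments.
"""

from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_rmsd(a: np.ndarray, b: np.ndarray, n_starts: int = 60, seed: int = 0) -> float:
    """Minimum RMSD over rotations via random starts + Nelder-Mead polish."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    n = a.shape[0]

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.sum((ac @ r.T - bc) ** 2) / n)

    rng = np.random.default_rng(seed)
    starts = rng.normal(size=(n_starts, 3)) * np.pi
    values = [rmsd_of(v) for v in starts]
    best = np.inf
    for i in np.argsort(values)[:4]:
        res = minimize(
            rmsd_of,
            starts[i],
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
        )
        best = min(best, res.fun)
    return float(best)


def exact_mannwhitney_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Only feasible for small tie-free samples; returns (U of x, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)

    def u_stat(idx_x):
        xs = pooled[list(idx_x)]
        ys = np.delete(pooled, list(idx_x))
        return np.sum(xs[:, None] > ys[None, :]) + 0.5 * np.sum(xs[:, None] == ys[None, :])

    u_obs = float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))
    null = np.array([u_stat(c) for c in combinations(range(n1 + n2), n1)])
    p = 2.0 * min(np.mean(null <= u_obs + 1e-12), np.mean(null >= u_obs - 1e-12))
    return u_obs, float(min(p, 1.0))
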