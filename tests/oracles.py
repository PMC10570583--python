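"""Independent brute-force oracles used to cross-check the solvers."""

from __future__ import annotations

import itertools

import numpy as np


def simplex_grid(n: int, step: float) -> np.ndarray:
    """All strictly positive weight vectors on the n-simplex with components
    that are multiples of ``step``."""
    m = round(1.0 / step)
    pts = []
    for combo in itertools.combinations(range(1, m), n - 1):
        cuts = (0,) + combo + (m,)
        w = np.diff(cuts) / m
        if np.all(w > 0):
            pts.append(w)
    return np.array(pts)


def _local_grid(center: np.ndarray, step: float, span: int) -> np.ndarray:
    """Simplex points near ``center``: perturb n-1 free coordinates on a
    lattice of ``step`` within ±span*step, renormalizing the last."""
    n = center.size
    offsets = np.arange(-span, span + 1) * step
    pts = []
    for combo in itertools.product(offsets, repeat=n - 1):
        w = center.copy()
        w[:-1] = w[:-1] + np.array(combo)
        w[-1] = 1.0 - w[:-1].sum()
        if np.all(w > 0):
            pts.append(w)
    return np.array(pts)


def bwm_deviation(w: np.ndarray, best: int, worst: int,
                  bto: np.ndarray, otw: np.ndarray) -> np.ndarray:
    """Max BWM constraint deviation for each row of stacked weights w."""
    devs = []
    n = bto.size
    for j in range(n):
        if j != best:
            devs.append(np.abs(w[:, best] / w[:, j] - bto[j]))
        if j != worst:
            devs.append(np.abs(w[:, j] / w[:, worst] - otw[j]))
    return np.max(devs, axis=0)


def fucom_deviation(w: np.ndarray, phi: np.ndarray) -> np.ndarray:
    n = phi.size + 1
    devs = []
    for k in range(n - 1):
        devs.append(np.abs(w[:, k] / w[:, k + 1] - phi[k]))
    for k in range(n - 2):
        devs.append(np.abs(w[:, k] / w[:, k + 2] - phi[k] * phi[k + 1]))
    return np.max(devs, axis=0)


def grid_minimax(dev_fn, n: int, coarse: float = 0.01, fine: float = 1e-4):
    """Grid search minimizing the max deviation over the simplex: a coarse
    sweep, then successively zoomed local lattices around the argmin (each
    stage shrinks the step 5x until ``fine`` is reached)."""
    grid = simplex_grid(n, coarse)
    devs = dev_fn(grid)
    center = grid[int(np.argmin(devs))]
    best = float(np.min(devs))
    step = coarse
    while step > fine:
        nxt = max(step / 5.0, fine)
        local = _local_grid(center, nxt, span=int(step / nxt) + 2)
        ldevs = dev_fn(local)
        i = int(np.argmin(ldevs))
        center, best = local[i], float(ldevs[i])
        step = nxt
    return center, best
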