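"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the integral oracle
evaluates composition vectors by direct counting on a fine radius grid,
and the superposition oracle searches rotations on a refined Euler-angle
grid instead of using an SVD.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def hellinger_scalar(p, q) -> float:
    """Plain-Python evaluation of sqrt(0.5 * sum (sqrt(p)-sqrt(q))^2)."""
    return math.sqrt(0.5 * sum((math.sqrt(a) - math.sqrt(b)) ** 2 for a, b in zip(p, q)))


def composition_at(entries: list[tuple[float, str]], type_set: tuple[str, ...], r: float) -> np.ndarray:
    counts = np.array([sum(1 for d, t in entries if d <= r and t == ts) for ts in type_set], float)
    return counts / counts.sum()


def riemann_locohd(
    entriesA: list[tuple[float, str]],
    entriesB: list[tuple[float, str]],
    type_set: tuple[str, ...],
    lower: float,
    upper: float,
    step: float = 1e-3,
) -> float:
    """Riemann sum of the weighted Hellinger integral over (lower, upper).

    The integrand is piecewise constant, so a midpoint sum over a grid
    whose cell edges include every neighbor distance is exact up to
    float rounding.  Compositions are counted directly per cell; no
    closed-form machinery is reused.
    """
    breaks = sorted({d for d, _ in entriesA} | {d for d, _ in entriesB})
    edges = np.unique(np.concatenate([
        np.arange(lower, upper, step),
        [upper],
        [b for b in breaks if lower < b < upper],
    ]))
    total = 0.0
    # vectorized per-type cumulative counts at cell midpoints
    mids = (edges[:-1] + edges[1:]) / 2.0
    widths = np.diff(edges) / (upper - lower)
    compA = _comps_on_grid(entriesA, type_set, mids)
    compB = _comps_on_grid(entriesB, type_set, mids)
    h = np.sqrt(0.5 * np.sum((np.sqrt(compA) - np.sqrt(compB)) ** 2, axis=1))
    total = float(np.sum(h * widths))
    return total


def _comps_on_grid(entries, type_set, radii: np.ndarray) -> np.ndarray:
    counts = np.zeros((len(radii), len(type_set)))
    for j, ts in enumerate(type_set):
        dists = np.sort([d for d, t in entries if t == ts])
        counts[:, j] = np.searchsorted(dists, radii, side="right")
    return counts / counts.sum(axis=1, keepdims=True)


def grid_search_rmsd(X: np.ndarray, Y: np.ndarray, levels: int = 6) -> float:
    """Best RMSD over proper rotations found by a refined Euler-angle grid."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    center = np.zeros(3)
    width = np.pi
    best = None
    steps = 12
    for _ in range(levels):
        axes = [np.linspace(c - width, c + width, steps) for c in center]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        mats = Rotation.from_euler("xyz", grid).as_matrix()
        rotated = np.einsum("rij,nj->rni", mats, Yc)
        rmsds = np.sqrt(((Xc[None] - rotated) ** 2).sum(axis=(1, 2)) / X.shape[0])
        k = int(np.argmin(rmsds))
        best = float(rmsds[k])
        center = grid[k]
        width = width * 2.5 / steps
    return best
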