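"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: texture matrices are
built by enumerating voxel pairs / walking runs one voxel at a time, and
AUC by the O(n^2) concordance double loop.
"""

from __future__ import annotations

import numpy as np


def brute_glcm(levels: np.ndarray, direction, distance: int = 1) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit pair enumeration."""
    nb = int(levels.max())
    mat = np.zeros((nb, nb))
    d = tuple(c * distance for c in direction)
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if levels[x, y, z] == 0:
                    continue
                xx, yy, zz = x + d[0], y + d[1], z + d[2]
                if not (0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz):
                    continue
                if levels[xx, yy, zz] == 0:
                    continue
                i, j = levels[x, y, z] - 1, levels[xx, yy, zz] - 1
                mat[i, j] += 1
                mat[j, i] += 1
    s = mat.sum()
    return mat / s if s > 0 else mat


def brute_glrlm(levels: np.ndarray, direction) -> np.ndarray:
    """Run-length matrix by walking every lattice line voxel by voxel."""
    nx, ny, nz = levels.shape
    max_len = max(nx, ny, nz)
    nb = int(levels.max())
    mat = np.zeros((nb, max_len))
    d = direction

    def inside(p):
        return all(0 <= p[i] < levels.shape[i] for i in range(3))

    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                p = (x, y, z)
                if levels[p] == 0:
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if inside(prev) and levels[prev] == levels[p]:
                    continue  # not a run start
                length = 1
                cur = p
                while True:
                    nxt = tuple(cur[i] + d[i] for i in range(3))
                    if inside(nxt) and levels[nxt] == levels[cur]:
                        length += 1
                        cur = nxt
                    else:
                        break
                mat[levels[p] - 1, length - 1] += 1
    return mat


def brute_auc(scores, labels) -> float:
    """Pairwise concordance with ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_soft_threshold_lasso(X: np.ndarray, y: np.ndarray, lam: float,
                               grid_half_width: float = 5.0,
                               n_grid: int = 200_001) -> np.ndarray:
    """Per-coordinate 1-D minimization of the LASSO objective on an
    orthonormal design ((1/n) X'X = I), by dense grid search."""
    n, p = X.shape
    yc = y - y.mean()
    beta = np.zeros(p)
    grid = np.linspace(-grid_half_width, grid_half_width, n_grid)
    for j in range(p):
        ols = X[:, j] @ yc / n
        # objective restricted to coordinate j (others at 0, orthonormal)
        obj = (ols - grid) ** 2 + lam * np.abs(grid)
        beta[j] = grid[int(np.argmin(obj))]
    return beta
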