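"""Independent oracles used by the tests.

These deliberately re-derive geometric and statistical quantities by brute
force (per-pixel loops, direct normal equations), independently of the
package's implementations, so tests compare two routes to the same answer.
"""

import numpy as np


def raster_disk(shape, center, radius):
    """Boolean disk mask: pixel centers within ``radius`` of ``center``."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def brute_boundary(mask):
    """4-neighbour boundary by an explicit per-pixel scan."""
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def normal_equations_ols(x, y):
    """Slope and intercept via the closed-form normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1]), float(beta[0])


def boundary_distance_mean(mask, centroid):
    """Mean Euclidean distance from ``centroid`` to the brute-force boundary
    pixels of ``mask``."""
    b = brute_boundary(mask)
    rows, cols = np.nonzero(b)
    return float(np.hypot(rows - centroid[0], cols - centroid[1]).mean())


def penetration_oracle(radius, depth, scale=1.10, shape=(200, 200), center=(100, 100)):
    """Raster-oracle penetration for a coat of ``depth`` px on a disk.

    External boundary from an independently rasterized disk of the scaled
    radius; internal boundary from a disk of radius ``radius - depth``
    (the unstained core). Both distance means are taken from the scaled
    disk's pixel centroid, mirroring the measurement's definition.
    """
    outer = raster_disk(shape, center, radius * scale)
    rows, cols = np.nonzero(outer)
    centroid = (rows.mean(), cols.mean())
    ext = boundary_distance_mean(outer, centroid)
    core_radius = radius - depth
    if core_radius <= 0:
        return ext, 0.0, ext  # full penetration convention
    core = raster_disk(shape, center, core_radius)
    internal = boundary_distance_mean(core, centroid)
    return ext, internal, ext - internal
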