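"""Numba kernels for the inner loops of rim selection and Debye sums.

These are pure-performance rewrites of operations defined (and tested)
in plain NumPy elsewhere: the weighted pair-distance histogram behind
the Debye intensity, and the point-to-curve anisotropic distance scan
behind rim selection.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def pair_histogram(pos, b, inv_bw, nbins):
    """Histogram of b_i·b_j over i<j pair distances, bins of 1/inv_bw Å."""
    n = pos.shape[0]
    hist = np.zeros(nbins)
    for i in range(n):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        bi = b[i]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            k = int(r * inv_bw)
            if k < nbins:
                hist[k] += bi * b[j]
    return hist


@njit(cache=True)
def curve_scan(points, curve, rx2, rz2, ox2, oz2):
    """Fused anisotropic distance scan of points against a curve.

    For each point, returns the minimum scaled squared distance under
    the core metric (half-axes² rx2, rz2), the index of the curve point
    achieving it, and the minimum under the outer/shell metric (ox2,
    oz2).  No fastmath: results are bit-identical to the NumPy
    formulation, whichever path runs.
    """
    n = points.shape[0]
    m = curve.shape[0]
    min_core = np.empty(n)
    arg_core = np.empty(n, np.int64)
    min_outer = np.empty(n)
    for i in range(n):
        xi, yi, zi = points[i, 0], points[i, 1], points[i, 2]
        best_c = 1e300
        best_j = 0
        best_o = 1e300
        for j in range(m):
            dx = curve[j, 0] - xi
            dy = curve[j, 1] - yi
            dz = curve[j, 2] - zi
            dxy = dx * dx + dy * dy
            dzz = dz * dz
            c = dxy / rx2 + dzz / rz2
            if c < best_c:
                best_c = c
                best_j = j
            o = dxy / ox2 + dzz / oz2
            if o < best_o:
                best_o = o
        min_core[i] = best_c
        arg_core[i] = best_j
        min_outer[i] = best_o
    return min_core, arg_core, min_outer
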