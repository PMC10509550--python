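"""Exact Euclidean distance transform on binary rasters.

The transform here is the workhorse behind the inscribed-disk width
estimator: for every foreground (object) pixel it returns the squared
Euclidean distance, in pixel units, from that pixel's center to the center
of the nearest background pixel.  The two-pass separable algorithm (column
scan followed by a lower-envelope-of-parabolas pass per row) computes the
exact transform in O(rows x cols).

Implemented as a numba kernel so that it can be called millions of times on
tiny windows (exhaustive small-shape verification, per-fragment windows)
without per-call overhead, and invoked from other jitted code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Sentinel "no background in this column yet" distance; squares stay well
# inside float64 range (1e18 << 1.8e308).
_BIG = 1.0e9


@njit(cache=False)
def edt_sq(occ: np.ndarray) -> np.ndarray:  # pragma: no cover - jitted
    """Squared EDT of a 2-D boolean array (True = object).

    Distances are measured between pixel centers, to the nearest False
    pixel *within the array*; pixels outside the array do not exist.  If
    the array contains no False pixel, all entries come back >= _BIG**2
    (callers guard this case).
    """
    nr, nc = occ.shape
    g = np.empty((nr, nc), dtype=np.float64)

    # vertical pass: per-column distance (in rows) to nearest background
    for j in range(nc):
        g[0, j] = 0.0 if not occ[0, j] else _BIG
        for i in range(1, nr):
            g[i, j] = 0.0 if not occ[i, j] else min(_BIG, g[i - 1, j] + 1.0)
        for i in range(nr - 2, -1, -1):
            if g[i + 1, j] + 1.0 < g[i, j]:
                g[i, j] = g[i + 1, j] + 1.0

    out = np.empty((nr, nc), dtype=np.float64)
    v = np.empty(nc, dtype=np.int64)
    z = np.empty(nc + 1, dtype=np.float64)

    # horizontal pass: lower envelope of parabolas f_p(q) = (q-p)^2 + g[i,p]^2
    for i in range(nr):
        k = 0
        v[0] = 0
        z[0] = -1.0e30
        z[1] = 1.0e30
        for q in range(1, nc):
            fq = g[i, q] * g[i, q] + q * q
            while True:
                p = v[k]
                fp = g[i, p] * g[i, p] + p * p
                s = (fq - fp) / (2.0 * (q - p))
                if s <= z[k]:
                    k -= 1
                else:
                    break
            k += 1
            v[k] = q
            z[k] = s
            z[k + 1] = 1.0e30
        k = 0
        for q in range(nc):
            while z[k + 1] < q:
                k += 1
            p = v[k]
            dq = float(q - p)
            out[i, q] = dq * dq + g[i, p] * g[i, p]
    return out


@njit(cache=False)
def max_inscribed_radius(occ: np.ndarray) -> float:  # pragma: no cover
    """Largest EDT value over object pixels = radius of the largest
    inscribed disk, in pixels.  Returns -1.0 for an empty object and
    >= _BIG for an object with no background pixel in view."""
    d2 = edt_sq(occ)
    best = -1.0
    nr, nc = occ.shape
    for i in range(nr):
        for j in range(nc):
            if occ[i, j] and d2[i, j] > best:
                best = d2[i, j]
    if best < 0.0:
        return -1.0
    return np.sqrt(best)
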