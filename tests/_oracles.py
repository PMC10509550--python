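"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented by the most direct method
available (exhaustive scans, flood fill, enumeration) and shares no code
with the package's own algorithms.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from numba import njit

from fragmetrics._edt import edt_sq


def brute_force_width_px(occ: np.ndarray) -> float:
    """Inscribed-disk diameter by exhaustive per-pixel nearest-boundary scan.

    For every fragment pixel, scan *all* non-fragment pixels for the
    nearest one; the width is twice the largest such distance.  O(n^2).
    """
    occ = np.asarray(occ, dtype=bool)
    fr = np.argwhere(occ).astype(float)
    bg = np.argwhere(~occ).astype(float)
    if len(fr) == 0 or len(bg) == 0:
        raise ValueError("need both fragment and background pixels")
    # chunked so large rasters stay within memory; still a full scan
    worst = 0.0
    for i in range(0, len(fr), 256):
        chunk = fr[i : i + 256]
        d = np.sqrt(((chunk[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2))
        worst = max(worst, float(d.min(axis=1).max()))
    return 2.0 * worst


def flood_fill_count(occ: np.ndarray) -> int:
    """8-connected component count by plain stack-based flood fill."""
    occ = np.asarray(occ, dtype=bool)
    seen = np.zeros_like(occ)
    count = 0
    nr, nc = occ.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if occ[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < nr and 0 <= cc < nc:
                                if occ[rr, cc] and not seen[rr, cc]:
                                    seen[rr, cc] = True
                                    stack.append((rr, cc))
    return count


def brute_force_min_distance_px(pa: np.ndarray, pb: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance between two pixel-coordinate sets."""
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return float(d.min())


def mann_whitney_exact_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Returns (U of sample a, two-sided p).  Assumes no ties.
    """
    a, b = list(a), list(b)
    na = len(a)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_of = lambda sample: sum(ranks[v] for v in sample) - len(sample) * (len(sample) + 1) / 2
    u_obs = u_of(a)
    n = len(pooled)
    mean_u = na * (n - na) / 2
    us = [
        sum(ranks[pooled[i]] for i in idx) - na * (na + 1) / 2
        for idx in combinations(range(n), na)
    ]
    dev = abs(u_obs - mean_u)
    p = sum(abs(u - mean_u) >= dev - 1e-12 for u in us) / len(us)
    return float(u_obs), float(p)


def random_blob(rng: np.random.Generator, size: int = 40) -> np.ndarray:
    """One random 8-connected blob in a (size x size) grid with clear border."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=3.0)
    occ = noise > np.quantile(noise, rng.uniform(0.6, 0.9))
    occ[0, :] = occ[-1, :] = occ[:, 0] = occ[:, -1] = False
    labels, n = ndimage.label(occ, structure=np.ones((3, 3), bool))
    if n == 0:
        occ = np.zeros((size, size), bool)
        occ[size // 2, size // 2] = True
        return occ
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def random_multi_blob(rng: np.random.Generator, size: int = 60) -> np.ndarray:
    """A random mask that may contain several 8-connected components."""
    from scipy import ndimage

    noise = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=2.0)
    occ = noise > np.quantile(noise, rng.uniform(0.7, 0.95))
    occ[0, :] = occ[-1, :] = occ[:, 0] = occ[:, -1] = False
    return occ


# ---------------------------------------------------------------------------
# exhaustive small-shape driver (jitted: it visits every 8-connected shape
# that fits a 5x5 grid, ~2e7 of them)


@njit(cache=False)
def exhaustive_width_check_5x5(nbr):  # pragma: no cover - jitted
    """Enumerate every non-empty 8-connected subset of the 5x5 grid.

    For each shape, embedded with a 1-pixel background ring in a 7x7
    window, compare twice the largest package-EDT value over shape pixels
    (the tested implementation path) against an exhaustive per-pixel
    nearest-background scan (the oracle).  Returns (number of connected
    shapes checked, maximum |impl - oracle| in pixels).
    """
    n_checked = 0
    max_err = 0.0
    occ = np.zeros((7, 7), dtype=np.bool_)
    for s in range(1, 1 << 25):
        # connectivity by bitmask flood fill from the lowest set bit
        low = s & (-s)
        reached = low
        frontier = low
        while frontier != 0:
            nxt = 0
            f = frontier
            while f != 0:
                b = f & (-f)
                i = 0
                bb = b
                while bb > 1:
                    bb >>= 1
                    i += 1
                nxt |= nbr[i]
                f ^= b
            frontier = nxt & s & ~reached
            reached |= frontier
        if reached != s:
            continue
        n_checked += 1
        for i in range(25):
            occ[1 + i // 5, 1 + i % 5] = (s >> i) & 1 == 1
        # implementation route: the package's EDT kernel
        d2 = edt_sq(occ)
        best = 0.0
        for r in range(1, 6):
            for c in range(1, 6):
                if occ[r, c] and d2[r, c] > best:
                    best = d2[r, c]
        w_impl = 2.0 * np.sqrt(best)
        # oracle route: exhaustive nearest-background scan
        worst = 0.0
        for r in range(1, 6):
            for c in range(1, 6):
                if occ[r, c]:
                    m = 1.0e18
                    for r2 in range(7):
                        for c2 in range(7):
                            if not occ[r2, c2]:
                                dd = float((r - r2) ** 2 + (c - c2) ** 2)
                                if dd < m:
                                    m = dd
                    if m > worst:
                        worst = m
        w_oracle = 2.0 * np.sqrt(worst)
        err = abs(w_impl - w_oracle)
        if err > max_err:
            max_err = err
    return n_checked, max_err


def neighbor_masks_5x5() -> np.ndarray:
    """8-neighborhood bitmasks for each cell of the 5x5 grid."""
    nbr = np.zeros(25, dtype=np.int64)
    for i in range(25):
        r, c = i // 5, i % 5
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < 5 and 0 <= cc < 5:
                    nbr[i] |= 1 << (rr * 5 + cc)
    return nbr
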