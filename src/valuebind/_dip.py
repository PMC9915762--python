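"""Hartigan's dip statistic of unimodality.

The dip of an empirical CDF F_n is the smallest sup-norm distance from F_n to
any unimodal CDF (convex up to its mode, concave beyond). This implements the
classical iterative modal-interval algorithm: working in count units, it fits
the greatest convex minorant (GCM) and least concave majorant (LCM) of F_n on
a candidate modal interval [low, high], finds the largest separation between
the two fits, updates the dip with the maximal deviation of F_n from the GCM
left of the separation point and from the LCM right of it, and shrinks the
interval until the separation no longer exceeds the current dip. The dip has
floor 1/(2n) and approaches 1/4 in the extreme two-cluster limit. The test
suite validates it against an independent linear-programming oracle at
small n.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hartigan_dip"]


def _gcm_touches(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Knot indices where the greatest convex minorant touches (x_i, i).

    Monotone-chain lower hull of the points (x_i, i) for i in [lo, hi]; a
    point is dropped when it lies on or above the chord joining its hull
    predecessor to the incoming point.
    """
    hull: list[int] = []
    for j in range(lo, hi + 1):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (b - a) * (x[j] - x[a]) >= (j - a) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(j)
    return np.array(hull)


def _lcm_touches(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Knot indices where the least concave majorant touches (x_i, i)."""
    rev = _gcm_touches(-x[::-1], len(x) - 1 - hi, len(x) - 1 - lo)
    return (len(x) - 1 - rev)[::-1]


def _interp(touches: np.ndarray, x: np.ndarray, xq: np.ndarray) -> np.ndarray:
    return np.interp(xq, x[touches], touches.astype(float))


def hartigan_dip(values: np.ndarray) -> float:
    """Dip statistic of a 1-D sample."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = len(x)
    if n < 1:
        raise ValueError("empty sample")
    if n == 1:
        return 0.5

    low, high = 0, n - 1
    dip = 1.0  # count units; scaled by 1/(2n) on return

    while True:
        gcm = _gcm_touches(x, low, high)     # ascending knot indices
        lcm = _lcm_touches(x, low, high)     # ascending knot indices

        if len(gcm) == 2 and len(lcm) == 2:
            d = 1.0
            arg = ("none", low, high)
        else:
            # largest separation between the LCM and GCM fits, in counts:
            # LCM touch v sits one upper step above the GCM interpolation;
            # GCM touch g sits one lower step below the LCM interpolation.
            d = -np.inf
            arg = None
            gv = _interp(gcm, x, x[lcm])
            for k, v in enumerate(lcm):
                dx = (v + 1) - gv[k]
                if dx >= d:
                    # modal interval shrinks to [left GCM touch of v's segment, v]
                    a = gcm[np.searchsorted(x[gcm], x[v], side="right") - 1]
                    d, arg = dx, (int(a), int(v))
            lv = _interp(lcm, x, x[gcm])
            for k, g in enumerate(gcm):
                dx = lv[k] - (g - 1)
                if dx >= d:
                    # modal interval shrinks to [g, right LCM touch of g's segment]
                    idx = np.searchsorted(x[lcm], x[g], side="left")
                    w = lcm[min(idx if x[lcm[min(idx, len(lcm) - 1)]] >= x[g] else idx + 1,
                                len(lcm) - 1)]
                    d, arg = dx, (int(g), int(w))

        if d < dip:
            break

        new_low, new_high = arg if arg[0] != "none" else (low, high)

        # deviation of F_n above the GCM on [low, new_low]
        dip_l = 1.0
        seg = gcm[gcm <= new_low]
        for a, b in zip(seg[:-1], seg[1:]):
            if b - a > 1 and x[b] != x[a]:
                jj = np.arange(a, b + 1)
                t = (jj - a + 1) - (x[jj] - x[a]) * (b - a) / (x[b] - x[a])
                dip_l = max(dip_l, float(t.max()))

        # deviation of F_n below the LCM on [new_high, high]
        dip_u = 1.0
        seg = lcm[lcm >= new_high]
        for a, b in zip(seg[:-1], seg[1:]):
            if b - a > 1 and x[b] != x[a]:
                jj = np.arange(a, b + 1)
                t = (x[jj] - x[a]) * (b - a) / (x[b] - x[a]) - (jj - a - 1)
                dip_u = max(dip_u, float(t.max()))

        dip = max(dip, dip_l, dip_u)
        if (new_low, new_high) == (low, high):
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)
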