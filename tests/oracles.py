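"""Independent brute-force oracles for the ROC point estimates.

Deliberately slow and literal: geometric interpolation along the ROC
polyline, exhaustive pair counting, exhaustive support scans in exact
rational arithmetic, and the closed-form Mann-Whitney variance estimator.
They share no code with the package's implementations.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def roc_vertices(g, i):
    """ROC polyline vertices [(FAR, TAR)] from origin to (1, 1)."""
    support = sorted(set(g) | set(i))
    pts = [(0.0, 0.0)]
    for s in reversed(support):
        far = sum(1 for x in i if x >= s) / len(i)
        tar = sum(1 for x in g if x >= s) / len(g)
        pts.append((far, tar))
    return pts


def tar_at_far_polyline(g, i, f):
    """Linear interpolation of TAR at FAR = f along the ROC polyline."""
    pts = roc_vertices(g, i)
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if x0 < f <= x1:
            return y0 + (y1 - y0) * (f - x0) / (x1 - x0)
    raise AssertionError(f"no polyline segment covers FAR={f}")


def aurc_pairs(g, i):
    """Exhaustive pair count: mean of 1(g > i) + 0.5 * 1(g = i)."""
    total = Fraction(0)
    for a in g:
        for b in i:
            if a > b:
                total += 1
            elif a == b:
                total += Fraction(1, 2)
    return float(total / (len(g) * len(i)))


def eer_scan(g, i):
    """Exhaustive threshold scan for the EER in exact rational arithmetic.

    Enumerates every admissible operating point literally: for integer score
    systems, every lattice score from min to max (observed or not); for
    continuous ones, every observed score plus the midpoint between each
    adjacent pair. Type I error = fraction of genuine scores <= t, type II
    error = fraction of impostor scores >= t, both with the next-value offset
    folded in by the <= / >= asymmetry. Returns
    (eer, s1, s2, threshold, min_absdiff).
    """
    support = sorted(set(g) | set(i))
    n_g, n_i = len(g), len(i)
    integral = all(float(s).is_integer() for s in support)

    def rates(t):
        er1 = Fraction(sum(1 for x in g if x <= t), n_g)
        er2 = Fraction(sum(1 for x in i if x >= t), n_i)
        return er1, er2

    rows = []  # (span_lo, span_hi, er1, er2)
    if integral:
        for t in range(int(support[0]), int(support[-1]) + 1):
            er1, er2 = rates(t)
            rows.append((float(t), float(t), er1, er2))
    else:
        for k, s in enumerate(support):
            er1, er2 = rates(s)
            rows.append((s, s, er1, er2))
            if k + 1 < len(support):
                er1, er2 = rates((s + support[k + 1]) / 2)
                rows.append((s, support[k + 1], er1, er2))

    m = min(abs(r[2] - r[3]) for r in rows)
    argmin = [r for r in rows if abs(r[2] - r[3]) == m]
    first, last = argmin[0], argmin[-1]
    eer = ((first[2] + first[3]) / 2 + (last[2] + last[3]) / 2) / 2
    s1, s2 = first[0], last[1]
    mid = (s1 + s2) / 2
    if integral:
        threshold = float(np.floor(mid))
    else:
        threshold = max(s for s in support if s <= mid)
    return float(eer), s1, s2, threshold, float(m)


def mann_whitney_se(g, i):
    """Closed-form SE of the AUC: the two-sample U-statistic variance
    estimator built from placement values (half-weight ties)."""
    g = np.asarray(g, dtype=float)
    i = np.asarray(i, dtype=float)
    gs, isrt = np.sort(g), np.sort(i)
    v10 = (
        np.searchsorted(isrt, g, side="left") + np.searchsorted(isrt, g, side="right")
    ) / (2.0 * i.size)
    v01 = 1.0 - (
        np.searchsorted(gs, i, side="left") + np.searchsorted(gs, i, side="right")
    ) / (2.0 * g.size)
    return float(np.sqrt(np.var(v10, ddof=1) / g.size + np.var(v01, ddof=1) / i.size))


def random_tied_sample(rng, max_n=50):
    """A small random score sample with deliberate ties (integer support)."""
    n_g = int(rng.integers(2, max_n + 1))
    n_i = int(rng.integers(2, max_n + 1))
    hi = int(rng.integers(3, 12))
    shift = int(rng.integers(0, 4))
    g = rng.integers(shift, shift + hi, n_g).astype(float)
    i = rng.integers(0, hi, n_i).astype(float)
    return g, i
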