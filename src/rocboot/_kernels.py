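"""Array-based statistic evaluators.

These compute the same quantities as the public distribution-based operations
in :mod:`rocboot.roc_metrics`, but directly from raw genuine/impostor score
arrays with O(n log n) sorting-based counting, avoiding the construction of a
:class:`~rocboot.score_data.DiscreteScoreDistribution` object per bootstrap
iteration. Equality of the two routes is asserted by the test suite.
"""

from __future__ import annotations

import numpy as np


def tar_at_far(g: np.ndarray, i: np.ndarray, f: float) -> float:
    """TAR at FAR = f with proportional division of genuine ties.

    The threshold t is the score at which the impostor top-down cumulative
    crosses f (FAR just above f at t, just below f past t); the genuine mass
    tied at t is split linearly so the operating point sits exactly on the
    trapezoidal ROC polyline at FAR = f.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"FAR must lie strictly inside (0, 1), got {f!r}")
    n_i = i.size
    # t = j-th largest impostor score, j = ceil(f * N_I): the unique support
    # value with C_I(t) >= f and C_I(next(t)) < f (impostor mass at t > 0).
    j = max(int(np.ceil(f * n_i - 1e-12)), 1)
    t = np.partition(i, n_i - j)[n_i - j]
    ci_t = np.count_nonzero(i >= t) / n_i
    ci_next = np.count_nonzero(i > t) / n_i
    pi_t = ci_t - ci_next
    cg_next = np.count_nonzero(g > t) / g.size
    pg_t = np.count_nonzero(g == t) / g.size
    return cg_next + pg_t * (f - ci_next) / pi_t


def rates_at_threshold(g: np.ndarray, i: np.ndarray, t: float) -> tuple[float, float]:
    """(TAR, FAR) at a real threshold t, cumulated from the top down.

    The acceptance region is every observed score >= t, i.e. probabilities are
    cumulated down to the smallest support value at or above t (ceiling rule);
    a threshold above every observed score yields (0, 0).
    """
    tar = np.count_nonzero(g >= t) / g.size
    far = np.count_nonzero(i >= t) / i.size
    return float(tar), float(far)


def eer_candidates(
    support: np.ndarray, er1: np.ndarray, er2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Candidate operating points for the EER search.

    ``er1``/``er2`` are the type I and type II error rates evaluated at the
    observed support values (type I with the next-larger-value offset). The
    candidate list interleaves the support points with "gap" thresholds lying
    strictly between adjacent support values, where the type I rate of the
    lower value meets the type II rate of the upper one:

    * integer-valued supports admit a gap threshold only when at least one
      unobserved integer score lies between the neighbours (lattice
      semantics: the gap spans [s_k + 1, s_{k+1} - 1]);
    * non-integral supports are treated as continuous score systems, where a
      threshold between any two adjacent observed values is legitimate (the
      gap is reported as bracketed by the two observed values).

    Returns (cand_er1, cand_er2, span_lo, span_hi, integral), candidates
    ordered by score position so both error rates remain monotone.
    """
    integral = bool(np.all(support == np.floor(support)))
    n = support.size
    if n == 1:
        return er1, er2, support, support, integral
    if integral:
        gap_idx = np.flatnonzero(np.diff(support) > 1.5)
        gap_lo = support[gap_idx] + 1.0
        gap_hi = support[gap_idx + 1] - 1.0
    else:
        gap_idx = np.arange(n - 1)
        gap_lo = support[:-1]
        gap_hi = support[1:]
    # interleave support points with gap candidates by score position:
    # point k sits at key 2k, the gap after it at key 2k + 1
    keys = np.concatenate([2 * np.arange(n), 2 * gap_idx + 1])
    order = np.argsort(keys, kind="stable")
    c_er1 = np.concatenate([er1, er1[gap_idx]])[order]
    c_er2 = np.concatenate([er2, er2[gap_idx + 1]])[order]
    c_lo = np.concatenate([support, gap_lo])[order]
    c_hi = np.concatenate([support, gap_hi])[order]
    return c_er1, c_er2, c_lo, c_hi, integral


def eer_from_rates(
    support: np.ndarray,
    er1: np.ndarray,
    er2: np.ndarray,
    tol: float = 1e-12,
) -> tuple[float, float, float, float, float]:
    """EER search over the candidate operating points.

    Returns ``(eer, s1, s2, threshold, min_absdiff)``. The absolute
    difference of the two monotone step functions attains its minimum on a
    contiguous run of candidates; [s1, s2] spans that run, the EER averages
    the error-rate midpoints at the run's two ends, and the threshold is the
    floor of (s1 + s2) / 2 — to an integer for lattice supports, to the next
    lower observed value for continuous ones.
    """
    c_er1, c_er2, c_lo, c_hi, integral = eer_candidates(support, er1, er2)
    absdiff = np.abs(c_er1 - c_er2)
    m = float(absdiff.min())
    if m <= tol:  # float-noise floor: the gap genuinely closes
        m = 0.0
    idx = np.flatnonzero(absdiff <= m + tol)
    if np.any(np.diff(idx) != 1):  # pragma: no cover - monotone steps forbid this
        raise AssertionError("minimizing score range is not contiguous")
    first, last = idx[0], idx[-1]
    mid_first = (c_er1[first] + c_er2[first]) / 2.0
    mid_last = (c_er1[last] + c_er2[last]) / 2.0
    eer_value = float(np.clip((mid_first + mid_last) / 2.0, 0.0, 1.0))
    s1 = float(c_lo[first])
    s2 = float(c_hi[last])
    mid = (s1 + s2) / 2.0
    if integral:
        threshold = float(np.floor(mid))
    else:
        threshold = float(support[np.searchsorted(support, mid, side="right") - 1])
    return eer_value, s1, s2, threshold, m


def eer(
    g: np.ndarray, i: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Equal error rate of the discrete empirical distributions.

    Returns ``(eer, s1, s2, threshold, min_absdiff)``; see
    :func:`eer_from_rates` for the search semantics. The error rates are
    built from exact integer counts: type I error 1 - C_G(next(s)) =
    #{g <= s}/N_G, type II error C_I(s) = #{i >= s}/N_I.
    """
    g_sorted = np.sort(g)
    i_sorted = np.sort(i)
    support = np.unique(np.concatenate([g_sorted, i_sorted]))
    er1 = np.searchsorted(g_sorted, support, side="right") / g.size
    er2 = (i.size - np.searchsorted(i_sorted, support, side="left")) / i.size
    return eer_from_rates(support, er1, er2)


def aurc(g: np.ndarray, i: np.ndarray) -> float:
    """Area under the trapezoidal ROC curve = Mann-Whitney statistic.

    (1/(N_G N_I)) * sum over pairs of [1(g > i) + 0.5 * 1(g = i)], computed by
    cumulative counting (searchsorted) rather than materializing the pairs.
    """
    i_sorted = np.sort(i)
    below = np.searchsorted(i_sorted, g, side="left")
    below_or_tied = np.searchsorted(i_sorted, g, side="right")
    return float((below + below_or_tied).sum() / (2.0 * g.size * i.size))


def weighted_cost(
    g: np.ndarray, i: np.ndarray, t: float, w1: float, w2: float
) -> float:
    """Weighted sum of type I and type II error probabilities at threshold t."""
    tar, far = rates_at_threshold(g, i, t)
    return w1 * (1.0 - tar) + w2 * far
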