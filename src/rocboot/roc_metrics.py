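"""Point estimates in operational ROC analysis.

Three operating-point scenarios are covered, each with explicit handling of
the ties that discrete score distributions produce:

1. TAR at a specified FAR ``f`` — the threshold is the support value where the
   impostor cumulative crosses ``f``, and the genuine mass tied at that
   threshold is divided proportionally (trapezoidal rule), so the estimate
   lies exactly on the empirical ROC polyline.
2. TAR and FAR at a given real threshold ``t`` — probabilities are cumulated
   from the top score down to the smallest support value at or above ``t``.
3. The equal error rate (EER) — the midpoint of the type I and type II error
   rates over the score range minimizing their absolute difference, together
   with the *systematic error* that score discreteness induces.

The area under the ROC curve (AURC, the Mann-Whitney statistic with
half-weight ties), a weighted two-error cost, and the FNMR = 1 - TAR
transform complete the metric set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .score_data import DiscreteScoreDistribution, ScoreSample

__all__ = [
    "RocCurve",
    "TarAtFarResult",
    "ThresholdRates",
    "EerResult",
    "roc_curve",
    "tar_at_far",
    "rates_at_threshold",
    "eer",
    "aurc",
    "weighted_cost",
]


@dataclass(frozen=True)
class RocCurve:
    """The empirical ROC polyline.

    ``points`` holds (FAR, TAR) = (C_I(s), C_G(s)) for s from s_max down to
    s_min, prepended with the origin (0, 0); the final point is (1, 1).
    Consecutive duplicate points occur where neither class has mass.
    """

    points: np.ndarray

    @property
    def far(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tar(self) -> np.ndarray:
        return self.points[:, 1]

    def area(self) -> float:
        """Trapezoidal area under the polyline (equals the AURC)."""
        return float(np.trapezoid(self.tar, self.far))


@dataclass(frozen=True)
class TarAtFarResult:
    f: float
    threshold: float
    tar: float


@dataclass(frozen=True)
class ThresholdRates:
    t_input: float
    s: float  # smallest support value >= t_input (inf when above s_max)
    tar: float
    far: float


@dataclass(frozen=True)
class EerResult:
    """EER with its minimizing score range and discreteness diagnostics.

    ``min_absdiff`` is the smallest attainable |type I - type II| gap;
    ``systematic_error`` = (min_absdiff / 2) / eer is the relative error that
    the discreteness of the score distributions contributes on top of the
    statistical (sampling) error, and is 0 when the gap closes exactly.
    """

    eer: float
    s1: float
    s2: float
    threshold: float
    min_absdiff: float
    systematic_error: float


def roc_curve(dist: DiscreteScoreDistribution) -> RocCurve:
    """Build the empirical ROC polyline from the discrete distributions."""
    far = np.concatenate([[0.0], dist.c_impostor[::-1]])
    tar = np.concatenate([[0.0], dist.c_genuine[::-1]])
    return RocCurve(np.column_stack([far, tar]))


def tar_at_far(dist: DiscreteScoreDistribution, f: float) -> TarAtFarResult:
    """TAR at FAR = f (Scenario 1), dividing genuine ties proportionally.

    The threshold t is the largest support value with C_I(t) >= f (so that
    C_I(next(t)) < f); such t always exists for f in (0, 1) and carries
    positive impostor mass. The estimate interpolates linearly between the ROC
    vertices at t and next(t).
    """
    if not 0.0 < f < 1.0:
        raise ValueError(
            f"FAR must lie strictly inside (0, 1) for the threshold crossing "
            f"to exist, got {f!r}"
        )
    ci = dist.c_impostor
    t_idx = int(np.flatnonzero(ci >= f)[-1])
    ci_next = ci[t_idx + 1] if t_idx + 1 < ci.size else 0.0
    cg_next = dist.c_genuine[t_idx + 1] if t_idx + 1 < ci.size else 0.0
    pi_t = ci[t_idx] - ci_next
    pg_t = dist.p_genuine[t_idx]
    tar = cg_next + pg_t * (f - ci_next) / pi_t
    return TarAtFarResult(f=f, threshold=float(dist.support[t_idx]), tar=float(tar))


def rates_at_threshold(dist: DiscreteScoreDistribution, t_input: float) -> ThresholdRates:
    """TAR and FAR at a real threshold (Scenario 2), ceiling rule.

    The threshold need not be an observed score: probabilities are cumulated
    from the top down to the smallest support value s >= t_input. Above s_max
    both rates are 0; at or below s_min both are 1.
    """
    idx = int(np.searchsorted(dist.support, t_input, side="left"))
    if idx == dist.support.size:
        return ThresholdRates(t_input=t_input, s=float("inf"), tar=0.0, far=0.0)
    return ThresholdRates(
        t_input=t_input,
        s=float(dist.support[idx]),
        tar=float(dist.c_genuine[idx]),
        far=float(dist.c_impostor[idx]),
    )


def eer(dist: DiscreteScoreDistribution) -> EerResult:
    """Equal error rate (Scenario 3) with systematic-error diagnostic.

    Evaluates the type I error 1 - C_G(next(s)) and type II error C_I(s) at
    every support value s (with the cumulative past s_max taken as 0), plus
    the thresholds lying in gaps between adjacent support values (for an
    integer score system, the unobserved lattice scores; for a continuous
    one, any point between two observed scores). The type I rate is
    non-decreasing and the type II rate non-increasing along that sweep, so
    their absolute difference attains its minimum on a contiguous range
    [s1, s2]; the EER is the midpoint of the two error rates there, and the
    threshold the floor of (s1 + s2) / 2.
    """
    cg_next = np.concatenate([dist.c_genuine[1:], [0.0]])
    er_type1 = 1.0 - cg_next
    er_type2 = dist.c_impostor
    eer_value, s1, s2, threshold, min_absdiff = _kernels.eer_from_rates(
        dist.support, er_type1, er_type2
    )
    systematic = (min_absdiff / 2.0) / eer_value if eer_value > 0 else 0.0
    return EerResult(
        eer=eer_value,
        s1=s1,
        s2=s2,
        threshold=threshold,
        min_absdiff=min_absdiff,
        systematic_error=systematic,
    )


def aurc(sample: ScoreSample) -> float:
    """Area under the trapezoidal ROC curve (Mann-Whitney statistic).

    Equals the probability that a random genuine score exceeds a random
    impostor score, ties counted with weight 1/2; computed by cumulative
    counting without materializing the N_G x N_I pairs.
    """
    return _kernels.aurc(sample.genuine, sample.impostor)


def weighted_cost(
    dist: DiscreteScoreDistribution, t_input: float, w1: float, w2: float
) -> float:
    """w1 * (type I error) + w2 * (type II error) at the given threshold."""
    if w1 < 0 or w2 < 0:
        raise ValueError(f"weights must be non-negative, got w1={w1!r}, w2={w2!r}")
    rates = rates_at_threshold(dist, t_input)
    return w1 * (1.0 - rates.tar) + w2 * rates.far
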