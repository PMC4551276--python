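"""Bootstrap-variability study: how many replications are enough?

Bootstrap estimates carry resampling variability on top of sampling
variability: repeating an entire B-replication bootstrap gives a different SE
and different CI bounds each time. This module quantifies that spread by
running the two-sample bootstrap L times per candidate replication count B
and reporting the coefficient of variation (CV = SD / mean) of

* the L standard errors,
* the L percentile-CI lower bounds, and
* the L percentile-CI upper bounds.

The CV of the SE decreases as B grows; B is chosen as the smallest count
whose CV falls below a user-chosen tolerance (0.02 is a common choice for the
SE; the CI-bound CVs are far smaller whenever the bounds sit near 1, because
the mean in the denominator is then close to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .resampling import StatisticSpec, bootstrap, summarize_bootstrap, point_estimate
from .score_data import ScoreSample

__all__ = ["VariabilityCell", "VariabilityResult", "coefficient_of_variation", "variability_study"]


def coefficient_of_variation(values: np.ndarray) -> float:
    """SD / mean of a sequence (sample variance, divisor n - 1).

    Undefined for mean zero; raises rather than returning an infinity.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values for a coefficient of variation")
    mean = arr.mean()
    if mean == 0.0:
        raise ValueError("coefficient of variation undefined: mean of values is zero")
    return float(np.std(arr, ddof=1) / mean)


def _cv_or_nan(values: np.ndarray) -> float:
    try:
        return coefficient_of_variation(values)
    except ValueError:
        return float("nan")


@dataclass(frozen=True)
class VariabilityCell:
    """One (B, L) cell of the study: the three L-sized sets and their CVs.

    A CV is NaN when its set has zero mean (e.g. every bootstrap SE is 0 for
    a degenerate sample), in which case the quantity is not computable.
    """

    B: int
    L: int
    ses: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    cv_se: float
    cv_lb: float
    cv_ub: float

    def as_fnmr(self) -> "VariabilityCell":
        """The same study cell for FNMR = 1 - TAR (for TAR-type statistics).

        SEs are unchanged; the bound sets swap and reflect around 1, so the
        bound CVs change substantially — FNMR bounds sit near 0 where TAR
        bounds sit near 1 — while CV_SE is identical. Derived by transform
        rather than a second Monte Carlo study.
        """
        lbs = 1.0 - self.upper_bounds
        ubs = 1.0 - self.lower_bounds
        return VariabilityCell(
            B=self.B, L=self.L, ses=self.ses, lower_bounds=lbs, upper_bounds=ubs,
            cv_se=self.cv_se, cv_lb=_cv_or_nan(lbs), cv_ub=_cv_or_nan(ubs),
        )


@dataclass(frozen=True)
class VariabilityResult:
    cells: tuple[VariabilityCell, ...]
    spec: StatisticSpec
    alpha: float
    seed: int | None

    def cell(self, B: int) -> VariabilityCell:
        for c in self.cells:
            if c.B == B:
                return c
        raise KeyError(f"no study cell for B={B}")

    def as_rows(self) -> list[tuple[int, float, float, float]]:
        """(B, CV_SE, CV_LB, CV_UB) rows for tabular export."""
        return [(c.B, c.cv_se, c.cv_lb, c.cv_ub) for c in self.cells]


def variability_study(
    sample: ScoreSample,
    spec: StatisticSpec,
    B_list: tuple[int, ...] = (200, 400, 600, 800, 1000, 1200, 1400, 1600, 1800, 2000),
    L: int = 500,
    alpha: float = 0.05,
    seed: int | None = None,
    component: int | str = 0,
) -> VariabilityResult:
    """Run L independent bootstraps per B and summarize their spread.

    The study seed is expanded into one independent RNG substream per (B, i)
    cell iteration, so any individual bootstrap pass can be reproduced in
    isolation and the loops could run in any order (they are embarrassingly
    parallel). The CI bounds entering the CVs are the percentile (quantile
    definition 2) bounds, matching the bootstrap summary.
    """
    if L < 2:
        raise ValueError(f"L must be at least 2, got {L}")
    comp_idx = component if isinstance(component, int) else spec.components.index(component)
    point = point_estimate(sample, spec)[comp_idx]
    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(len(B_list) * L))
    cells = []
    for B in B_list:
        ses = np.empty(L)
        lbs = np.empty(L)
        ubs = np.empty(L)
        for i in range(L):
            boot = bootstrap(sample, spec, B=B, seed=next(streams))
            summary = summarize_bootstrap(boot, point, alpha=alpha, component=component)
            ses[i] = summary.se
            lbs[i], ubs[i] = summary.ci_quantile
        cells.append(
            VariabilityCell(
                B=B,
                L=L,
                ses=ses,
                lower_bounds=lbs,
                upper_bounds=ubs,
                cv_se=_cv_or_nan(ses),
                cv_lb=_cv_or_nan(lbs),
                cv_ub=_cv_or_nan(ubs),
            )
        )
    return VariabilityResult(cells=tuple(cells), spec=spec, alpha=alpha, seed=seed)
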