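"""Significance tests for operational ROC metrics.

Bootstrap replications of verification statistics (TAR at a fixed FAR, EER,
AURC, ...) are close to normally distributed, so evaluation and comparison
reduce to two-tailed Z-tests:

* one algorithm against a hypothesized criterion value mu0:
  Z = (T - mu0) / SE(T);
* two algorithms against each other, with the correlation r between the two
  estimates absorbed into the denominator:
  Z = (T1 - T2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2).

Ignoring a positive correlation inflates the denominator and can mask a real
difference, so r is estimated explicitly by *synchronized* resampling: when
two algorithms scored the same comparisons, the score with ordinal position j
in A's list co-varies with position j in B's, and drawing one index vector
per class and applying it to both lists preserves that coupling. The Pearson
correlation of the two resulting replication sequences, averaged over several
independent runs, estimates r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .resampling import StatisticSpec
from .score_data import PairedScoreSample

__all__ = [
    "TestResult",
    "CorrelationResult",
    "one_algorithm_test",
    "two_algorithm_test",
    "synchronized_correlation",
]


@dataclass(frozen=True)
class TestResult:
    """A two-tailed Z-test outcome with its inputs echoed."""

    z: float
    p_two_tailed: float
    estimates: tuple[float, ...]
    ses: tuple[float, ...]
    mu0: float | None = None
    r: float | None = None
    direction: str = ""

    @property
    def significant_05(self) -> bool:
        return self.p_two_tailed < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_two_tailed < 0.01


def _two_tailed_p(z: float) -> float:
    # survival function of the standard normal; accurate far into the tail
    return float(2.0 * _sps.norm.sf(abs(z)))


def _verdict_one(diff: float, p: float, larger_is_better: bool | None) -> str:
    if larger_is_better is None:
        return ""
    if p >= 0.05:
        return "difference from the criterion value is not significant at the 5 % level"
    better = (diff > 0) == larger_is_better
    return (
        "estimate is significantly {} than the criterion value".format(
            "better" if better else "worse"
        )
    )


def _verdict_two(diff: float, p: float, larger_is_better: bool | None) -> str:
    if larger_is_better is None:
        return ""
    if p >= 0.05:
        return "difference between the two algorithms is not significant at the 5 % level"
    first_better = (diff > 0) == larger_is_better
    return "algorithm {} performs significantly better".format("1" if first_better else "2")


def one_algorithm_test(
    T_hat: float,
    mu0: float,
    se: float,
    larger_is_better: bool | None = None,
) -> TestResult:
    """Two-tailed Z-test of H0: T = mu0 for a single algorithm.

    ``larger_is_better`` states the metric's orientation (True for TAR/AURC,
    False for EER/FNMR/cost) and only affects the verdict text; it is never
    inferred from the metric itself.
    """
    if se <= 0:
        raise ValueError(f"SE must be positive, got {se!r}")
    z = (T_hat - mu0) / se
    p = _two_tailed_p(z)
    return TestResult(
        z=float(z),
        p_two_tailed=p,
        estimates=(float(T_hat),),
        ses=(float(se),),
        mu0=float(mu0),
        direction=_verdict_one(T_hat - mu0, p, larger_is_better),
    )


def two_algorithm_test(
    T1: float,
    T2: float,
    se1: float,
    se2: float,
    r: float = 0.0,
    larger_is_better: bool | None = None,
) -> TestResult:
    """Two-tailed correlated Z-test of H0: T1 = T2.

    With r = 0 this reduces to the unpaired two-sample Z-test. The radicand
    se1^2 + se2^2 - 2 r se1 se2 degenerates to 0 only when r -> 1 with equal
    SEs (the two estimates are then almost surely identical and no test is
    possible); that case raises.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError(f"SEs must be positive, got se1={se1!r}, se2={se2!r}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r!r}")
    radicand = se1**2 + se2**2 - 2.0 * r * se1 * se2
    if radicand <= 0:
        raise ValueError(
            "degenerate test: se1^2 + se2^2 - 2 r se1 se2 is not positive "
            f"(r={r!r} with se1={se1!r}, se2={se2!r}); the two estimates are "
            "perfectly coupled and their difference has no sampling variance"
        )
    z = (T1 - T2) / np.sqrt(radicand)
    p = _two_tailed_p(z)
    return TestResult(
        z=float(z),
        p_two_tailed=p,
        estimates=(float(T1), float(T2)),
        ses=(float(se1), float(se2)),
        r=float(r),
        direction=_verdict_two(T1 - T2, p, larger_is_better),
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Synchronized-resampling correlation between two algorithms' statistics.

    ``per_run`` holds one Pearson correlation per independent run (NaN when a
    run's replication sequence had zero variance); ``r_mean`` averages the
    defined runs.
    """

    r_mean: float
    per_run: np.ndarray
    M: int
    runs: int
    seed: int | None
    spec: StatisticSpec

    @property
    def n_degenerate_runs(self) -> int:
        return int(np.count_nonzero(np.isnan(self.per_run)))


def synchronized_correlation(
    paired: PairedScoreSample,
    spec: StatisticSpec,
    M: int = 2000,
    runs: int = 10,
    seed: int | None = None,
    component: int | str = 0,
) -> CorrelationResult:
    """Estimate the correlation r between two algorithms' statistics.

    Per iteration one genuine index vector (length N_G) and one impostor index
    vector (length N_I) are drawn with replacement and applied to *both*
    algorithms' score lists, so co-varying scores are selected together. The
    statistic is evaluated per algorithm, giving M paired replications per
    run; the per-run Pearson correlation is averaged over ``runs`` independent
    runs to damp Monte Carlo fluctuation.
    """
    if M < 2:
        raise ValueError(f"M must be at least 2, got {M}")
    if runs < 1:
        raise ValueError(f"runs must be at least 1, got {runs}")
    comp_idx = component if isinstance(component, int) else spec.components.index(component)
    g_a, i_a = paired.sample_a.genuine, paired.sample_a.impostor
    g_b, i_b = paired.sample_b.genuine, paired.sample_b.impostor
    n_g, n_i = paired.n_genuine, paired.n_impostor
    run_streams = np.random.SeedSequence(seed).spawn(runs)
    per_run = np.empty(runs)
    for run, stream in enumerate(run_streams):
        rng = np.random.default_rng(stream)
        t_a = np.empty(M)
        t_b = np.empty(M)
        for m in range(M):
            g_idx = rng.integers(0, n_g, n_g)
            i_idx = rng.integers(0, n_i, n_i)
            t_a[m] = spec.evaluate(g_a[g_idx], i_a[i_idx])[comp_idx]
            t_b[m] = spec.evaluate(g_b[g_idx], i_b[i_idx])[comp_idx]
        if np.ptp(t_a) == 0.0 or np.ptp(t_b) == 0.0:
            per_run[run] = np.nan  # zero-variance sequence: correlation undefined
        else:
            per_run[run] = np.corrcoef(t_a, t_b)[0, 1]
    defined = per_run[~np.isnan(per_run)]
    r_mean = float(defined.mean()) if defined.size else float("nan")
    return CorrelationResult(
        r_mean=r_mean, per_run=per_run, M=M, runs=runs, seed=seed, spec=spec
    )
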