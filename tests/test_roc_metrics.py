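import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rocboot as rb
from rocboot import _kernels

import oracles


class TestRocCurve:
    def test_toy_curve_contains_expected_vertices(self, toy_dist):
        pts = rb.roc_curve(toy_dist).points
        assert any(np.allclose(p, [1 / 6, 1 / 2]) for p in pts)
        assert any(np.allclose(p, [1 / 2, 3 / 4]) for p in pts)
        assert np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])

    def test_monotone_coordinates(self, toy_dist):
        pts = rb.roc_curve(toy_dist).points
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)

    def test_identical_classes_lie_on_diagonal(self):
        sample = rb.ScoreSample([1, 2, 3], [1, 2, 3])
        pts = rb.roc_curve(rb.build_distributions(sample)).points
        assert np.allclose(pts[:, 0], pts[:, 1])

    def test_single_support_value_degenerates_to_diagonal(self):
        pts = rb.roc_curve(rb.build_distributions(rb.ScoreSample([2], [2]))).points
        assert np.allclose(pts, [[0, 0], [1, 1]])


class TestTarAtFar:
    def test_toy_interpolated_value(self, toy_dist):
        res = rb.tar_at_far(toy_dist, 0.25)
        assert res.threshold == 2.0
        assert res.tar == pytest.approx(0.5625, abs=1e-15)

    def test_vertex_far_returns_vertex_tar(self, toy_dist):
        # at an achievable FAR vertex the tie division collapses
        assert rb.tar_at_far(toy_dist, 1 / 6).tar == pytest.approx(0.5)
        assert rb.tar_at_far(toy_dist, 0.5).tar == pytest.approx(0.75)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.5])
    def test_far_outside_open_interval_rejected(self, toy_dist, f):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            rb.tar_at_far(toy_dist, f)

    def test_monotone_in_f(self, toy_dist):
        fs = np.linspace(0.01, 0.99, 37)
        tars = [rb.tar_at_far(toy_dist, f).tar for f in fs]
        assert np.all(np.diff(tars) >= -1e-15)


class TestRatesAtThreshold:
    def test_toy_ceiling_rule(self, toy_dist):
        res = rb.rates_at_threshold(toy_dist, 1.5)
        assert (res.s, res.tar, res.far) == (2.0, 0.75, 0.5)

    def test_threshold_at_top_score(self, toy_dist):
        res = rb.rates_at_threshold(toy_dist, 3.0)
        assert res.tar == pytest.approx(0.5) and res.far == pytest.approx(1 / 6)

    def test_threshold_above_support_gives_zero_rates(self, toy_dist):
        res = rb.rates_at_threshold(toy_dist, 99.0)
        assert res.tar == 0.0 and res.far == 0.0

    def test_threshold_at_or_below_minimum_gives_unit_rates(self, toy_dist):
        assert rb.rates_at_threshold(toy_dist, -5.0).tar == 1.0
        assert rb.rates_at_threshold(toy_dist, 0.0).far == 1.0


class TestEer:
    def test_separating_gap_gives_zero(self):
        dist = rb.build_distributions(rb.ScoreSample([3, 3], [1, 1]))
        res = rb.eer(dist)
        assert res.eer == 0.0
        assert res.min_absdiff == 0.0
        assert res.systematic_error == 0.0

    def test_range_minimum_with_midpoint_and_floor_threshold(self):
        dist = rb.build_distributions(rb.ScoreSample([3, 2, 2, 1], [2, 1, 1, 0]))
        res = rb.eer(dist)
        assert res.eer == pytest.approx(0.5)
        assert (res.s1, res.s2) == (1.0, 2.0)
        assert res.threshold == 1.0
        assert res.min_absdiff == pytest.approx(0.5)
        assert res.systematic_error == pytest.approx(0.25 / 0.5)

    def test_eer_bounded_by_error_rate_envelopes(self, toy_dist):
        res = rb.eer(toy_dist)
        assert 0.0 <= res.eer <= 1.0
        assert res.s1 <= res.threshold <= res.s2


class TestAurc:
    def test_toy_pair_count(self, toy_sample):
        assert rb.aurc(toy_sample) == pytest.approx(17 / 24, abs=1e-15)

    def test_identical_classes_give_half(self):
        assert rb.aurc(rb.ScoreSample([1, 2, 3], [1, 2, 3])) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        assert rb.aurc(rb.ScoreSample([5, 6], [1, 2, 3])) == 1.0

    def test_equals_trapezoidal_area(self, toy_sample, toy_dist):
        area = rb.roc_curve(toy_dist).area()
        assert rb.aurc(toy_sample) == pytest.approx(area, abs=1e-12)


class TestWeightedCost:
    def test_reductions(self, toy_dist):
        # w2=0 leaves the false-non-match rate, w1=0 leaves the FAR
        assert rb.weighted_cost(toy_dist, 1.5, 1, 0) == pytest.approx(0.25)
        assert rb.weighted_cost(toy_dist, 1.5, 0, 1) == pytest.approx(0.5)
        assert rb.weighted_cost(toy_dist, 1.5, 1, 1) == pytest.approx(0.75)

    def test_negative_weight_rejected(self, toy_dist):
        with pytest.raises(ValueError, match="non-negative"):
            rb.weighted_cost(toy_dist, 1.5, -1, 1)


@settings(derandomize=True, max_examples=50)
@given(
    g=st.lists(st.integers(0, 6), min_size=1, max_size=25),
    i=st.lists(st.integers(0, 6), min_size=1, max_size=25),
)
def test_aurc_always_matches_trapezoid(g, i):
    sample = rb.ScoreSample(g, i)
    area = rb.roc_curve(rb.build_distributions(sample)).area()
    assert rb.aurc(sample) == pytest.approx(area, abs=1e-12)


def test_kernel_route_matches_distribution_route(rng):
    """The array kernels used inside the bootstrap loops agree with the
    public distribution-based operations on random tied samples."""
    for _ in range(50):
        g, i = oracles.random_tied_sample(rng)
        sample = rb.ScoreSample(g, i)
        dist = rb.build_distributions(sample)
        f = float(rng.uniform(0.02, 0.98))
        t = float(rng.uniform(-1, 12))
        assert _kernels.tar_at_far(g, i, f) == pytest.approx(
            rb.tar_at_far(dist, f).tar, abs=1e-12)
        rates = rb.rates_at_threshold(dist, t)
        assert _kernels.rates_at_threshold(g, i, t) == pytest.approx(
            (rates.tar, rates.far), abs=1e-15)
        k_eer = _kernels.eer(g, i)
        d_eer = rb.eer(dist)
        assert k_eer[0] == pytest.approx(d_eer.eer, abs=1e-12)
        assert k_eer[1:4] == (d_eer.s1, d_eer.s2, d_eer.threshold)
        assert k_eer[4] == pytest.approx(d_eer.min_absdiff, abs=1e-12)


def test_fnmr_transform_swaps_and_reflects_bounds():
    summary = rb.UncertaintySummary(
        point_estimate=0.993255, se=0.000325,
        ci_quantile=(0.992622, 0.993922), ci_normal=(0.992618, 0.993892),
        alpha=0.05, B=2000,
    )
    fnmr = summary.as_fnmr()
    assert fnmr.point_estimate == pytest.approx(1 - 0.993255)
    assert fnmr.se == summary.se
    assert fnmr.ci_quantile == (pytest.approx(1 - 0.993922), pytest.approx(1 - 0.992622))
    assert fnmr.ci_normal == (pytest.approx(1 - 0.993892), pytest.approx(1 - 0.992618))
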