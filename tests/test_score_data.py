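import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rocboot as rb
from rocboot.score_data import load_scores, load_paired_scores, load_scores_split


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadScores:
    def test_labelled_file_parses_with_counts_and_order(self, tmp_path):
        p = write(tmp_path, "s.csv", "genuine,3\ngenuine,3\ngenuine,2\ngenuine,1\n"
                  "impostor,3\nimpostor,2\nimpostor,2\nimpostor,1\nimpostor,1\nimpostor,0\n")
        sample = load_scores(p)
        assert sample.n_genuine == 4 and sample.n_impostor == 6
        assert list(sample.genuine) == [3, 3, 2, 1]  # file order preserved
        assert list(sample.impostor) == [3, 2, 2, 1, 1, 0]

    def test_tab_delimited_and_alternate_labels(self, tmp_path):
        p = write(tmp_path, "s.tsv", "g\t1.5\ni\t0.5\n")
        sample = load_scores(p)
        assert sample.n_genuine == 1 and sample.n_impostor == 1

    def test_non_numeric_score_names_the_row(self, tmp_path):
        p = write(tmp_path, "bad.csv", "genuine,1\nimpostor,abc\n")
        with pytest.raises(ValueError, match="row 2.*'abc'"):
            load_scores(p)

    def test_empty_impostor_section_rejected(self, tmp_path):
        p = write(tmp_path, "g_only.csv", "genuine,1\ngenuine,2\n")
        with pytest.raises(ValueError, match="impostor set empty"):
            load_scores(p)

    def test_unknown_label_rejected(self, tmp_path):
        p = write(tmp_path, "s.csv", "genuine,1\nwhatever,2\n")
        with pytest.raises(ValueError, match="row 2"):
            load_scores(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ValueError, match="cannot read"):
            load_scores(tmp_path / "nope.csv")

    def test_split_single_column_files(self, tmp_path):
        g = write(tmp_path, "g.txt", "3\n3\n2\n1\n")
        i = write(tmp_path, "i.txt", "3\n2\n2\n1\n1\n0\n")
        sample = load_scores_split(g, i)
        assert sample.n_genuine == 4 and sample.n_impostor == 6


class TestPaired:
    def test_matching_sizes_pair_up(self, tmp_path):
        text = "genuine,1\ngenuine,2\nimpostor,0\n"
        a = write(tmp_path, "a.csv", text)
        b = write(tmp_path, "b.csv", "genuine,3\ngenuine,4\nimpostor,1\n")
        paired = load_paired_scores(a, b)
        assert paired.n_genuine == 2 and paired.n_impostor == 1

    def test_size_mismatch_reports_both_counts(self, tmp_path):
        a = write(tmp_path, "a.csv", "genuine,1\ngenuine,2\nimpostor,0\n")
        b = write(tmp_path, "b.csv", "genuine,1\nimpostor,0\n")
        with pytest.raises(ValueError, match="A has 2, B has 1"):
            load_paired_scores(a, b)

    def test_identical_files_give_equal_samples(self, tmp_path):
        a = write(tmp_path, "a.csv", "genuine,1\nimpostor,0\n")
        paired = load_paired_scores(a, a)
        assert paired.sample_a == paired.sample_b


class TestScoreSampleValidation:
    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="genuine set empty"):
            rb.ScoreSample([], [1.0])

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError, match="not finite"):
            rb.ScoreSample([1.0, bad], [0.0])


class TestBuildDistributions:
    def test_toy_probabilities_and_cumulatives(self, toy_dist):
        assert list(toy_dist.support) == [0, 1, 2, 3]
        assert np.allclose(toy_dist.p_genuine, [0, 0.25, 0.25, 0.5])
        assert np.allclose(toy_dist.c_genuine, [1, 1, 0.75, 0.5])
        assert np.allclose(toy_dist.c_impostor, [1, 5 / 6, 0.5, 1 / 6])

    def test_point_mass(self):
        dist = rb.build_distributions(rb.ScoreSample([5.0, 5.0], [1.0]))
        idx = list(dist.support).index(5.0)
        assert dist.p_genuine[idx] == 1.0 and dist.c_genuine[idx] == 1.0

    def test_decimal_rescaling_merges_close_scores(self):
        sample = rb.ScoreSample([0.514, 0.51], [0.1])
        dist = rb.build_distributions(sample, decimals=2)
        assert 0.51 in dist.support and dist.support.size == 2
        assert dist.p_genuine[list(dist.support).index(0.51)] == 1.0

    def test_negative_decimals_rejected(self, toy_sample):
        with pytest.raises(ValueError, match="decimals"):
            rb.build_distributions(toy_sample, decimals=-1)

    def test_counts_recoverable_from_probabilities(self, toy_sample, toy_dist):
        # P * N recovers the multiset of discretized scores
        g_counts = np.round(toy_dist.p_genuine * toy_sample.n_genuine).astype(int)
        rebuilt = np.repeat(toy_dist.support, g_counts)
        assert sorted(rebuilt) == sorted(toy_sample.genuine)

    def test_order_invariance(self, rng):
        g = rng.integers(0, 10, 40).astype(float)
        i = rng.integers(0, 10, 60).astype(float)
        d1 = rb.build_distributions(rb.ScoreSample(g, i))
        perm_g, perm_i = rng.permutation(g), rng.permutation(i)
        d2 = rb.build_distributions(rb.ScoreSample(perm_g, perm_i))
        assert np.array_equal(d1.support, d2.support)
        assert np.array_equal(d1.p_genuine, d2.p_genuine)
        assert np.array_equal(d1.c_impostor, d2.c_impostor)


@settings(derandomize=True, max_examples=60)
@given(
    g=st.lists(st.integers(0, 8), min_size=1, max_size=30),
    i=st.lists(st.integers(0, 8), min_size=1, max_size=30),
)
def test_distribution_invariants(g, i):
    """Probabilities sum to 1, cumulatives start at 1, are non-increasing,
    and difference back to the probabilities."""
    dist = rb.build_distributions(rb.ScoreSample(g, i))
    for p, c in ((dist.p_genuine, dist.c_genuine), (dist.p_impostor, dist.c_impostor)):
        assert abs(p.sum() - 1.0) < 1e-12
        assert c[0] == 1.0
        assert np.all(np.diff(c) <= 1e-15)
        c_next = np.concatenate([c[1:], [0.0]])
        assert np.allclose(c - c_next, p, atol=1e-12)
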