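import numpy as np
import pytest

import rocboot as rb


@pytest.fixture()
def toy_sample() -> rb.ScoreSample:
    """Small integer-score sample with ties in both classes."""
    return rb.ScoreSample([3, 3, 2, 1], [3, 2, 2, 1, 1, 0])


@pytest.fixture()
def toy_dist(toy_sample) -> rb.DiscreteScoreDistribution:
    return rb.build_distributions(toy_sample)


@pytest.fixture()
def labelled_toy_file(tmp_path, toy_sample):
    path = tmp_path / "toy.csv"
    lines = [f"genuine,{v:g}" for v in toy_sample.genuine]
    lines += [f"impostor,{v:g}" for v in toy_sample.impostor]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
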