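"""Generating synthetic score samples and writing them to disk.

The generator emulates the structural features of operational score data:
fixed-decimal discreteness (ties), a point-mass spike at the top genuine
score where a matcher saturates, and configurable class separation. Files
are written in the labelled CSV format the loaders read back.
"""

import tempfile
from pathlib import Path

import numpy as np

import rocboot as rb

params = rb.preset("high_accuracy", n_genuine=10000, n_impostor=20000, seed=33)
sample = rb.simulate_scores(params)

spike = params.spike_value
spike_freq = np.mean(sample.genuine == spike)
print(f"n_genuine={sample.n_genuine}, n_impostor={sample.n_impostor}")
print(f"top genuine score {spike:g} carries {spike_freq:.2%} of the genuine mass")
# the stand-alone peak at the maximum score, here ~9 % of the population

dist = rb.build_distributions(sample)
print(f"EER {rb.eer(dist).eer:.4f}, AURC {rb.aurc(sample):.6f}")

out = Path(tempfile.mkdtemp()) / "scores.csv"
with out.open("w") as fh:
    for v in sample.genuine:
        fh.write(f"genuine,{v:g}\n")
    for v in sample.impostor:
        fh.write(f"impostor,{v:g}\n")
back = rb.load_scores(out)
print(f"round-trip through {out.name}: {back.n_genuine} genuine, "
      f"{back.n_impostor} impostor scores")
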