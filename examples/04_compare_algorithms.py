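"""Comparing two algorithms with the correlated Z-test.

Two simulated matchers score the same comparisons (coupled through a latent
variable), so their EER estimates are positively correlated. The correlation
is estimated by synchronized resampling — the same index draw is applied to
both score lists — and folded into the two-algorithm Z-test. Ignoring it
would inflate the denominator and hide real differences.
"""

import rocboot as rb

strong = rb.preset("low_accuracy", n_genuine=4000, n_impostor=8000,
                   genuine_location=3.1)
weaker = rb.preset("low_accuracy", n_genuine=4000, n_impostor=8000,
                   genuine_location=2.9)
paired = rb.simulate_paired_algorithms(strong, weaker, latent_rho=0.7, seed=5)

spec = rb.StatisticSpec("eer")
t1 = rb.point_estimate(paired.sample_a, spec)[0]
t2 = rb.point_estimate(paired.sample_b, spec)[0]
se1 = rb.summarize_bootstrap(rb.bootstrap(paired.sample_a, spec, B=2000, seed=1), t1).se
se2 = rb.summarize_bootstrap(rb.bootstrap(paired.sample_b, spec, B=2000, seed=2), t2).se

corr = rb.synchronized_correlation(paired, spec, M=2000, runs=10, seed=3)
print(f"EER A: {t1:.6f} (SE {se1:.6f})   EER B: {t2:.6f} (SE {se2:.6f})")
print(f"synchronized correlation r = {corr.r_mean:.6f} (avg of {corr.runs} runs)")

test = rb.two_algorithm_test(t1, t2, se1, se2, r=corr.r_mean, larger_is_better=False)
print(f"with r    : Z = {test.z:+.4f}, two-tailed p = {test.p_two_tailed:.4f}")
naive = rb.two_algorithm_test(t1, t2, se1, se2, r=0.0, larger_is_better=False)
print(f"without r : Z = {naive.z:+.4f}, two-tailed p = {naive.p_two_tailed:.4f}")
print(test.direction)
# the correlation-adjusted p-value is smaller: accounting for the positive
# coupling sharpens the comparison
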