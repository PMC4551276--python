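# Methods

## Scope and data model

The package analyses verification scores: a genuine set **G** (size `N_G`)
and an impostor set **I** (size `N_I`), treated as i.i.d. draws from two
unknown discrete distributions. All estimates are empirical; no parametric
form is fitted anywhere. Scores are placed on a shared support — by default
every distinct observed value; optionally after rounding to `d` decimal
digits to mimic fixed-precision score systems — with per-class probabilities
`P_G`, `P_I` and top-down cumulatives `C_G`, `C_I` (fraction of scores at or
above each support value). Cumulatives are computed from integer counts, not
floating accumulation, so ratios like `C(s) = #{x ≥ s}/N` carry only the
rounding of a single division.

The original integer-score formulation writes `s + 1` for the successor of a
score. Real-valued score systems (thresholds like 0.634030 occur in
practice) make the lattice unavailable, so every formula here uses
`next(s)`, the next larger support value, with the cumulative beyond the top
defined as 0.

## Point estimates and tie handling

**TAR at FAR `f`.** The threshold `t` is the unique support value with
`C_I(next(t)) < f ≤ C_I(t)`; it exists for any `f ∈ (0,1)` and carries
positive impostor mass. The estimate
`C_G(next(t)) + P_G(t)·(f − C_I(next(t)))/P_I(t)` divides the genuine ties
at `t` proportionally, i.e. interpolates linearly between the two ROC
vertices adjacent to `f`. Ties are the norm, not the exception, at
operational sample sizes; skipping this division biases TAR at any `f`
falling inside a tie run.

**Rates at a threshold.** For a real threshold `t` (not necessarily an
observed score), rates are cumulated down to the smallest support value
`≥ t` (ceiling rule); above the top score both rates are 0, at or below the
bottom score both are 1.

**EER.** Type I error `ER_I(s) = 1 − C_G(next(s))` and type II error
`ER_II(s) = C_I(s)` are evaluated as printed — the offset is deliberately
asymmetric, bracketing the crossing of the two step functions. Candidate
operating points are the support values plus thresholds inside gaps between
adjacent support values: for an all-integer support, a gap exists when at
least one unobserved integer lies between neighbours (and spans those
lattice scores); for non-integral supports the score scale is treated as
continuous and any between-values threshold is admissible (the gap is
reported bracketed by the two observed values). `ER_I` is non-decreasing and
`ER_II` non-increasing along this sweep, so `|ER_I − ER_II|` attains its
minimum on one contiguous run of candidates `[s1, s2]` (asserted, never
tie-broken). The EER is the average of the error-rate midpoints at the two
ends of the run (they coincide whenever the minimum is attained at a single
candidate or on a constant plateau); the reported threshold is
`⌊(s1+s2)/2⌋` — to an integer for lattice supports, to the next lower
observed value otherwise. Degenerate case: a single shared support value
yields EER = 1, which is what the printed estimator produces for coincident
point masses; it is not special-cased.

**Systematic error.** Discreteness can keep the two error rates from
crossing exactly; half the residual gap `min |ER_I − ER_II|`, relative to
the EER, is reported as the systematic (non-sampling) error, 0 when the EER
is 0. Values are reported unrounded. One published table prints a worked
instance of this ratio as 0.51 % where its own printed operands give
(0.000061/2)/0.006064 = 0.503 %; the package reports the computed value and
leaves the reader to round.

**AURC.** Computed by cumulative counting (`searchsorted` of each genuine
score into the sorted impostor set, half weight on ties), never by
materializing the `N_G × N_I` pairs. It equals the trapezoidal area under
the ROC polyline to 1e-12; the test suite checks both identities and an
exhaustive pair-count oracle.

**Weighted cost.** `w1·(1 − TAR) + w2·FAR` at a given threshold, for
application-weighted operating points.

**FNMR.** `1 − TAR` shares the SE of TAR; CI bounds swap and reflect:
`(lb, ub) → (1 − ub, 1 − lb)`. Implemented as a transform on the uncertainty
summary rather than a second bootstrap.

## Bootstrap uncertainty

Each of `B` replications draws `N_G` genuine and `N_I` impostor scores with
replacement (genuine block first, then impostor, from one seeded PCG64
stream, so the replication sequence is a pure function of `(seed, B)`), and
re-evaluates the statistic. Array kernels recompute each statistic directly
from the resampled arrays (partition/searchsorted counting); their equality
with the distribution-based public API is asserted by tests.

* SE = sample SD of the replications with divisor `B − 1` (the source is
  silent on the divisor; the unbiased-variance convention is used and
  documented here).
* Percentile CI: sample-quantile definition that inverts the ECDF with
  averaging at discontinuities (Hyndman–Fan definition 2): for sorted
  `x(1..n)`, `n·p` integral `j` gives `(x(j)+x(j+1))/2` with
  `x(n+1) := x(n)` guarding `p → 1`; otherwise `x(⌈n·p⌉)`; `n·p < 1` clamps
  to `x(1)`. Integrality of `n·p` is detected with absolute tolerance 1e-9
  (e.g. `2000 × 0.025` is not exactly 50 in binary). A property test
  cross-checks against numpy's `averaged_inverted_cdf` method.
* Normal CI: `T̂ ± z_{1−α/2}·SE` with the exact standard-normal quantile.

Defaults `B = 2000`, `α = 0.05`. For high-accuracy statistics at
operational sample sizes the two CI styles agree to three–four decimals,
which is the empirical basis for the normality assumption behind the
Z-tests; the acceptance suite re-measures this agreement on synthetic data.

## Calibrating the number of replications

The variability study repeats the entire bootstrap `L` times per candidate
`B` and reports the coefficient of variation (SD/mean, divisor `L − 1`) of
the `L` SEs and of the `L` percentile-CI bounds. The study seed is expanded
into one independent substream per `(B, i)` cell via `SeedSequence.spawn`,
so cells are individually reproducible and order-independent
(embarrassingly parallel by construction). A CV whose set has zero mean
(degenerate samples) is reported as NaN — not computable — rather than
raised, since other cells of the study remain valid. `L` is exposed as a
parameter with no recommendation attached; the CV of the SE behaves like
`sqrt(1/2B)` for near-normal replication distributions, so the 0.02
tolerance on CV_SE is met around `B ≈ 1400–2000` for strong matchers, and
`B = 2000` is the conservative default. The CVs of the CI bounds are orders
of magnitude smaller than CV_SE whenever the bounds sit near 1 (the mean in
the denominator is then ≈ 1 while the spread is tiny); under the FNMR
transform the bounds move near 0 and their CVs grow accordingly, which is
why bound tolerances are metric-specific user inputs, echoed in reports,
never auto-selected.

## Significance testing

One algorithm against a criterion value: `Z = (T̂ − μ₀)/SE(T̂)`. Two
algorithms: `Z = (T̂₁ − T̂₂)/sqrt(SE₁² + SE₂² − 2·r·SE₁·SE₂)`. Both
two-tailed (`p = 2(1 − Φ(|Z|))`, survival-function accuracy well beyond
1e-12); a one-tailed variant is deliberately not offered. The verdict text
uses a caller-supplied larger-is-better flag (TAR/AURC true, EER/FNMR/cost
false) — orientation is never inferred. The radicand degenerates only as
`r → 1` with equal SEs; that raises with an explanation rather than
returning an infinite Z.

**Correlation by synchronized resampling.** When two algorithms scored the
same comparisons, scores with the same ordinal position co-vary. Per
iteration one genuine and one impostor index vector are drawn and applied to
*both* algorithms' lists, preserving the coupling; the statistic is
evaluated per algorithm, and the Pearson product-moment correlation over the
`M` paired replications is the per-run estimate ("correlation coefficient"
unqualified is read as Pearson). Defaults `M = 2000` and the average of 10
independent runs, both configurable; a zero-variance replication sequence
makes that run's correlation undefined (NaN, counted and reported).
Shuffling away the ordinal pairing drives the estimate to Monte Carlo noise
(`|r| ≲ 1/sqrt(M)` per run) — a property test checks this, along with
monotonicity in the latent coupling of the synthetic generator. The paired
single-bootstrap route (treating co-varying score pairs as bootstrap units
and applying the one-sample formula) is algebraically equivalent after
expansion and is not implemented separately.

## Synthetic data

The generator emulates the structural features the methods are sensitive
to, nothing more: Gaussian margins rounded to `decimals` digits (ties),
an optional point mass at the top genuine score (`spike_mass`, replacing
draws with the fixed value `location + 6·scale`; continuum draws are clipped
there, a < 1e-9 distortion), and a Gaussian-copula latent pairing across
algorithms (`latent_rho`; with `ρ = 1` and identical margins the two lists
are bit-identical). Real operational score distributions are not Gaussian —
they are skewed, multi-modal, and matcher-specific — but the estimators
under test are nonparametric, so passing tests demonstrate correctness of
the estimation machinery under discreteness/ties/correlation, not fidelity
to any particular matcher. What synthetic data cannot show: behavior under
dependent scores (multiple acquisitions per subject), which would require a
grouped bootstrap that is out of scope.

Preset conditions: samples of 60 000 genuine and 120 000 impostor scores
(the operational regime this methodology targets; at FAR 0.001 that leaves
~120 false-accept instances above threshold, enough for the tail estimates
to be stable). The `high_accuracy` preset (separation 5.5σ, 8.95 % top-score
spike) has TAR@FAR(0.001) ≈ 0.99 and EER ≈ 0.003; `low_accuracy`
(separation 3σ) has EER ≈ 0.07. Rounding is to 2 decimals. The acceptance
suite runs the variability study at the full preset sizes with `L = 100`
Monte Carlo passes and `B ∈ {200, 2000}` (about five minutes on one CPU);
the CI-agreement and AURC-SE checks use `B = 2000` with, respectively, the
full preset and 500/500 scores; synchronized-correlation checks use paired
samples of 2 000/4 000 scores with `M = 2000` and 10 runs.

## Numerical choices and limitations

* Threshold search and quantiles use exact counting; EER tie detection uses
  absolute tolerance 1e-12 on error-rate differences (rates are multiples of
  `1/(N_G·N_I)`, so real ties are exact and the tolerance only absorbs float
  noise), and a sub-tolerance minimum gap is snapped to 0.
* `tar_at_far` rejects `f ∉ (0,1)` (no threshold crossing exists);
  `rates_at_threshold` accepts any real threshold.
* Bootstrap replications of a two-component statistic (TAR and FAR at a
  threshold) are stored as paired columns from the same resamples; their
  CIs form a bounds rectangle, not a joint confidence region.
* No BCa or studentized intervals; no smooth/binormal ROC fit; no partial
  AUC; no clustered bootstrap for dependent scores; no rank-based 1-to-n
  identification analysis. These are scope boundaries, not oversights.
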