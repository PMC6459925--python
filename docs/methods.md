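# Methods

## Setting

A cohort of biliary tract cancer patients undergoes radical surgery; serum
is drawn at three time points per patient — pre-operative, postoperative,
and at recurrence (or, for patients who never relapse, at the last
observation). Each serum sample is profiled on a miRNA microarray carrying
target probes, negative-control probes, and a preselected set of
internal-control miRNAs with stable serum expression. The scientific goal
is a *recurrence-predictive index*: a small weighted sum of pre-operative
miRNA levels whose value at or above a cut-off flags a high risk of
post-surgical recurrence.

## Normalization chain

The chain runs strictly forward; each operation checks and advances an
explicit stage tag (`raw → background_corrected → quantile_normalized →
control_scaled → log2`), so a matrix cannot be normalized twice or out of
order.

**Presence calls and background.** Per array, the detection floor is the
mean of the negative-control intensities after removing `ceil(0.05·n)`
probes from each tail of the intensity ranking (ties broken by probe id).
A miRNA is *present* only when its signal strictly exceeds the floor; in
that case the floor is subtracted, otherwise the value is set to 0 and
flagged undetected. A probe at exactly the floor is absent. The trim
fraction is configurable (`negctrl_trim_fraction`, per tail, default
0.05).

**Quantile normalization.** All arrays are forced onto the common
distribution given by the across-array mean of sorted value vectors. Ties
within an array receive the mean of the quantile values their rank range
spans. Undetected cells enter as zeros rather than being excluded, which
keeps per-array vectors equal-length as the procedure requires. The
operation is idempotent to 1e-12 and equivariant under sample reordering.

**Internal-control scaling.** Each array is divided by the ratio of its
internal-control mean to a preset target, after which every array's
internal-control mean equals the preset exactly (checked to 1e-9
relative). The preset defaults to the grand mean of per-array
internal-control means — the batch is then self-normalizing — and can be
fixed to a constant for cross-batch comparability. Rescaling twice is a
no-op.

**log2.** Discriminant fitting operates on `log2(value + 1)` by default.
The printed coefficient magnitudes of indices of this kind (≈0.2–0.5) are
consistent with a log-like dynamic range; a linear-scale analysis is
available by passing `log2=False` to `normalize_chain`.

A note on what the chain can and cannot equalize: after the full chain,
arrays that measured the same material are indistinguishable by a
two-sample KS test. Detection dropout breaks this deliberately — absent
probes produce per-array zero-inflation whose tie-averaged plateaus
differ between arrays. That is signal, not an array effect, so the
distributional-equality property is only asserted (and tested) with
dropout disabled.

## Selection funnel

Four stages, each producing a subset of the previous stage's set (checked
as an invariant):

1. **Detection:** keep miRNAs with value > 0 in at least
   `detection_fraction` (default 0.5, i.e. "most") of pre-operative
   samples. The boundary is inclusive: 11 of 22 passes at 0.5.
2. **Paired pre/post t test:** two-sided paired t on per-patient
   (pre − post) differences, significant at `alpha_paired` (default 0.05,
   uncorrected; a Benjamini–Hochberg option exists but is off by default —
   funnel-style analyses conventionally report raw counts). The sign of
   the mean difference labels each survivor *pre-high* or *pre-low*.
   Zero-variance differences with nonzero mean are flagged degenerate and
   treated as non-significant; identical pre/post vectors get p = 1.
3. **Median-split log-rank:** patients are split at the median
   pre-operative value (ties go to the high group — a fixed convention so
   results are reproducible), and the two groups compared on RFS by
   log-rank at `alpha_logrank` (default 0.05). Constant values cannot be
   split and are excluded with a flag.
4. **Trajectory rule:** a pre-high candidate is kept when (a) relapser
   medians fall from pre to post and rise from post to final, each by more
   than `trajectory_margin` (default 0); (b) at least
   `trajectory_majority` (default 0.5) of relapsers individually show
   fall-then-rise; and (c) that fraction exceeds the corresponding
   fraction among non-relapsers. Pre-low candidates use the mirror
   pattern. The rule is a formalization of the qualitative
   "drop after surgery, re-rise at recurrence" pattern; all three parts
   are configurable because no standard quantitative criterion exists.

Calibration: under a null simulation (no planted effects) the stage-2 pass
fraction sits at the nominal alpha within binomial error, and the final
candidate sets are empty at vanishing alpha.

## Discriminant index

For a member set with expression matrix X (patients × members) and class
labels (relapse / no relapse), the Fisher direction is
`w = S_w⁻¹(μ_rec − μ_non)` with `S_w` the pooled within-class covariance
(denominator n − 2). Fisher directions are defined only up to positive
scaling, so the package fixes a convention: `w` is scaled to unit
Euclidean norm and oriented so relapsers score higher; the intercept `b`
maps the projected grand mean to score 0; the cut-off `τ` is the midpoint
of the projected class means. A score at or above `τ` predicts
recurrence — ties predict recurrence. Because the published formulas use
an unstated normalization, numeric equality of coefficients with any
particular printed index is not expected; member identity, sign pattern
and classification behaviour are the meaningful comparisons, and the
printed formulas themselves are shipped verbatim in
`published_indices()` for direct application.

When `S_w` has condition number above 1e12 (collinear members, p close to
n), a ridge `λI` with `λ = 1e-6·trace(S_w)/dim` is added before
inversion.

`exhaustive_search` fits every nonempty subset of the candidates up to
`max_size` (guarded at 20 candidates; the search refuses rather than
silently truncating). Ranking is total and deterministic: accuracy desc,
AUC desc, fewer members, lexicographic member names. Metrics are apparent
(training-set) performance, matching how such indices are reported;
evaluation on held-out data is the caller's responsibility. AUC is the
Mann-Whitney statistic with ties counting ½, so it is invariant under any
strictly increasing transform of scores. Clinical comparator covariates
(CEA, CA19-9) are dichotomized either at a supplied clinical threshold
(strata `≤t` / `>t`) or at the Youden-optimal cutoff (ties resolved to
the lower cutoff).

## Survival models

Kaplan-Meier estimation, the two-group log-rank test, and Cox
proportional-hazards models are delegated to lifelines; the package adds
the conventions the pipeline needs. Log-rank on identical groups returns
statistic 0 / p = 1; with no events anywhere the test is undefined and
p = 1 is returned with a flag. Cox fits use Efron tie handling (event
times have day resolution, so ties occur); univariate mode fits one
covariate at a time, and the multivariate model takes exactly the
covariates whose univariate hazard ratio is ≥ 2 (`hr_threshold`,
configurable), preserving input order. Monotone likelihood (perfect
separation) is caught and flagged with an unbounded CI rather than
reported as a finite estimate. A from-scratch partial-likelihood score
test at β = 0 with Breslow ties is included because, for a binary
covariate on tie-free data, it equals the log-rank chi-square exactly —
a cross-check the tests exercise to 1e-6.

RFS is days from surgery to recurrence (event) or last observation
(censored); OS is days to death or last observation. Index-based KM
grouping uses the predicted class (score ≥ τ → high-risk group).

## Synthetic cohort generator

The generator emulates the target study design; its defaults are the
study's design constants: 22 patients (13 relapsers), three samples each
(66 arrays), 2565 miRNA probes of which 47 are internal controls, 100
negative-control probes, four planted up-markers and two down-markers,
and a follow-up horizon of 1454 days.

**Survival.** Relapser RFS is exponential (`rfs_rate`, default 1/365 —
a mean time-to-recurrence of one year, typical of resected BTC) resampled
into (0, follow-up) by inverse CDF, with the event observed; non-relapsers
are censored near follow-up with uniform jitter. OS is RFS plus an
independent exponential post-recurrence survival for relapsers, which
preserves rfs ≤ os by construction.

**Signals.** Per-probe baseline log2 levels are Normal(7, 1.5); per-sample
noise is Normal(0, 0.4). Planted up-markers add 1.5 log2 units
(`marker_effect_log2`) to relapsers' pre-operative samples, drop by 1.0
(`dynamics_amplitude_log2`) after surgery, and re-rise at the final draw
for a `trajectory_concordance` = 0.9 fraction of relapsers; non-relapsers
also dip post-operatively (surgery removes tumour-derived signal
transiently) and re-elevate with the complementary probability 0.1.
Down-markers are mirror images. Internal controls sit one log2 unit above
the panel mean and receive no group or time effect, so internal-control
scaling is statistically valid on simulated data by construction. Planted
markers are likewise given baselines about one log2 unit above the panel
mean: candidate biomarkers are stably detected serum miRNAs by
definition, and a marker whose baseline sat at the detection floor would
lose its trajectory to presence-call zeros.

Signals are assembled on the log2 scale, exponentiated, multiplied by a
per-array log-normal scale factor (sd 0.3) and summed with additive
Normal(40, 8) background — the multiplicative-plus-background structure
the normalization chain assumes. Negative controls carry background only.
A `detect_drop_fraction` = 0.54 share of non-marker targets is absent
from serum: essentially no specific signal, drawn slightly dimmer (0.85×)
than the negative-control background so the presence call rejects them in
most arrays. With these defaults roughly 1200 of 2565 miRNAs pass the
majority-detection filter, matching the detection ratio typical of serum
panels of this size.

**What the generator does not emulate:** probe sequence content and
cross-hybridization, exosomal vs protein-bound miRNA compartments,
disease-subtype structure in the signal model, or realistic inter-miRNA
correlation (probes are independent given the array effects). Passing
tests therefore demonstrate correctness of the algorithms under the
stated statistical model, not clinical validity on real serum data.

**Determinism.** All draws flow from a single integer seed via
`numpy.random.default_rng`; the pipeline derives per-stage seeds by stable
hashing of stage names, so runs are bit-reproducible and stages stay
decoupled.

## Problem sizes used in the test suite

Unit tests run on a miniature panel (80 miRNAs, 30 negative controls) at
the full 22-patient design. Recovery properties are asserted where they
hold statistically: at 22 patients recovery of planted markers is partial
(power-limited, as in any real cohort of that size) and the tests assert
direction correctness; full recovery of all six planted markers with
correct directions is asserted at 200 patients over 20 seeds, where it
holds in every run. Cox hazard-ratio recovery uses uncensored exponential
samples of 500 patients; the [1.7, 2.35] acceptance band corresponds to
roughly ±1.8 standard errors of the Wald estimate at that size, so 18–19
of 20 runs inside the band is the expected behaviour, and that is what is
asserted.

## Known limitations

- Training-set (apparent) metrics only by default; no cross-validation or
  external validation loop is built in.
- No multiple-testing correction in the default funnel (a BH option
  exists); funnel counts are descriptive, not inferential.
- The GEO series-matrix reader handles the common single-platform text
  layout and maps time points through an editable vocabulary; it does not
  download data or parse supplementary binary formats.
- No within-array spatial correction or batch-effect modelling beyond the
  stated chain.
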