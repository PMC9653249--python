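# Methods notes

## The generative model

`simulate_tokens` draws, in order: sequence sizes from a configurable
distribution over 1..6 (default: proportional to the published per-length
counts 244, 82, 21, 3, 7, 2); a signaller per sequence (one prolific
individual receives `prolific_fraction` ≈ 290/560 of the mass, the rest a
geometric tail, matching a corpus where one male contributed half the
tokens and the others 2–76); a recording date per sequence from a per-
signaller pool sized at about one day per three sequences; and a gesture
type per token from Zipf-like weights `rank^-0.9` over 26 types (21
manual, 5 whole-body interleaved across frequency ranks so category is
not confounded with frequency).

Log-duration of a token is

    mu0 + beta_freq*p(type) + beta_size*n + beta_category*[whole-body]
        + u_signaller + u_sequence + u_type + eps

with `p(type)` the *expected* type proportion implied by the configured
weights (not the realized sample proportion), so the ground-truth slope
is well defined; each `u` is a zero-mean Gaussian intercept and `eps` the
residual. Durations are `exp(·)` rounded **up** to the nearest 0.04 s
video frame, never below one frame, mirroring frame-based video coding.
Defaults `mu0 = 0.75`, `sd_signaller = 0.30`, `sd_sequence = 0.35`,
`sd_type = 0.35`, `sd_resid = 0.70` put the median duration near 1.8 s
and the range at roughly 0.04–15 s, the scale of the corpus emulated.
`beta_size = −0.18` (log-seconds per token of sequence size) is the
default Menzerath effect; `beta_freq` and `beta_category` default to 0.

Tokens are laid out on a per-(signaller, date) video timeline with
within-sequence gaps uniform on frame multiples strictly below
`within_gap_max` (default 0.90 s) and between-sequence gaps of at least
`between_gap_min` (default 5 s). Because the rapid-sequence threshold
(1 s) separates the two bounds, segmentation recovers the simulated
partition exactly — a round-trip the tests rely on. The empirical gap
distribution of real corpora is not published; both bounds are free
parameters, chosen once for comfortable separation.

What the generator does **not** emulate: gesture kinematics and phase
structure (preparation/stroke/hold/recovery), recipient responses and
response-waiting persistence sequences, date-level variance (dates exist
so a date random term is fittable, but no variance is injected — fitting
one on such data is a benign boundary case), and any dependence between
sequence size and signaller identity. Passing tests therefore show the
*machinery* is sound under the stated hierarchical model, not that real
gesture data satisfy that model.

## Segmentation conventions

The gap is end-to-start by default ("time in between" two tokens);
start-to-start is available (`gap_mode`) because the original coding
convention is not documented. The threshold is strict: a gap of exactly
1.000 s closes a sequence. Sequences never span videos or signallers. A
token with an unknown end time closes its sequence (the following gap is
undefined) and marks the sequence incomplete; completeness filtering then
drops the whole sequence, since a sequence-level analysis needs all
member durations.

## Permutation tests and their calibration

Brevity and compression permute the **type-level** duration vector
against the frequency vector (the classic frequency-duration pairing
shuffle). P-values use the add-one convention `(r+1)/(n_perm+1)`; for
seven or fewer types both tests can enumerate all pairings, giving exact
p-values (then without add-one, the identity pairing counting itself).
Kendall tau-b (tie-corrected) is the default correlation — repertoire
durations carry heavy ties at frame resolution — with median per-type
durations for the correlation and mean durations for the compression test
(`L` is an expectation; with token proportions as weights `L_obs` equals
the overall mean token duration exactly).

Two calibration facts, both verified by the test suite, deserve notice:

- The permutation null assumes the type-level duration summaries are
  exchangeable. When per-type means are computed from very unequal token
  counts (study-scale counts run from ~5 to ~130), frequent types have
  much stabler means; the observed pairing then sits near the centre of a
  permutation distribution whose tails are driven by the noisy rare-type
  means, and the one-sided compression test becomes **conservative**
  (almost never rejects under the null) rather than anti-conservative.
  Nominal 5% behaviour holds under the exchangeable type-level null
  (`simulate_null_repertoire`: iid duration summaries across types).
- With tied counts, the discrete two-sided tau null is conservative
  (~2.4% at α = 0.05); the one-sided law-direction alternative
  (`alternative="less"`), which matches the one-sided compression test,
  is calibrated (~4%).

Token-level label shuffling (permuting durations across tokens before
aggregating to types) was considered and not adopted: the type-level
vector shuffle is the standard scheme in this literature, and mixing the
two would change what "null" means between the correlation and
compression tests.

## The hierarchical models

Both models are linear mixed models on the natural log of duration,
fitted by REML with variance components (statsmodels MixedLM). When one
random factor nests the others (sequence within signaller, or within
date for the single-signaller subset) it becomes the grouping factor and
the fit is block-diagonal and fast; the Zipf-model's gesture-type term is
crossed with signaller, so that model falls back to a single-group
variance-components fit. Fixed-effect intervals are Wald 95% intervals
(estimate ± 1.96 se). PWB enters the Menzerath-model as a fixed control
(a config switch can add a gesture-type random intercept). Type
proportions are computed on the analysis dataset, i.e. after the
completeness exclusion and after subsetting. Degenerate noiseless data
(zero residual and random variance) are detected and fitted by exact
least squares, since the mixed likelihood is singular there.

The engine is likelihood-based rather than sampler-based by design: the
model structure (response, fixed terms, random intercepts) is what
defines the analysis, and REML point estimates and Wald intervals are the
standard frequentist counterpart of weakly-informative-prior Bayesian
fits at these sample sizes. No MCMC diagnostics apply; convergence is
reported from the optimizer.

**Full/null comparison.** The null drops only the term of interest
(proportion, or sequence size), keeping controls and random terms. The
criterion is an out-of-sample expected log predictive density estimated
by 5-fold cross-validation with whole sequences held out together
(respecting the sequence random intercept); predictions use fixed
effects with the total marginal variance. `delta` = elpd(null) −
elpd(full): negative favours the full model. Because all tokens in a
fold share one pair of fold fits, the standard error is clustered at the
fold level, `sqrt(K)·sd(fold sums)` — a pointwise standard error would
understate the uncertainty badly. Under a true null the delta
concentrates near the +1-ish overfitting penalty with |delta| within two
standard errors in ~9/10 replicates; a strong injected effect drives the
delta far below −1 se.

**Parameter recovery.** `recovery_experiment` simulates, segments,
filters and fits per seed, reporting the mean point estimate and
95%-interval coverage. At study scale the size coefficient is recovered
with a small attenuation (~0.02 toward zero), traceable to the ceil-to-
frame quantization which inflates short durations relatively more; this
sits well within the two-reported-sd tolerance used by the tests.

## Numerical and design choices

- All randomness flows from explicit integer seeds; identical seed and
  config give byte-identical token streams and reports.
- Quantization uses `ceil(x/frame − 1e-12)` to avoid float-edge
  misrounding; token times are integer frame counts internally.
- Comparison tolerances in permutation counting use a 1e-12 cushion so
  ties at the observed value count as at-least-as-extreme.
- ICC(3,1) is computed from the two-way ANOVA decomposition directly,
  `(MS_rows − MS_err)/(MS_rows + MS_err)` for two occasions; the
  consistency form is invariant to an additive shift between codings.
- The Menzerath–Altmann law is fitted in its two-parameter form
  `d = a·n^b` only; with sizes spanning 1–6 the three-parameter
  `a·n^b·e^{cn}` form is not identifiable in practice.
- The pipeline degrades gracefully: law tests whose preconditions fail
  (e.g. fewer than three types) are reported as skipped with the reason,
  and a subset that cannot be fitted is skipped with a warning.

## Problem sizes

The default test and acceptance runs use 377-sequence (~530-token)
corpora, 10 seeds per recovery scenario, 999–9999 permutations, and 500
replicates for calibration — sizes chosen to keep every check
informative while the whole suite runs in minutes on one core.

## Known limitations

- Real corpora may violate the lognormal-duration and additive-effects
  assumptions; the generator cannot detect that, only the robustness of
  the machinery to its own model.
- The compression test's conservatism under heteroscedastic type means
  (above) means a non-significant compression result on a small, skewed
  repertoire is weak evidence against compression.
- Date effects are fitted but never simulated; recovery of a *true* date
  variance component is untested.
- Wald intervals can undercover for variance-component-heavy designs at
  very small n; coverage at study scale is verified empirically (~80%+
  at 10 seeds) but no small-sample correction (Kenward–Roger etc.) is
  applied.
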