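# Methods

## The model

A single masked target is encoded into visual working memory, per feature,
as a Bernoulli event whose probability grows with exposure duration `t`
(seconds):

- below the temporal threshold `t0` no processing has started, so the
  encoding probability is 0 and report accuracy sits at the guessing level
  `chance = 1/n_alternatives` (1/12 here, 12 locations and 12 letters);
- above `t0`, encoding probability rises as `1 - exp(-v (t - t0))`, an
  exponential approach to 1 at rate `v` (objects/second);
- a non-encoded feature is reported by a uniform guess, so accuracy is
  `p_enc + (1 - p_enc) * chance`.

The function is continuous at `t = t0`, bounded in `[chance, 1)`,
nondecreasing in `t` and `v` and nonincreasing in `t0`. `chance` is a
design constant, never a free parameter. There is no lapse parameter: the
masked-report paradigm pushes asymptotic accuracy to ~1 and the designs
analysed here contain no long-duration lapse information to identify one.

## Estimation

Per observer, feature and (optionally) report-order cell, trials are
reduced to per-duration correct counts — the binomial sufficient statistic;
trial order carries no information under the model. `(t0, v)` minimise the
binomial negative log-likelihood with `chance` fixed.

Numerical choices:

- **Bounds** `t0 ∈ [0, 0.150] s`, `v ∈ [0.5, 500] /s`. The upper `t0`
  bound lies above the densely sampled duration range (12–129 ms) but below
  the asymptotic region, where `t0` ceases to be identifiable; the `v`
  bounds bracket every plausible single-target rate.
- **Multi-start**: the negative log-likelihood is evaluated on a coarse
  grid (`t0` every 10 ms from 0–120 ms × `v` in {5, 10, 20, 40, 80, 160}),
  and the ten best grid points are refined by bounded Nelder-Mead
  (parameter/objective tolerance 1e-8). The likelihood is continuous but
  only piecewise-smooth in `t0` (the kink at each sampled duration), hence
  a derivative-free refiner.
- **Ties** are broken by lower negative log-likelihood, then lower `t0`
  (ties at 1e-10 resolution).
- **Degenerate data**: accuracy flat at chance leaves `v` unidentified; the
  fit returns with `v` pinned at its lower bound, flagged `at_bound` and
  `converged=False`, rather than raising. Probabilities are clipped one ulp
  below 1 and the likelihood uses `xlogy`, so saturated cells (k = n,
  p → 1) stay finite.
- The refined optimum is validated in the test suite against an exhaustive
  grid search at 1 ms × 0.5 /s resolution (refined NLL ≤ grid minimum +
  1e-6 on every fixture).

The "aggregate observer" curve is the arithmetic mean of the individually
fitted `t0` and `v` — a descriptive summary, not a pooled fit.

## Stochastic independence

Per observer × duration, the four joint outcomes (location correct/wrong ×
identity correct/wrong) are tabulated as relative frequencies; the
independence prediction replaces them with products of the observed
marginals (which preserves the marginals exactly and sums to 1). The
per-observer Pearson correlation is computed over the vector of all
durations × all four cells. Using all four cells is a choice — the two
off-diagonal cells are linear combinations of the others given the
marginals — and a two-cell variant (CC and WW only) is exposed
(`cells="two"`) for sensitivity analysis. The group-level statistic is a
one-sample t test of the per-observer correlations against zero, on raw
correlations by default; a Fisher-z option exists but is off, since the
headline statistic in this literature is reported on raw r. Zero-variance
vectors (an observer at ceiling everywhere) yield an undefined correlation;
such observers are excluded from the group test with a warning.

## Group statistics

- **Paired/one-sample t** with Cohen's `d_z = mean(d)/sd(d) = t/√n`;
  two-sided p throughout. Differences that are identically zero resolve to
  `t = 0` (no effect); a constant *nonzero* difference has no finite t and
  is returned flagged degenerate.
- **JZS Bayes factor**: Cauchy(0, r) prior on the standardized effect,
  default `r = 0.707`. Computed by expressing the Cauchy prior as an
  inverse-gamma(1/2, r²/2) mixture of normal g-priors, marginalising the
  effect analytically, and integrating the remaining one-dimensional
  elementary integrand over log g by adaptive quadrature (relative
  tolerance 1e-10) with the peak factored out in log space. This is
  numerically stable and fast for |t| far beyond the hundreds, a regime
  where noncentral-t-density-based integration becomes slow and where at
  least one reference implementation saturates. BF01 is the exact
  reciprocal.
- **2×2 repeated-measures ANOVA** by explicit sums-of-squares
  decomposition; each effect's F uses its own subject-interaction error
  term with df (1, n−1), so sphericity is moot. Effect size is generalized
  eta squared in the fully-within convention (Olejnik–Algina): the
  denominator is the effect's SS plus *all* subject-related SS (subjects
  and every subject × condition interaction). SS components at rounding
  noise (< 1e-12 of the total SS) are treated as exactly zero so that
  constant data yields F = 0 rather than a ratio of float dust.
- **Holm correction**: step-down adjusted p-values. The post-hoc family for
  the 2×2 follow-up is the four feature-related pairwise cell comparisons
  (location vs identity within each report order and across the two
  orders); the family is configurable.
- **Within-subject CIs**: Cousineau normalization (subtract the observer
  mean, add the grand mean) followed by Morey's bias correction
  (normalized variance × M/(M−1)), half-width `t_crit(n−1) × SE`. For two
  conditions this equals the paired-difference CI half-width divided by √2.
  A plain between-subject CI is available behind `method="between"` for
  comparison.
- **Accuracy advantage**: per observer and duration, location minus
  identity accuracy, averaged over durations within observer and then over
  observers (equal duration weighting, matching how the per-duration means
  enter the figures).

## Synthetic data

The generator emulates the two designs: dual report (11 durations ×
2 report orders × 25 trials per session; both features reported each trial,
order counterbalanced and randomised) and blocked report (11 × 50 per
session; exactly one feature reported). Canonical durations are 12–224 ms;
letters index into the canonical 12-letter set; targets are uniform over
12 locations and 12 letters. Durations are stored in ms in files and
converted to seconds for model math.

Per trial, each feature's encoding event is drawn with the model
probability; an encoded feature is reported correctly, a non-encoded one by
a uniform guess over all 12 alternatives (so chance is exactly 1/12 — no
perceptual confusion structure among letters or neighbouring locations is
modelled). The dependence parameter `rho` couples the two encoding draws:
with probability `rho` both events threshold a single shared uniform
(comonotone; P(both) = min of the marginals), otherwise independent
uniforms. Marginals are exact for every `rho`; `rho = 0` is the
independence structure the analysis tests for, `rho > 0` exists purely as a
synthetic probe of the independence machinery and corresponds to no claim
about real data.

Observer parameters are drawn uniformly, by default with a systematic
location advantage: the stated `t0` and `v` ranges (defaults 10–40 ms and
10–40 /s) are split at the midpoint, location drawing from the favorable
half. This makes the between-feature contrast a population effect of
`d_z ≈ 2.4`, the order of the feature effects this paradigm was designed
around, rather than a coin-flip margin per observer; the pooled parameter
mean stays at the range midpoint. `feature_ordering="none"` gives
exchangeable, full-range features for null calibration. Randomness uses one
master seed with per-observer substreams spawned by index, so enlarging the
roster never perturbs earlier observers' data. Sessions are homogeneous (no
practice, learning or fatigue effects — the analysis pools sessions, so the
generator models the pooled process).

What the generator deliberately omits: response times, eye movements, mask
similarity structure, spatial scoring ambiguity (reports are discrete
indices), and any session-level nonstationarity. Tests that pass on this
synthetic data therefore establish that the *pipeline* is correct and
well-calibrated under the model's own assumptions — parameter recovery at
the study's trial counts, independence detection, contrast direction
recovery — not that real observers satisfy those assumptions.

## Problem sizes

The test suite and analysis scripts run everything at the study's scale:
9 observers, 550 trials per session, one to four sessions. Recovery checks
use the blocked design's 50 trials × 11 durations per feature; the
brute-force grid oracle runs at 1 ms × 0.5 /s resolution over the full
parameter box. These sizes keep any single check in seconds while leaving
binomial noise at its realistic level.

## Known limitations

- `t0` estimates inherit a small positive bias at low trial counts (the
  threshold is a boundary-ish parameter); the recovery tests quantify the
  practical error (median |error| < 5 ms at 50 trials/duration).
- The independence correlation is computed on probabilities that share
  estimated marginals, which builds in some correlation even under modest
  dependence; the comonotone probe (`rho = 1`) shows the statistic that
  does discriminate is the signed CC excess, and both are reported.
- The ANOVA handles exactly the 2×2 fully-within design; larger designs
  are out of scope.
- No Bayesian posterior over `(t0, v)` and no multi-object TVA rate
  equations: single-target paradigm only.
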