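# Methods

## The assay and its statistical unit

A trial releases a group of flies into a T-maze with an orange-odor and an
apple-odor food chamber and counts how many enter each.  The statistical
unit throughout is the **trial**, summarized by the proportion of choosing
flies that picked orange; flies that never enter a chamber drop out of the
denominator (they are recorded only through the optional `n_released`
field).  Arm summaries are unweighted means of per-trial proportions, not
pooled counts — trials, not flies, carry the replication, and pooling
would let large trials dominate and understate between-trial variance.

Two designs share the readout:

* **preference** — flies pre-exposed to both odors in one of two orders
  (`A_then_O` / `O_then_A`);
* **learning** — flies conditioned with one odor's flavor made aversive
  (quinine) in one of two pairings (`A_aversive_O_palatable` /
  `O_aversive_A_palatable`).

## Scores and their sign convention

* order-effect score `o` = mean proportion (A-then-O trials) − mean
  proportion (O-then-A trials);
* learning score `l` = mean proportion (apple-aversive trials) − mean
  proportion (orange-aversive trials).

The positive direction always favours the apple-first / apple-aversive
arm, so a positive `l` reads directly as "conditioning shifted flies
toward the palatable-paired odor".  The mirrored orientation is one flag
away (`flip_sign` / `flip_score_signs`) because both appear in the
literature for difference scores of this kind.

For one-sample tests against zero the score is decomposed into per-pair
values: trials are split by arm, sorted by `trial_id`, and paired
positionally (ids encode the running block when the experiment is run in
matched sessions).  With balanced arms the mean of per-pair values equals
the arm-mean difference exactly, so the two views agree; an unmatched
trailing trial is dropped from pairing with a warning.  The arm contrast
is additionally reported as a two-sample test, since which unit the
original analyses paired on is not always recoverable from a dataset.

## Non-responder exclusion

A cohort (line) is excluded when *every* one of its trials has fewer than
`min_choosers` choosing flies (default 1, i.e. only cohorts that never
respond are dropped).  Exclusion is cohort-level because a line that
consistently refuses the chambers carries no choice information at any
trial; a single adequately-responding trial keeps the whole cohort.

## Heritability

Per-trial trait values: the orange proportion (preference) or the
palatable-paired-choice proportion (learning; well defined in both
pairings).  The default estimator is transparent method-of-moments:

* `Vb` — sample variance (denominator `k − 1`) of the line means,
  unweighted;
* `Vw` — pooled within-line sample variance, weighted by `size − 1`.

Then the intraclass correlation `t = (n·Vb − Vw)/(n·Vb + (n−1)·Vw)`,
bounded in `[−1/(n−1), 1]`, equal to 1 only for `Vw = 0 < Vb`, and
converging to the classic `Vb/(Vb + Vw)` as `n → ∞`.  `n` defaults to the
number of retained lines, the convention under which line panels of this
design are usually reported; classical usage (`n` = measurements per line)
is available through the same argument (`icc_n` in the pipeline config).
With 20 trials per line, `E[Vb] = σb² + σw²/20`, and the `−Vw/n` correction
at `n = 10` slightly over-corrects, so the estimator carries a small
downward bias of order `σw²/20` — visible in the recovery study below and
well inside its tolerance.

A one-way ANOVA variant (`method="anova"`: `Vb = (MSB − MSW)/n0`, with the
negative case clipped to 0 under a warning) is provided as a sensitivity
check, and a percentile bootstrap over trials within lines gives interval
estimates; no closed-form F-based confidence intervals are attempted, and
`t` is a broad-sense proxy, not narrow-sense h².

## Test battery

Each analysis vector is gated on its own by a Shapiro–Wilk test at
α = 0.05: not rejected → *t*-test, rejected → rank test (Wilcoxon
signed-rank one-sample, Mann–Whitney two-sample, Kruskal–Wallis across
lines).  A constant vector routes nonparametric with a warning rather than
failing a whole report.  All p-values are two-sided.  scipy.stats supplies
the distributions; the signed-rank statistic is recomputed in-package as
`V` (sum of positive-difference ranks) with Pratt handling of zeros —
zeros are real observations when proportions from discrete counts land
exactly on the null, so they stay in the ranking and drop only from the
rank sums.  The two-sample t-test pools variances by default (df =
`n_a + n_b − 2`); Welch is a config switch.  Post-hoc families (per-line ×
per-arm tests against chance, per-line score tests) are Holm-adjusted via
statsmodels, with single-step Bonferroni as an option.

## Synthetic data generator

Logit-additive binomial model per trial:

```
n_choosers ~ Binomial(flies_per_trial, responder_prob)
n_orange   ~ Binomial(n_choosers, p_cell)
logit(p_cell) = logit(p0) + shift(cell) + b_line,   b_line ~ N(0, line_sd²)
```

with cell shifts `±order_effect/2` for the two exposure orders (symmetric,
so `p0` stays the order-averaged baseline), `+learning_effect` for the
apple-aversive pairing and `−asymmetry·learning_effect` for the
orange-aversive pairing.  `asymmetry < 1` encodes that conditioning
*against* the innately preferred orange odor is weaker than conditioning
against apple.  Non-responsiveness exists at two levels: per fly
(`responder_prob`) and per line (`nonresponder_line_prob`, emitting
zero-count trials that exercise the exclusion path).

Defaults are the study conditions the analysis is designed around:
`p0 = 0.56` (the observed unconditioned orange bias), conditioning shifts
sized to the observed arm means (`learning_effect = 0.6`,
`asymmetry = 0.53` put the arms near 0.70 and 0.48, learning score near
0.22), `order_effect = 0.25` (a detectable but modest order shift),
`line_sd = 0.4` (moderate heritability of the baseline bias),
`responder_prob = 0.9`, trials of 40 flies in 10-line panels.  Population
mode is a single cohort of 250-fly trials with no line structure — 14
trials per exposure order (preference) or 29 per pairing (learning),
matching the trial counts the population analyses are built for.
Identical parameters + seed reproduce the identical dataset.

`expected_icc` gives the intraclass correlation the parameters imply for
per-trial trait values: the between-line variance of the line-mean trait
and the within-line variance (binomial noise plus across-cell spread) are
integrated over the Normal line effect with 80-node Gauss–Hermite
quadrature.  One approximation remains — the binomial term divides by the
*mean* chooser count instead of integrating over its distribution — and
the test suite checks the result against a 100,000-trial Monte-Carlo
estimate (agreement within 0.02).  `line_sd_for_icc` inverts it by Brent
root-finding, which is how the recovery studies hit target ICCs exactly.

### What the generator does and does not emulate

It reproduces the structure the analysis assumes: binomial per-fly
choices, a baseline odor bias, order and conditioning shifts with
asymmetry, line-level random effects, and non-responders at both levels.
It does **not** model overdispersion beyond binomial noise (real per-trial
variances of this assay are several-fold larger than binomial, e.g. from
shared within-trial social effects), per-fly trajectories, side bias, or
— deliberately — line variation in *conditionability*: the single line
effect is an odor-bias effect common to both pairing arms, so it largely
cancels in the palatable-paired learning trait and simulated learning-trait
heritability sits near its null.  Passing recovery tests therefore
demonstrate estimator correctness for the preference trait under in-model
noise, not that real learning heritability has any particular value.

## Validation studies (sizes chosen for tight Monte-Carlo error at
interactive runtimes)

* **Calibration** — 2,000 null population-learning datasets (`p0 = 0.5`,
  no conditioning effect); the gated learning-score test at α = 0.05 must
  reject in 5% ± 1.5%.
* **Recovery** — targets ICC ∈ {0.3, 0.6, 0.8}; 50 replicate panels of
  10 lines × 20 trials × 40 flies each; mean pipeline estimate within
  ±0.15 of the generator-implied value.
* **Asymmetry** — 50 replicate pairs of matched population experiments
  with `learning_effect = 0.15`, `asymmetry = 0.2` (an effect sized near
  the detection threshold so the contrast is informative): the
  apple-aversive stratum of the cross-assay comparison rejects in ≥ 80% of
  replicates, the orange-aversive stratum in ≤ 30%.

All replicate seeds derive from a single base seed and stay below 2^31.

## Numerical and degenerate-input choices

Zero-chooser trials raise on direct scoring and are silently skipped when
aggregating trait vectors (after cohort-level exclusion has had its say);
an empty design arm raises rather than returning a one-armed "score"; a
completely tied Kruskal–Wallis input reports H = 0, p = 1; Vb = Vw = 0
makes the ICC undefined (error) rather than silently 0; reports round to
2 decimals for proportions/scores and 3 for statistics with scientific
notation below 0.001 for p-values, while the JSON always keeps full
precision.

## Known limitations

The printed-variance route (injecting externally computed Vb/Vw into the
ICC) depends on what trait values produced them, which an input dataset
must make explicit; the learning-trait choice here (palatable-paired
proportion) is one defensible option and is flagged in reports.  Pooled-df
two-sample tests assume equal variances across arms of different sizes;
switch to Welch when that is doubtful.  The generator's binomial-only
noise means its absolute Vw is smaller than field data typically show, so
simulated variance components are not comparable to empirical ones —
only the estimator's behaviour is.
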