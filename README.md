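# tmaze

Analysis toolkit for large-scale two-choice (T-maze) olfactory assays in
*Drosophila*.  Groups of flies — hundreds for a mass population, dozens for
an inbred line — are released into a T-maze whose arms hold an orange-odor
and an apple-odor food chamber; flies entering a chamber are trapped and
counted.  The package scores these counts, runs the statistical battery the
design calls for, and estimates the heritability of olfactory behavior from
replicated inbred-line panels.  A seeded synthetic-data generator with
known ground truth makes every stage verifiable without any external data.

## What it computes

For each trial, the orange-choice proportion `p = n_orange / (n_orange + n_apple)`
(only flies that made a choice count).  From per-trial proportions:

* **Order-effect score** — `o = mean p(A/O) − mean p(O/A)`, the shift in
  choice caused by the order of the two pre-exposures (apple-then-orange
  vs orange-then-apple).
* **Learning score** — `l = mean p(A-/O) − mean p(O-/A)`, the shift caused
  by which odor's flavor was quinine-paired during conditioning
  (apple-aversive vs orange-aversive).  Positive `l` means flies moved
  toward the palatable-paired odor, i.e. conditioning worked.
* **Heritability proxy** — from per-trial trait values of replicated lines,
  the between-line (`Vb`) and pooled within-line (`Vw`) variances give the
  intraclass correlation

  ```
  t = (n·Vb − Vw) / (n·Vb + (n − 1)·Vw)
  ```

  the fraction of phenotypic variance attributable to line (genetic)
  differences.
* **Test battery** — each vector of proportions or scores is
  Shapiro–Wilk-gated into a one-sample *t*-test or Wilcoxon signed-rank
  test (reported as `V`, the positive-rank sum) against chance (0.5) or
  against 0; arms are compared with two-sample *t*/Mann–Whitney tests and
  lines with Kruskal–Wallis; post-hoc families are Holm-corrected.
  Cohorts of flies that never enter the chambers (non-responder lines) are
  excluded before analysis.

## Worked example

```python
import tmaze as tm
from tmaze import Assay

params = tm.SimulationParams.inbred_panel(seed=42)   # 10 lines x 2 arms x 10 trials of 40 flies
pref  = tm.simulate_dataset(params, Assay.PREFERENCE)
learn = tm.simulate_dataset(params.replace(seed=43), Assay.LEARNING)

prep = tm.run_preference_analysis(pref)
rep  = tm.run_learning_analysis(learn)
vc, est = tm.heritability_pipeline(pref, Assay.PREFERENCE)

s, sc = rep["summary"], rep["learning_score"]
t = rep["tests"]["learning_score_vs_zero"]
print(f"unconditioned orange-choice mean: {prep['summary']['overall_mean']:.3f} ({prep['summary']['n_trials']} trials)")
print(f"conditioned orange-choice mean:   {s['overall_mean']:.3f} ({s['n_trials']} trials)")
print(f"learning score l = {sc['score']:.3f}  (A-/O mean {sc['mean_arm1']:.3f}, O-/A mean {sc['mean_arm2']:.3f})")
print(f"score vs 0: {t['test_name']}  t={t['statistic']:.1f}  p={t['p_value']:.2e}")
print(f"preference trait: Vb={vc.Vb:.4f}  Vw={vc.Vw:.4f}  ->  t = {est.t:.2f}  (n = {est.n_used} lines)")
```

prints:

```
unconditioned orange-choice mean: 0.532 (200 trials)
conditioned orange-choice mean:   0.584 (200 trials)
learning score l = 0.209  (A-/O mean 0.689, O-/A mean 0.480)
score vs 0: one_sample_t  t=18.1  p=3.35e-33
preference trait: Vb=0.0080  Vw=0.0067  ->  t = 0.52  (n = 10 lines)
```

Read: flies choose orange slightly above chance without conditioning
(0.532); conditioning moves the apple-aversive arm up to 0.689 and the
orange-aversive arm down to 0.480, a learning score of 0.209 that is far
from zero (t-test p ≈ 3e-33); roughly half the variance in spontaneous
preference lies between lines (t = 0.52) in this simulated panel, whose
generating line-effect spread implies an ICC near 0.55.

The same analyses run from the shell on any trial CSV:

```
tmaze simulate --assay learning --mode inbred --seed 5 --out trials.csv
tmaze analyze-learning --input trials.csv --out-dir results --format both
tmaze heritability --input trials.csv --out-dir results
```

Files with other column layouts are adapted with a YAML column mapping
(`--mapping`); see `tmaze.ColumnMapping`.

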