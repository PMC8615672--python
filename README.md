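# actirhythm

Actigraphy-based sleep and circadian rest-activity rhythm analysis for
cohort studies, with the cross-sectional inferential protocol used to
relate rhythm robustness to cognitive outcomes in developmental
populations (e.g. Down syndrome vs typically developing groups across
childhood, adolescence and young adulthood).

Wrist actigraphs record movement counts in fixed epochs (30 s here).
From those counts, per participant, the package computes:

* **Sleep summaries** — per-epoch sleep/wake scoring by the weighted
  moving-average rule of the Actiwatch device family (centre weight 2,
  ±1–2 epochs 1/5, ±3–4 epochs 1/25; wake iff the weighted sum exceeds a
  threshold, default 40), inside diary-anchored nightly rest intervals:
  total sleep time (TST, min), wake after sleep onset (WASO, min) and
  sleep efficiency (SE = 100·TST/interval).
* **Phase markers** — daily activity onset/offset by step-template
  matching (the boundary best separating 5 h of inactivity from 5 h of
  activity on the median-binarized day), and acrophase/MESOR/amplitude
  from a per-day least-squares 24-h cosinor fit,
  `y(t) = M + A·cos(2π(t − φ)/24)`.
* **Non-parametric circadian statistics** (hourly bins) —
  interdaily stability `IS = N·Σ_h(x̄_h − x̄)² / (p·Σ_i(x_i − x̄)²)`
  (0–1; 1 = identical days), intradaily variability
  `IV = N·Σ(x_i − x_{i−1})² / ((N−1)·Σ(x_i − x̄)²)` (≈0 smooth, ≈2
  uncorrelated), the least-active 5-h and most-active 10-h window means
  (L5, M10) and relative amplitude `RA = (M10 − L5)/(M10 + L5)`.
* **Spectral rhythm strength** — the maximum relative (non-DC) power at
  periods between 18 and 30 h.

At the cohort level it runs the study protocol: Shapiro-gated two-factor
(diagnostic group × age band) **Freedman–Lane permutation ANOVAs** with
Type-II sums of squares (Kruskal–Wallis per factor when residuals are
non-normal) under step-down **Holm correction**, and forward-stepwise
**hierarchical linear models** of cognitive outcomes on IS with the
covariates SE, age, gender and recorded weekend days (outcome
transformation, >3 SD outlier exclusion, and an IS×age interaction kept
only if p ≤ 0.10 or it significantly improves R²).

A synthetic-cohort generator with full ground truth (nightly rest
intervals, arousal minutes, planted regression coefficients) makes every
stage testable end to end; its six presets are calibrated to the group
means of a published cross-sectional study.

## Worked example

```python
from actirhythm.simulate import STUDY_PRESETS, generate_cohort
from actirhythm.pipeline import RunConfig, run_pipeline

groups = [STUDY_PRESETS["children_DS"], STUDY_PRESETS["children_TD"]]
participants, cohort, truth = generate_cohort(groups, seed=7)
cfg = RunConfig(seed=7, stats={"n_perm": 999, "holm_family": "per_factor",
                               "interaction_alpha": 0.10})
result = run_pipeline(cfg, participants=participants, cohort=cohort)

print(result.summary.query("measure in ['TST','WASO','IS']").round(2))
print(result.contrasts.query("measure == 'WASO'"))
print(result.anovas.query("outcome == 'WASO'").round(4))
```

prints

```
measure group age_group  n   mean    sd
    TST    DS     child 20 459.19 13.65
   WASO    DS     child 20  89.10 13.65
     IS    DS     child 20   0.82  0.04
    TST    TD     child 20 480.68 10.75
   WASO    TD     child 20  53.47  9.44
     IS    TD     child 20   0.74  0.07

measure age_group  DS_mean  TD_mean  pct_diff
   WASO     child     89.1    53.47        67

outcome  term  statistic     p  p_holm      method
   WASO group    92.1952 0.001   0.011 permutation
```

Read: the two simulated groups of 20 children sleep a similar total
amount (TST 459 vs 481 min) but the DS group accumulates 67% more wake
after sleep onset (89 vs 53 min/night) while keeping higher interdaily
stability (0.82 vs 0.74); the permutation ANOVA flags the WASO group
difference (F = 92.2, Holm-corrected p = 0.011 — with 999 permutations
the smallest attainable raw p is 0.001).

The same run is available from a shell:

```bash
actirhythm simulate --group children_DS --n 20 --seed 7 --out data/
actirhythm analyze --config run.yaml
actirhythm report --run results/
```

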