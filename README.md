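# sceval

An evaluation toolkit for web-based **symptom checkers** (SCs) tested
with **clinical vignettes** — written scenarios with an expert gold
standard for the most-likely condition and a 9-level triage
recommendation.  Vignette studies use a handful of human testers to
translate each scenario into an SC consultation, which makes the
headline "accuracy" a composite of SC quality *and* tester behaviour.
`sceval` implements the analyses needed to take that composite apart:

* **tester regimes** — free interpretation, prescribed chief
  complaints (*partially free*), and prescribed complaints plus
  decline-unless-present answering (*restricted*);
* **agreement statistics** — Fleiss' κ across the tester panel and
  Cohen's κ for test–retest, with asymptotic standard errors, 95% CIs,
  p-values, Landis–Koch bands, and full/partial/no-agreement
  breakdowns;
* **crude accuracy** — per tester, panel mean with population SD, and
  the any-tester union, plus ANOVA / pooled-variance t comparisons
  between regimes;
* **fidelity auditing and adjusted accuracy** — every consultation is
  compared data point by data point with its vignette; cases where no
  tester's consultation was *identical* to the vignette are excluded
  (`Accuracy_Excluded`) or replaced by re-audited retests
  (`Accuracy_Retested`), isolating the SC's data/algorithm quality
  from tester error;
* **symptom comprehension** — a 2/1/0 rubric (exact meaning / broader
  logical category / incorrect) over phrasing variants of chief
  complaints, aggregated per SC, symptom or vignette;
* **a synthetic study simulator** — a deterministic toy symptom
  checker plus stochastic tester models, so every metric can be
  exercised with known ground truth and fully seeded reproducibility.

## The statistics, briefly

For N vignettes rated by R testers into nominal categories (condition
labels or the 9 triage levels; "no outcome" is its own category),
Fleiss' κ is

    κ = (P̄o − P̄e) / (1 − P̄e)

with P̄o the mean per-vignette pairwise agreement and P̄e = Σⱼ pⱼ² from
the pooled category proportions; the SE uses the Fleiss–Nee–Landis
large-sample variance.  Cohen's κ for two ratings uses
P̄e = Σⱼ p₊ⱼ pⱼ₊ and the Fleiss–Cohen–Everitt variance.  Degenerate
single-category data reports κ as *undefined* (P̄o = 1), never NaN.
A seeded percentile bootstrap CI is available as a sensitivity check.

Crude accuracy is the percentage of vignettes whose most-likely
condition (or triage) equals the gold standard; panel summaries use
the population SD (divisor n).  `Accuracy_Excluded` retains only cases
with at least one vignette-identical consultation and scores each from
its identical consultations; `Accuracy_Retested` restores the full
denominator with re-audited replacement consultations.

## Worked example

Simulate a restricted-regime study of 114 vignettes with 3 noisy
testers, then analyse it:

```sh
sceval simulate --config sim.yaml --out study.json
sceval agreement --study study.json --field condition
sceval accuracy  --study study.json --per-tester --any-tester
sceval adjusted  --study study.json
```

with `sim.yaml`:

```yaml
seed: 11
n_vignettes: 114
n_conditions: 12
n_symptoms: 30
regime: restricted
profiles:
  - {p_human_error: 0.1, p_misinterpret: 0.1, p_complaint_rephrase: 0.5}
  - {p_human_error: 0.1, p_misinterpret: 0.1, p_complaint_rephrase: 0.5}
  - {p_human_error: 0.1, p_misinterpret: 0.1, p_complaint_rephrase: 0.5}
```

This prints:

```
### Intertester agreement

| Group | Kappa (95% CI) | P value | Full agreement, n (%) | Partial agreement, n (%) | No agreement, n (%) |
| --- | --- | --- | --- | --- | --- |
| condition | 0.82 (0.79-0.85) | <.001 | 87 (76.3) | 24 (21.1) | 3 (2.6) |

### Most likely condition accuracy

| Measure | Accuracy (%) |
| --- | --- |
| tester1 | 91.2 |
| tester2 | 88.6 |
| tester3 | 92.1 |
| Average of 3 testers (SD) | 90.6 (1.49) |
| If any tester met the gold standard | 100.0 |
```

Reading this: the panel agrees "almost perfectly" on the top condition
(κ = 0.82), yet per-tester accuracy still spreads over ~3.5 points —
tester noise leaks into the composite metric.  `sceval adjusted` then
reports `"accuracy_excluded": 100.0` over the 61 cases in which at
least one tester's consultation was identical to the vignette: once
consultations that misrepresent the vignette are removed, the toy SC's
data/algorithm quality is recovered exactly (its intrinsic accuracy on
this world is 100%).  The gap between 90.6 and 100.0 is what the
audit-and-exclude step is designed to expose.

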