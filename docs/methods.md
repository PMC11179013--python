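# Methods

This note documents the models, estimators, conventions and design
choices behind `sceval`, and what the synthetic-study simulator does
and does not emulate.

## Study model

A *study* is a rectangular design: every tester processes every
vignette (optionally twice, for test–retest).  A vignette carries
demographics (age, sex), a coded symptom duration, a non-empty set of
symptom concepts, optional comorbidities, optional prescribed chief
complaints, and the expert gold standard: one condition code and one
of 9 ordered triage levels (`no_triage` … `emergency_ambulance`).  A
consultation records everything the tester entered — chief-complaint
strings, each answered symptom question (selected/declined, with an
optional *forced-choice* flag), duration, demographics, comorbidities
— and the SC's outcome: top condition, ranked condition list, triage.
An SC that returns nothing yields the `ABSENT` sentinel, which is a
real category for agreement (two empty outcomes agree) but never
matches a gold standard for accuracy.

Condition codes are opaque strings compared after surface
normalization (lowercase, collapsed whitespace, trailing punctuation
stripped); no semantic matching is attempted.  Duration, age, sex and
comorbidities are compared exactly — no tolerance is defined for them
anywhere in the pipeline.

The concept lexicon maps surface strings to concepts (each normalized
surface belongs to exactly one concept) and carries an acyclic
broader-category relation used transitively: "pain in knee" → "pain in
leg" → "lower limb".

## Agreement estimators

* **Fleiss' κ** (panel, nominal): P̄o is the mean per-subject pairwise
  agreement, P̄e = Σ pⱼ² from pooled category proportions.  The SE is
  the Fleiss–Nee–Landis large-sample form; it is used both for the
  κ = 0 test and for the 95% Wald CI.  This is one of several
  estimators in circulation (different software packages differ in
  their variance formulas); a seeded percentile bootstrap over
  subjects (`bootstrap=` argument) is provided so users can check
  sensitivity of the CI to that choice.
* **Cohen's κ** (two ratings, e.g. round 1 vs round 2 of the same
  tester): P̄e from the product of marginals; the CI uses the
  Fleiss–Cohen–Everitt variance around the estimate, the p-value the
  null-hypothesis variance.  The raw match proportion is reported
  alongside κ.
* **Triage κ is unweighted** despite the ordered scale: the study
  design reports a single nominal κ per Landis–Koch band, and
  introducing weights would change the estimand.  Landis–Koch bands
  use cut-points 0.20/0.40/0.60/0.80; κ < 0 is reported as
  `negative` (the published scale starts at 0).
* **Degenerate data**: if every rating falls in one category, P̄e = 1
  and κ is undefined.  This is signalled explicitly (`kappa is None`,
  P̄o = 1) rather than returned as 1.0 or NaN — perfect observed
  agreement with no category variation carries no chance-corrected
  information.
* **Category coding**: condition labels get positive integer codes in
  row-major first-appearance order per matrix (κ is invariant to
  labels); triage uses its fixed 1–9 codes; `ABSENT` is 0.
* **Chief-complaint agreement** reduces each tester's complaint list
  to a nominal category — the *multiset* of normalized strings at the
  exact-wording level, the *set* of resolved lexicon concepts at the
  concept level (unresolvable strings become unique pseudo-concepts)
  — and runs the same κ machinery on the resulting matrix.  This
  set-as-category coding is one defensible reading of how complaint
  agreement can be scored; it is a convention of this package, not a
  uniquely determined procedure.

## Accuracy conventions

Per-tester accuracy is 100 × hits / N with exact (normalized) equality
for conditions and exact 9-level equality for triage; no near-miss or
top-3 credit.  The panel summary reports the **population SD**
(divisor n): with a complete panel of testers, the panel is the whole
population of interest, and only this convention reproduces a
3-tester summary such as mean 50.6, SD 5.35 from (43.9, 50.9, 57.0);
the sample SD (6.56) is exposed as `sd_sample`.  Between-group
comparisons use one-way fixed-effects ANOVA and the pooled-variance
two-tailed Student t test.

## Fidelity audit and adjusted accuracy

The audit compares every recorded data point with the vignette:

* a **selected** symptom is compliant iff it is a vignette symptom, a
  lexicon synonym of one, or a transitive broader category of one
  (selecting "pain in leg" for a "pain in knee" vignette is
  faithful);
* a selected off-vignette symptom that shares a direct parent with a
  vignette symptom is classified `misinterpreted_symptom`; any other
  off-vignette selection is `added_symptom`;
* a vignette symptom never affirmed (directly, by synonym, or by a
  selected ancestor) is `missing_symptom`, whether it was explicitly
  declined or simply never asked;
* duration, age, sex and comorbidities must match exactly
  (`wrong_duration`, `wrong_demographic`, `wrong_comorbidity`);
* unresolvable raw strings and forced-choice answers are logged as
  `other` — forced answers are not tester errors, but a consultation
  containing one still failed to represent the vignette, so it is not
  *identical* and the case becomes a candidate for retesting.

`identical` ⇔ the discrepancy list is empty; the audit is
deterministic.

**Accuracy_Excluded** drops every case with zero identical
consultations and scores each retained case from its identical
consultations only, counting the case correct if **any** of them met
the gold standard.  The any-identical rule is the default because the
adjusted metric asks "did the SC get it right when it received the
vignette faithfully?", and any faithful consultation answers that
question; a `majority_identical` alternative is exposed for
sensitivity.  **Accuracy_Retested** restores the denominator to N:
every excluded case must supply at least one replacement consultation
that re-audits as identical (a still-discrepant retest is rejected
with its audit report attached), and is scored from those retests.

The cross-tab stratifies cases by the number of identical
consultations (0..R) against whether all testers agreed on *both*
condition and triage.

## Comprehension rubric

Each trial submits one phrasing variant of one chief-complaint concept
to one SC.  Scores: 2 if the returned concept is the intended one
(synonyms resolve to the same concept); 1 if it is a proper broader
category of it; 0 otherwise, including no return.  A manual judgment
stored on the trial always overrides the lexicon rule.  Aggregation is
raw points over 2 × trials, per SC / per symptom / per vignette.  Two
bookkeeping conventions coexist, matching how such studies report:
per-*symptom* totals score every symptom variant as its own 2-point
trial (51 symptoms × 3 variants ⇒ max 306), while per-*vignette*
totals treat the vignette's complaint set as the trial unit (29
vignettes × 3 variants ⇒ max 174).  The grouping machinery is
identical; only the trial unit supplied by the caller differs.

## The simulator

The simulator exists so that every metric has known ground truth; it
is not a clinical model.

* **World**: `n_symptoms` base concepts under a 3-level
  broader-category tree (4 siblings per parent), each with 3 synonym
  surfaces; `n_conditions` conditions draw 3–5 symptoms, sharing a
  common pool with probability `symptom_overlap` (distinct sets
  enforced; infeasible configurations are rejected).  Each vignette
  instantiates one condition's full symptom set with random
  demographics, a day-count duration, 0–2 comorbidities and 1–2
  prescribed complaints rendered as canonical synonym surfaces.
* **Toy SC**: top condition = argmax of
  `|answers ∩ S_c| − λ·|answers \ S_c|` (λ default 0.5), ties to the
  lexicographically smaller code, non-positive best score ⇒ `ABSENT`.
  It asks only about symptoms of conditions whose sets intersect the
  chief complaints — this candidate-driven questioning is what makes
  the complaint choice matter, the mechanism the regimes control.
* **Tester noise** (per question): `p_human_error` flips an answer;
  `p_misinterpret` swaps a present symptom for a random sibling
  (and, outside the restricted regime, also lets a tester
  over-affirm a sibling of a vignette symptom — only restricted
  testers are instructed to decline anything not written in the
  vignette).  Free testers choose 1–3 complaint symptoms themselves,
  can misread each as a sibling at `p_misinterpret`, and rephrase via
  synonyms at `p_complaint_rephrase`.  Transcription of the duration
  slips by ±1 day at `p_human_error`.
* **Defaults** (`symptom_overlap=0.6`, `p_human_error=0.05`,
  `p_misinterpret=0.05`, `p_complaint_rephrase=0.5`, 114 vignettes ×
  3 testers): chosen once as order-of-magnitude values that produce a
  qualitatively realistic study — substantial-but-imperfect panel
  agreement and visible accuracy spread.  No quantitative tester
  error rates are available to calibrate against, so these defaults
  are validated only by qualitative behaviour (noise monotonicity,
  regime ordering), never by matching printed κ values.
* **Reproducibility**: each tester × vignette × round consultation
  uses RNG stream `[seed, tester, vignette, round]`, so the same seed
  gives a byte-identical study and adding testers or rounds never
  perturbs existing draws.  Round 2 is an independent redraw with the
  same profile (no drift term — a 6-month gap is modelled as fresh
  noise).

What the simulator does **not** emulate: real SC question-flow logic
and UI forced-choice structure (beyond the `forced` flag), NLP
misparsing of free text, tester learning or fatigue between rounds,
and clinically meaningful symptom semantics.  A passing pipeline on
simulated data therefore demonstrates the *statistical machinery* —
estimators, audit rules, bookkeeping — under controlled conditions,
not the performance of any real symptom checker.

## Problem sizes and numerical choices

Monte-Carlo checks use replicated small studies (20–40 vignettes × 3
testers, 60–200 replicates), which keeps the whole suite and the
acceptance script to a few seconds while leaving the qualitative
orderings far outside Monte-Carlo noise.  The independence check for
κ ≈ 0 uses 10 000 subjects and a 3·SE band.  Wald CIs use
z = 1.959964; percentage output is rounded to 1 decimal and κ to 2
decimals only at report time (JSON output keeps full precision).
Degenerate inputs (single-category matrices, empty answer sets,
all-cases-excluded adjustments) raise explicit, typed errors or
explicit undefined results rather than propagating NaN.

## Known limitations

* The Fleiss-type SE is asymptotic; for very small N (e.g. a handful
  of vignettes) the bootstrap CI option is the better guide.
* The audit cannot distinguish a deliberate addition from a
  misinterpretation when the added concept happens to neighbour a
  vignette symptom; category counts for those two channels are
  therefore approximate attributions.
* Complaint-agreement coding treats each distinct complaint set as
  its own category; with many unique sets, chance agreement is tiny
  and κ can be strongly negative — a property of the coding, to be
  interpreted qualitatively.
* CSV-bundle metadata survives a round trip only for
  JSON-serializable values.
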