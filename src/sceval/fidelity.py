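"""The review-and-selection procedure: fidelity auditing and adjusted accuracy.

Crude accuracy confounds the SC's data/algorithm quality with tester
behaviour.  To isolate the former, every consultation is audited
against its vignette: each recorded data point (chief complaints,
selected and declined symptoms, duration, demographics, comorbidities)
is compared with what the vignette actually says, and every deviation
is logged as a categorized discrepancy.  A consultation with no
discrepancies is *identical* to the vignette — the SC received exactly
the case the experts wrote.

Adjusted accuracy then comes in two flavours:

* ``accuracy_excluded`` drops every case in which none of the testers
  produced an identical consultation and scores the remaining cases
  from their identical consultations only;
* ``accuracy_retested`` restores the full denominator by scoring the
  dropped cases from externally supplied, re-audited retest
  consultations.

Compliance rules for symptoms follow the restricted-tester
instructions: a selected symptom is compliant when it is in the
vignette, is a lexicon synonym of a vignette symptom, or is a broader
category (transitive ancestor) of one; a declined symptom is compliant
when the vignette does not contain it.  A selected symptom that is a
sibling of a vignette symptom (shares its direct parent) is classified
``misinterpreted_symptom``; any other off-vignette selection is
``added_symptom``.  Duration, age, sex and comorbidities must match
exactly.  Forced-choice answers (no compliant option existed) are not
tester errors but still make the consultation non-identical; they are
logged with category ``other``.

The audit is deterministic: the same consultation and vignette always
produce the same report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .types import (
    ABSENT,
    ConceptLexicon,
    ConsultationRecord,
    StudyDataset,
    ValidationError,
    Vignette,
    normalize_surface,
)

DISCREPANCY_CATEGORIES = (
    "missing_symptom",
    "added_symptom",
    "misinterpreted_symptom",
    "wrong_duration",
    "wrong_demographic",
    "wrong_comorbidity",
    "other",
)


@dataclass
class Discrepancy:
    """One audited deviation of a consultation from its vignette."""

    category: str
    detail: str
    concept: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in DISCREPANCY_CATEGORIES:
            raise ValidationError(
                f"unknown discrepancy category {self.category!r}; "
                f"must be one of {DISCREPANCY_CATEGORIES}"
            )


@dataclass
class DiscrepancyReport:
    """Audit result for one consultation; identical <=> no discrepancies."""

    vignette_id: str
    tester_id: str
    discrepancies: list[Discrepancy] = field(default_factory=list)

    @property
    def identical(self) -> bool:
        return not self.discrepancies


@dataclass
class FidelityCrossTab:
    """Cases cross-tabulated by outcome agreement x number of identical consultations.

    ``counts[row][k]`` with row in {"all_match", "not_all_match"} and k
    the number of testers whose consultation was identical to the
    vignette (0..n_testers).
    """

    counts: dict[str, list[int]]
    n_testers: int

    @property
    def total(self) -> int:
        return sum(sum(v) for v in self.counts.values())

    def cell(self, row: str, k: int) -> int:
        return self.counts[row][k]

    def cell_pct(self, row: str, k: int) -> float:
        return 100.0 * self.counts[row][k] / self.total

    def column_totals(self) -> list[int]:
        return [
            sum(self.counts[r][k] for r in self.counts)
            for k in range(self.n_testers + 1)
        ]

    def row_total(self, row: str) -> int:
        return sum(self.counts[row])


@dataclass
class AdjustedAccuracyResult:
    """An adjusted accuracy with the case bookkeeping behind it."""

    accuracy: float
    n_cases: int          # denominator actually used
    n_correct: int
    excluded_case_ids: list[str]
    retested_case_ids: list[str] = field(default_factory=list)
    metric: str = "accuracy_excluded"


class RetestDiscrepancyError(ValidationError):
    """A supplied retest consultation still deviates from its vignette."""

    def __init__(self, report: DiscrepancyReport):
        self.report = report
        cats = ", ".join(d.category for d in report.discrepancies)
        super().__init__(
            f"retest for vignette {report.vignette_id!r} by "
            f"{report.tester_id!r} is still discrepant ({cats})"
        )


def _resolve(lex: ConceptLexicon, raw: str) -> Optional[str]:
    if raw in lex.concepts:
        return raw
    return lex.resolve(raw)


def _covers(lex: ConceptLexicon, selected: str, target: str) -> bool:
    """True if selecting *selected* is a faithful representation of *target*."""
    return selected == target or lex.is_ancestor(selected, target)


def check_fidelity(
    c: ConsultationRecord, v: Vignette, lex: ConceptLexicon
) -> DiscrepancyReport:
    """Audit one consultation against its vignette.

    Returns a :class:`DiscrepancyReport`; ``report.identical`` is True
    iff every recorded data point faithfully reproduces the vignette.
    """
    if c.vignette_id != v.id:
        raise ValidationError(
            f"consultation references vignette {c.vignette_id!r}, not {v.id!r}"
        )
    report = DiscrepancyReport(vignette_id=v.id, tester_id=c.tester_id)
    disc = report.discrepancies

    # --- resolve everything the tester affirmed ---------------------------
    selected: list[tuple[str, str, bool]] = []  # (concept-or-pseudo, source, forced)
    for s in c.entered_complaints:
        concept = _resolve(lex, s)
        if concept is None:
            selected.append((f"unresolved::{normalize_surface(s)}", s, False))
        else:
            selected.append((concept, s, False))
    declined: list[str] = []
    for a in c.answered_symptoms:
        concept = _resolve(lex, a.concept)
        if a.answer == "selected":
            if concept is None:
                selected.append((f"unresolved::{normalize_surface(a.concept)}", a.concept, a.forced))
            else:
                selected.append((concept, a.concept, a.forced))
        else:
            if concept is not None:
                declined.append(concept)

    selected_concepts = {concept for concept, _, _ in selected}

    # --- selected symptoms: on-vignette, broader category, or violation ---
    flagged: set[str] = set()
    for concept, raw, forced in selected:
        if forced:
            disc.append(
                Discrepancy(
                    "other",
                    f"forced-choice answer {raw!r}: no vignette-compliant option",
                    concept=concept,
                )
            )
            continue
        if concept in flagged:
            continue
        if concept.startswith("unresolved::"):
            flagged.add(concept)
            disc.append(
                Discrepancy(
                    "other",
                    f"selected symptom {raw!r} has no lexicon entry",
                    concept=None,
                )
            )
            continue
        if any(_covers(lex, concept, t) for t in v.symptoms):
            continue
        flagged.add(concept)
        if any(
            lex.parent.get(concept) is not None
            and lex.parent.get(concept) == lex.parent.get(t)
            for t in v.symptoms
        ):
            disc.append(
                Discrepancy(
                    "misinterpreted_symptom",
                    f"selected {raw!r}, a sibling of a vignette symptom",
                    concept=concept,
                )
            )
        else:
            disc.append(
                Discrepancy(
                    "added_symptom",
                    f"selected {raw!r}, not described in the vignette",
                    concept=concept,
                )
            )

    # --- vignette symptoms the consultation never affirmed ----------------
    for t in sorted(v.symptoms):
        covered = any(_covers(lex, s, t) for s in selected_concepts if not s.startswith("unresolved::"))
        if not covered:
            how = "declined" if t in declined else "never affirmed"
            disc.append(
                Discrepancy(
                    "missing_symptom",
                    f"vignette symptom {t!r} {how} during the consultation",
                    concept=t,
                )
            )

    # --- exact-match data points ------------------------------------------
    if _datapoint(c.entered_duration) != _datapoint(v.duration):
        disc.append(
            Discrepancy(
                "wrong_duration",
                f"entered duration {c.entered_duration!r} != vignette {v.duration!r}",
            )
        )
    if c.entered_age != v.age:
        disc.append(
            Discrepancy(
                "wrong_demographic", f"entered age {c.entered_age} != vignette {v.age}"
            )
        )
    if normalize_surface(str(c.entered_sex)) != normalize_surface(str(v.sex)):
        disc.append(
            Discrepancy(
                "wrong_demographic",
                f"entered sex {c.entered_sex!r} != vignette {v.sex!r}",
            )
        )
    for extra in sorted(c.entered_comorbidities - v.comorbidities):
        disc.append(
            Discrepancy(
                "wrong_comorbidity", f"comorbidity {extra!r} not in vignette", concept=extra
            )
        )
    for missing in sorted(v.comorbidities - c.entered_comorbidities):
        disc.append(
            Discrepancy(
                "wrong_comorbidity", f"vignette comorbidity {missing!r} not entered", concept=missing
            )
        )
    return report


def _datapoint(x):
    """Exact comparison key for duration-like coded values."""
    return normalize_surface(str(x))


def audit_study(
    ds: StudyDataset, round: int = 1
) -> dict[tuple[str, str], DiscrepancyReport]:
    """Audit every round-*round* consultation; keys are (tester_id, vignette_id)."""
    out = {}
    for c in ds.consultations:
        if c.round != round:
            continue
        out[(c.tester_id, c.vignette_id)] = check_fidelity(
            c, ds.vignettes[c.vignette_id], ds.lexicon
        )
    return out


def _outcomes_equal(a, b) -> bool:
    if a is ABSENT or b is ABSENT:
        return a is ABSENT and b is ABSENT
    return a == b


def _condition_key(c):
    return ABSENT if c.outcome_condition is ABSENT else normalize_surface(str(c.outcome_condition))


def _all_match(consults: Sequence[ConsultationRecord]) -> bool:
    """All testers agree on BOTH most-likely condition and triage."""
    conds = [_condition_key(c) for c in consults]
    triages = [c.outcome_triage for c in consults]
    return all(_outcomes_equal(conds[0], x) for x in conds[1:]) and all(
        _outcomes_equal(triages[0], x) for x in triages[1:]
    )


def build_crosstab(
    ds: StudyDataset,
    reports: dict[tuple[str, str], DiscrepancyReport],
    round: int = 1,
) -> FidelityCrossTab:
    """Cross-tabulate cases by outcome agreement x number of identical consultations."""
    testers = ds.testers()
    ds.require_rectangular(round=round)
    counts = {
        "not_all_match": [0] * (len(testers) + 1),
        "all_match": [0] * (len(testers) + 1),
    }
    for vid in ds.vignettes:
        consults = [ds.consultation(t, vid, round) for t in testers]
        k = sum(1 for t in testers if reports[(t, vid)].identical)
        row = "all_match" if _all_match(consults) else "not_all_match"
        counts[row][k] += 1
    return FidelityCrossTab(counts=counts, n_testers=len(testers))


def _case_correct_from_identical(
    ds: StudyDataset,
    vid: str,
    reports,
    target: str,
    round: int,
    rule: str,
) -> bool:
    """Score one retained case from its identical consultations only."""
    from .accuracy import _matches_gold

    v = ds.vignettes[vid]
    identical = [
        ds.consultation(t, vid, round)
        for t in ds.testers()
        if reports[(t, vid)].identical
    ]
    if rule == "any_identical":
        return any(_matches_gold(c, v, target) for c in identical)
    if rule == "majority_identical":
        hits = sum(1 for c in identical if _matches_gold(c, v, target))
        return hits * 2 > len(identical)
    raise ValueError("rule must be 'any_identical' or 'majority_identical'")


def excluded_cases(
    ds: StudyDataset,
    reports: dict[tuple[str, str], DiscrepancyReport],
    round: int = 1,
) -> list[str]:
    """Vignette ids where no tester's consultation was identical to the vignette."""
    testers = ds.testers()
    return [
        vid
        for vid in ds.vignettes
        if not any(reports[(t, vid)].identical for t in testers)
    ]


def accuracy_excluded(
    ds: StudyDataset,
    reports: dict[tuple[str, str], DiscrepancyReport],
    target: str = "condition",
    round: int = 1,
    rule: str = "any_identical",
) -> AdjustedAccuracyResult:
    """Adjusted accuracy after dropping cases with no identical consultation.

    A retained case counts as correct iff an identical consultation
    produced the gold outcome (``rule="any_identical"``, the default;
    ``"majority_identical"`` is exposed for sensitivity).
    """
    ds.require_rectangular(round=round)
    excluded = excluded_cases(ds, reports, round)
    retained = [vid for vid in ds.vignettes if vid not in set(excluded)]
    if not retained:
        raise ValidationError("every case was excluded; adjusted accuracy undefined")
    correct = sum(
        1
        for vid in retained
        if _case_correct_from_identical(ds, vid, reports, target, round, rule)
    )
    return AdjustedAccuracyResult(
        accuracy=100.0 * correct / len(retained),
        n_cases=len(retained),
        n_correct=correct,
        excluded_case_ids=excluded,
        metric="accuracy_excluded",
    )


def accuracy_retested(
    ds: StudyDataset,
    reports: dict[tuple[str, str], DiscrepancyReport],
    retests: Sequence[ConsultationRecord],
    target: str = "condition",
    round: int = 1,
    rule: str = "any_identical",
) -> AdjustedAccuracyResult:
    """Adjusted accuracy with excluded cases scored from retest consultations.

    Every excluded case needs at least one retest that re-audits as
    identical; a still-discrepant retest raises
    :class:`RetestDiscrepancyError` carrying its report.  The
    denominator is restored to the full case count.
    """
    ds.require_rectangular(round=round)
    excluded = set(excluded_cases(ds, reports, round))
    from .accuracy import _matches_gold

    retest_ok: dict[str, list[ConsultationRecord]] = {}
    for r in retests:
        if r.vignette_id not in ds.vignettes:
            raise ValidationError(f"retest references unknown vignette {r.vignette_id!r}")
        rep = check_fidelity(r, ds.vignettes[r.vignette_id], ds.lexicon)
        if not rep.identical:
            raise RetestDiscrepancyError(rep)
        retest_ok.setdefault(r.vignette_id, []).append(r)
    missing = sorted(excluded - set(retest_ok))
    if missing:
        raise ValidationError(
            f"excluded cases lack an identical retest: {', '.join(missing[:5])}"
        )
    correct = 0
    for vid in ds.vignettes:
        v = ds.vignettes[vid]
        if vid in excluded:
            if any(_matches_gold(r, v, target) for r in retest_ok[vid]):
                correct += 1
        elif _case_correct_from_identical(ds, vid, reports, target, round, rule):
            correct += 1
    n = len(ds.vignettes)
    return AdjustedAccuracyResult(
        accuracy=100.0 * correct / n,
        n_cases=n,
        n_correct=correct,
        excluded_case_ids=sorted(excluded),
        retested_case_ids=sorted(excluded),
        metric="accuracy_retested",
    )
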