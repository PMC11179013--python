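"""Isolated symptom-comprehension scoring.

Symptom comprehension is the SC's ability to understand the chief
complaint the user typed or picked — in isolation from the rest of the
consultation.  Each trial submits one phrasing variant of one symptom
concept to one SC and records the concept the SC returned.  Trials are
scored on a 3-point rubric:

* 2 — the exact symptom was detected or the same meaning conveyed
  (the returned concept equals the intended one, including via
  lexicon synonyms);
* 1 — a broader logical category was offered (the returned concept is
  a proper ancestor of the intended one), which still lets the SC ask
  the right follow-up questions;
* 0 — an incorrect symptom, or nothing, came back.

Scores aggregate per SC, per symptom, or per vignette (pooling the
trials of all the vignette's symptoms) as ``raw / max`` percentages,
with ``max = 2 x number of trials`` in the group.  A manual judgment
recorded on a trial always overrides the automatic lexicon rule, so
studies without a machine-readable concept mapping remain scorable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .types import ABSENT, ConceptLexicon, ValidationError, _AbsentType

INPUT_METHODS = ("nlp_free_text", "dropdown")


@dataclass
class ComprehensionTrial:
    """One chief-complaint variant submitted to one SC."""

    sc_id: str
    symptom_concept: str
    variant_text: str
    input_method: str
    returned_concept: Union[str, _AbsentType]
    judged: Optional[int] = None  # manual MatchLevel override

    def __post_init__(self) -> None:
        if not self.variant_text:
            raise ValidationError("variant_text must be non-empty")
        if self.input_method not in INPUT_METHODS:
            raise ValidationError(
                f"input_method must be one of {INPUT_METHODS}, got {self.input_method!r}"
            )
        if self.judged is not None and self.judged not in (0, 1, 2):
            raise ValidationError("judged override must be 0, 1 or 2")


@dataclass
class ComprehensionScore:
    """Rubric points accumulated over one group of trials."""

    group: tuple
    raw: int
    max: int
    n_trials: int
    grouping: str

    @property
    def percent(self) -> float:
        return 100.0 * self.raw / self.max


def judge_match(
    intended: str,
    returned: Union[str, _AbsentType],
    lex: ConceptLexicon,
) -> int:
    """Apply the 2/1/0 comprehension rubric to one returned concept.

    2 when *returned* is the intended concept (or a lexicon synonym of
    it resolves there); 1 when it is a proper broader category
    (transitive ancestor) of the intended concept; 0 otherwise,
    including when the SC returned nothing.  A returned concept the
    lexicon does not know scores 0 with a warning rather than raising.
    """
    if intended not in lex.concepts and lex.resolve(intended) is None:
        raise ValidationError(f"intended concept {intended!r} is not in the lexicon")
    intended = intended if intended in lex.concepts else lex.resolve(intended)
    if returned is ABSENT:
        return 0
    concept = returned if returned in lex.concepts else lex.resolve(str(returned))
    if concept is None:
        warnings.warn(
            f"returned concept {returned!r} is not in the lexicon; scoring 0",
            stacklevel=2,
        )
        return 0
    if concept == intended:
        return 2
    if lex.is_ancestor(concept, intended):
        return 1
    return 0


def score_trial(trial: ComprehensionTrial, lex: ConceptLexicon) -> int:
    """Rubric score for one trial; a manual ``judged`` override wins."""
    if trial.judged is not None:
        return trial.judged
    return judge_match(trial.symptom_concept, trial.returned_concept, lex)


def score_trials(
    trials: Sequence[ComprehensionTrial],
    lex: ConceptLexicon,
    group_by: str = "sc",
    vignette_map: Optional[dict[str, str]] = None,
) -> list[ComprehensionScore]:
    """Aggregate rubric scores over groups of trials.

    ``group_by`` is ``"sc"`` (one total per symptom checker),
    ``"sc_and_symptom"`` or ``"sc_and_vignette"``; the latter needs
    *vignette_map* (symptom concept -> vignette id) and pools all of a
    vignette's symptom trials, each still worth up to 2 points.
    """
    if not trials:
        raise ValidationError("score_trials needs at least one trial")
    if group_by not in ("sc", "sc_and_symptom", "sc_and_vignette"):
        raise ValueError("group_by must be 'sc', 'sc_and_symptom' or 'sc_and_vignette'")
    if group_by == "sc_and_vignette" and vignette_map is None:
        raise ValidationError("per-vignette grouping needs a vignette_map")

    groups: dict[tuple, list[int]] = {}
    for t in trials:
        if group_by == "sc":
            key = (t.sc_id,)
        elif group_by == "sc_and_symptom":
            key = (t.sc_id, t.symptom_concept)
        else:
            vid = vignette_map.get(t.symptom_concept)
            if vid is None:
                warnings.warn(
                    f"symptom {t.symptom_concept!r} has no vignette mapping; "
                    "trial omitted from per-vignette scores",
                    stacklevel=2,
                )
                continue
            key = (t.sc_id, vid)
        groups.setdefault(key, []).append(score_trial(t, lex))

    return [
        ComprehensionScore(
            group=key,
            raw=sum(scores),
            max=2 * len(scores),
            n_trials=len(scores),
            grouping=group_by,
        )
        for key, scores in sorted(groups.items())
    ]
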