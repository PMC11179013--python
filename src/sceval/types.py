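"""Core domain types for symptom-checker vignette studies.

A vignette study evaluates a web-based symptom checker (SC) by having
human testers translate short written clinical scenarios (vignettes)
into SC consultations and recording the SC's most-likely condition and
triage recommendation.  This module defines the shared vocabulary:
the 9-level triage scale, the concept lexicon (synonyms plus a
broader-category hierarchy), vignettes, per-tester consultation
records, and the study container that ties them together.

``ABSENT`` is the sentinel for "the SC returned no condition / no
triage".  It is a distinct category in agreement analyses (two testers
who both got no outcome agree with each other) but it never matches a
gold-standard condition when scoring accuracy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Union


class ValidationError(ValueError):
    """A study file or in-memory object violates the schema."""


class IncompleteDesignError(ValidationError):
    """An analysis requiring a rectangular tester x vignette design found holes."""


class _AbsentType:
    """Singleton sentinel for a consultation that produced no outcome."""

    __slots__ = ()
    _instance: Optional["_AbsentType"] = None

    def __new__(cls) -> "_AbsentType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSENT"

    def __bool__(self) -> bool:
        return False

    def __copy__(self) -> "_AbsentType":
        return self

    def __deepcopy__(self, memo: dict) -> "_AbsentType":
        return self


ABSENT = _AbsentType()

#: Type of an outcome slot: a real value or the ABSENT sentinel.
MaybeAbsent = Union[str, _AbsentType]

_WS = re.compile(r"\s+")
_TRAILING_PUNCT = " \t.,;:!?"


def normalize_surface(s: str) -> str:
    """Canonicalize a surface string for comparison.

    Lowercases, collapses internal whitespace, strips surrounding
    whitespace and trailing punctuation.  Idempotent:
    ``normalize_surface(normalize_surface(x)) == normalize_surface(x)``.
    """
    s = _WS.sub(" ", s.strip()).lower()
    return s.rstrip(_TRAILING_PUNCT)


class TriageLevel(IntEnum):
    """The 9-level ordered triage scale, least to most urgent."""

    NO_TRIAGE = 1
    SEE_A_PHYSICIAN = 2
    SELF_LIMITING = 3
    SELF_CARE = 4
    ROUTINE = 5
    URGENT_48H = 6
    URGENT_12H = 7
    EMERGENCY_DEPARTMENT = 8
    EMERGENCY_AMBULANCE = 9

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def labels(cls) -> list[str]:
        return [lvl.name.lower() for lvl in cls]

    @classmethod
    def from_label(cls, label: str) -> "TriageLevel":
        key = normalize_surface(label).replace(" ", "_").replace("-", "_")
        try:
            return cls[key.upper()]
        except KeyError:
            raise ValidationError(
                f"unknown triage label {label!r}; the 9 legal labels are: "
                + ", ".join(cls.labels())
            ) from None


REGIMES = ("free", "partially_free", "restricted")


@dataclass
class ConceptLexicon:
    """Clinical concept dictionary: synonyms and a broader-category hierarchy.

    Parameters
    ----------
    concepts
        Set of opaque concept identifiers.
    synonyms
        Map concept -> surface strings that express it.  Every surface
        string must resolve to exactly one concept after
        :func:`normalize_surface`.
    parent
        Partial map concept -> broader-category concept ("pain in knee"
        -> "pain in leg").  Must be acyclic; chains may be several
        levels deep.
    """

    concepts: set[str]
    synonyms: dict[str, set[str]] = field(default_factory=dict)
    parent: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concepts = set(self.concepts)
        self.synonyms = {c: set(s) for c, s in self.synonyms.items()}
        for c in list(self.synonyms) + list(self.parent):
            if c not in self.concepts:
                raise ValidationError(f"lexicon entry for unknown concept {c!r}")
        for c, p in self.parent.items():
            if p not in self.concepts:
                raise ValidationError(f"parent {p!r} of {c!r} is not a concept")
        self._check_acyclic()
        self._surface_index: dict[str, str] = {}
        for c in sorted(self.concepts):
            self._claim_surface(normalize_surface(c), c)
        for c in sorted(self.synonyms):
            for s in sorted(self.synonyms[c]):
                self._claim_surface(normalize_surface(s), c)

    def _claim_surface(self, surface: str, concept: str) -> None:
        owner = self._surface_index.setdefault(surface, concept)
        if owner != concept:
            raise ValidationError(
                f"surface {surface!r} is ambiguous between concepts "
                f"{owner!r} and {concept!r}"
            )

    def _check_acyclic(self) -> None:
        for start in self.parent:
            seen = {start}
            node = start
            while node in self.parent:
                node = self.parent[node]
                if node in seen:
                    raise ValidationError(
                        f"cycle in lexicon broader-category chain at {node!r}"
                    )
                seen.add(node)

    def resolve(self, surface: str) -> Optional[str]:
        """Map a surface string to its concept, or ``None`` if unknown."""
        return self._surface_index.get(normalize_surface(surface))

    def ancestors(self, concept: str) -> list[str]:
        """Proper ancestors of *concept*, nearest first."""
        out: list[str] = []
        node = concept
        while node in self.parent:
            node = self.parent[node]
            out.append(node)
        return out

    def is_ancestor(self, ancestor: str, concept: str) -> bool:
        """True iff *ancestor* is a proper broader category of *concept*."""
        return ancestor in self.ancestors(concept)

    def siblings(self, concept: str) -> list[str]:
        """Concepts sharing a direct parent with *concept* (excluding it)."""
        p = self.parent.get(concept)
        if p is None:
            return []
        return sorted(c for c in self.parent if self.parent[c] == p and c != concept)

    def canonical_surface(self, concept: str) -> str:
        """A deterministic surface string for *concept* (first synonym, else the id)."""
        syns = self.synonyms.get(concept)
        if syns:
            return min(syns)
        return concept


@dataclass
class Vignette:
    """One clinical scenario with its expert gold standard."""

    id: str
    age: int
    sex: str
    duration: Union[int, str]
    symptoms: set[str]
    gold_condition: str
    gold_triage: TriageLevel
    comorbidities: set[str] = field(default_factory=set)
    prescribed_complaints: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.symptoms = set(self.symptoms)
        self.comorbidities = set(self.comorbidities)
        if not isinstance(self.gold_triage, TriageLevel):
            self.gold_triage = TriageLevel.from_label(str(self.gold_triage))
        if not isinstance(self.age, int) or self.age <= 0:
            raise ValidationError(f"vignette {self.id!r}: age must be a positive integer")
        if not self.symptoms:
            raise ValidationError(f"vignette {self.id!r}: symptoms must be non-empty")
        if self.prescribed_complaints is not None and not self.prescribed_complaints:
            raise ValidationError(
                f"vignette {self.id!r}: prescribed_complaints, when given, must be non-empty"
            )


@dataclass
class AnsweredSymptom:
    """One answered SC question: the concept (or raw string) and the answer.

    ``forced`` marks a forced-choice question where no vignette-compliant
    answer existed (e.g. dry vs productive cough when the vignette does
    not say); the fidelity audit logs these separately from genuine
    tester errors.
    """

    concept: str
    answer: str  # "selected" | "declined"
    forced: bool = False

    def __post_init__(self) -> None:
        if self.answer not in ("selected", "declined"):
            raise ValidationError(
                f"answer must be 'selected' or 'declined', got {self.answer!r}"
            )


@dataclass
class ConsultationRecord:
    """One tester's pass through one vignette on one SC."""

    vignette_id: str
    tester_id: str
    round: int
    regime: str
    entered_complaints: list[str]
    answered_symptoms: list[AnsweredSymptom]
    entered_duration: Union[int, str]
    entered_age: int
    entered_sex: str
    outcome_condition: MaybeAbsent
    outcome_triage: Union[TriageLevel, _AbsentType]
    entered_comorbidities: set[str] = field(default_factory=set)
    outcome_condition_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entered_comorbidities = set(self.entered_comorbidities)
        if self.round not in (1, 2):
            raise ValidationError(
                f"consultation {self.tester_id}/{self.vignette_id}: round must be 1 or 2"
            )
        if self.regime not in REGIMES:
            raise ValidationError(
                f"consultation {self.tester_id}/{self.vignette_id}: "
                f"regime must be one of {REGIMES}, got {self.regime!r}"
            )
        if not isinstance(self.outcome_triage, (TriageLevel, _AbsentType)):
            self.outcome_triage = TriageLevel.from_label(str(self.outcome_triage))

    def selected_concepts(self, lexicon: ConceptLexicon) -> set[str]:
        """All concepts the tester affirmed: chief complaints plus selected answers.

        Strings that do not resolve in the lexicon are kept verbatim
        (prefixed) so they are never silently dropped.
        """
        out: set[str] = set()
        for s in self.entered_complaints:
            out.add(lexicon.resolve(s) or f"unresolved::{normalize_surface(s)}")
        for a in self.answered_symptoms:
            if a.answer == "selected":
                out.add(lexicon.resolve(a.concept) or f"unresolved::{normalize_surface(a.concept)}")
        return out


@dataclass
class StudyDataset:
    """A full study: vignettes, consultations, lexicon, and metadata."""

    vignettes: dict[str, Vignette]
    consultations: list[ConsultationRecord]
    lexicon: ConceptLexicon
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for vid, v in self.vignettes.items():
            if v.id != vid:
                raise ValidationError(f"vignette key {vid!r} != vignette id {v.id!r}")
        for c in self.consultations:
            if c.vignette_id not in self.vignettes:
                raise ValidationError(
                    f"consultation by {c.tester_id!r} references missing "
                    f"vignette {c.vignette_id!r}"
                )

    def testers(self) -> list[str]:
        return sorted({c.tester_id for c in self.consultations})

    def rounds(self) -> list[int]:
        return sorted({c.round for c in self.consultations})

    def consultation(
        self, tester_id: str, vignette_id: str, round: int = 1
    ) -> Optional[ConsultationRecord]:
        for c in self.consultations:
            if (
                c.tester_id == tester_id
                and c.vignette_id == vignette_id
                and c.round == round
            ):
                return c
        return None

    def require_rectangular(self, round: int = 1, testers: Optional[Iterable[str]] = None) -> None:
        """Raise :class:`IncompleteDesignError` unless every tester saw every vignette."""
        testers = list(testers) if testers is not None else self.testers()
        seen = {
            (c.tester_id, c.vignette_id)
            for c in self.consultations
            if c.round == round and c.tester_id in set(testers)
        }
        missing = [
            (t, vid)
            for t in testers
            for vid in self.vignettes
            if (t, vid) not in seen
        ]
        if missing:
            head = ", ".join(f"{t}x{vid}" for t, vid in missing[:5])
            raise IncompleteDesignError(
                f"round {round} design is not rectangular; {len(missing)} "
                f"missing tester x vignette cells (first: {head})"
            )
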