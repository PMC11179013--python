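"""Shared fixtures: a hand-built clinical lexicon, a tiny study, and
session-scoped simulated studies."""

from __future__ import annotations

import pytest

from sceval.types import (
    ABSENT,
    AnsweredSymptom,
    ConceptLexicon,
    ConsultationRecord,
    StudyDataset,
    TriageLevel,
    Vignette,
)
from sceval.simulator import SimConfig, TesterProfile, simulate_study

ZERO_NOISE = dict(p_human_error=0.0, p_misinterpret=0.0, p_complaint_rephrase=0.0)


@pytest.fixture(scope="session")
def clinical_lexicon() -> ConceptLexicon:
    """Small hand-built lexicon exercising synonyms and a 3-level hierarchy."""
    return ConceptLexicon(
        concepts={
            "lower limb",
            "pain in leg",
            "pain in knee",
            "pain in hip",
            "pain on walking",
            "abdominal pain",
            "lower abdominal pain",
            "upper abdominal pain",
            "passing too much urine",
            "burning on passing urine",
            "headache",
            "fever",
        },
        synonyms={
            "abdominal pain": {"tummy ache", "pain in the abdomen"},
            "lower abdominal pain": {"lower tummy pain"},
            "pain in knee": {"knee pain"},
            "headache": {"head ache", "pain in the head"},
        },
        parent={
            "pain in leg": "lower limb",
            "pain on walking": "lower limb",
            "pain in knee": "pain in leg",
            "pain in hip": "pain in leg",
            "lower abdominal pain": "abdominal pain",
            "upper abdominal pain": "abdominal pain",
        },
    )


def make_consultation(vignette: Vignette, tester_id: str, **overrides) -> ConsultationRecord:
    """A consultation that exactly mirrors *vignette* unless overridden."""
    base = dict(
        vignette_id=vignette.id,
        tester_id=tester_id,
        round=1,
        regime="restricted",
        entered_complaints=sorted(vignette.symptoms),
        answered_symptoms=[],
        entered_duration=vignette.duration,
        entered_age=vignette.age,
        entered_sex=vignette.sex,
        entered_comorbidities=set(vignette.comorbidities),
        outcome_condition=vignette.gold_condition,
        outcome_condition_list=[vignette.gold_condition],
        outcome_triage=vignette.gold_triage,
    )
    base.update(overrides)
    return ConsultationRecord(**base)


@pytest.fixture
def knee_vignette() -> Vignette:
    return Vignette(
        id="v-knee",
        age=45,
        sex="male",
        duration=7,
        symptoms={"pain in knee", "fever"},
        comorbidities=set(),
        prescribed_complaints=["knee pain"],
        gold_condition="septic arthritis",
        gold_triage=TriageLevel.URGENT_12H,
    )


@pytest.fixture
def tiny_study(clinical_lexicon, knee_vignette) -> StudyDataset:
    """Two vignettes x three testers, one tester wrong on one vignette."""
    v2 = Vignette(
        id="v-abdo",
        age=30,
        sex="female",
        duration=2,
        symptoms={"lower abdominal pain"},
        prescribed_complaints=["lower tummy pain"],
        gold_condition="uti",
        gold_triage=TriageLevel.ROUTINE,
    )
    consultations = []
    for t in ("t1", "t2", "t3"):
        consultations.append(make_consultation(knee_vignette, t))
    consultations.append(make_consultation(v2, "t1"))
    consultations.append(make_consultation(v2, "t2"))
    consultations.append(
        make_consultation(
            v2, "t3", outcome_condition=ABSENT, outcome_triage=ABSENT,
            outcome_condition_list=[],
        )
    )
    return StudyDataset(
        vignettes={knee_vignette.id: knee_vignette, v2.id: v2},
        consultations=consultations,
        lexicon=clinical_lexicon,
        metadata={"regime": "restricted"},
    )


@pytest.fixture(scope="session")
def noisy_restricted_study() -> StudyDataset:
    """Default-noise restricted study used by several analyses."""
    return simulate_study(
        SimConfig(seed=42, n_vignettes=40, n_conditions=10, n_symptoms=24)
    )


@pytest.fixture(scope="session")
def clean_restricted_study() -> StudyDataset:
    """Zero-tester-error restricted study (the degenerate reference chain)."""
    profiles = [TesterProfile(**ZERO_NOISE) for _ in range(3)]
    return simulate_study(
        SimConfig(
            seed=7, n_vignettes=30, n_conditions=10, n_symptoms=24,
            profiles=profiles, regime="restricted",
        )
    )
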