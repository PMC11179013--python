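"""Synthetic vignette-study generator.

Real tester data from SC evaluations is rarely shareable, so this
module fabricates complete studies with known ground truth: a concept
lexicon with synonyms and a broader-category hierarchy, a deterministic
toy symptom checker, a vignette set drawn from the toy SC's condition
space, and stochastic tester models operating under the three
instruction regimes (free, partially free, restricted).  Every metric
in the package can then be exercised against parameters we control.

The toy SC is an overlap scorer, not a clinical model: the top
condition maximizes ``|answers & S_c| - lam * |answers - S_c|`` over
conditions ``c`` with symptom sets ``S_c`` (ties broken by
lexicographic condition code; a non-positive best score returns
ABSENT).  It only asks about symptoms belonging to conditions whose
symptom sets intersect the chief complaints, which is what makes the
chief-complaint choice matter — exactly the mechanism the tester
regimes are designed to control.

Tester error channels (per answered question):

* ``p_human_error`` — the answer is flipped: a vignette symptom is
  declined, or an absent symptom selected;
* ``p_misinterpret`` — a vignette symptom is mistaken for a random
  sibling concept (the sibling is selected, the real symptom declined);
  outside the restricted regime the same rate also lets testers
  over-interpret by affirming a sibling of a vignette symptom, because
  only restricted testers are instructed to decline anything not
  written in the vignette;
* ``p_complaint_rephrase`` — in the free regime, a chief complaint is
  typed as a random lexicon synonym instead of the canonical phrase
  (and free testers pick their own 1-3 complaint symptoms to begin
  with, each of which can itself be misread as a sibling concept at
  rate ``p_misinterpret``).

Reproducibility: every tester x vignette x round consultation draws
from its own ``numpy`` RNG stream keyed on the master seed, so adding
testers or rounds never perturbs other draws, and the same seed always
yields a byte-identical study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np

from .types import (
    ABSENT,
    AnsweredSymptom,
    ConceptLexicon,
    ConsultationRecord,
    StudyDataset,
    TriageLevel,
    ValidationError,
    Vignette,
    _AbsentType,
)


@dataclass
class TesterProfile:
    """Stochastic tester error model; probabilities are per question."""

    __test__ = False  # keep pytest from collecting this as a test class

    p_human_error: float = 0.05
    p_misinterpret: float = 0.05
    p_complaint_rephrase: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_human_error", "p_misinterpret", "p_complaint_rephrase"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SyntheticSC:
    """The deterministic toy symptom checker."""

    conditions: dict[str, tuple[frozenset, TriageLevel]]
    lam: float = 0.5
    question_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for code, (symptoms, triage) in self.conditions.items():
            if not symptoms:
                raise ValidationError(f"condition {code!r} has no symptoms")
            if not isinstance(triage, TriageLevel):
                raise ValidationError(f"condition {code!r} lacks a triage level")


@dataclass
class SimConfig:
    """Study-generation parameters.  ``seed`` is mandatory."""

    seed: int
    n_vignettes: int = 114
    n_conditions: int = 12
    n_testers: int = 3
    regime: str = "restricted"
    rounds: int = 1
    profiles: Optional[list[TesterProfile]] = None
    n_symptoms: int = 30
    symptom_overlap: float = 0.6
    n_comorbidities: int = 5
    lam: float = 0.5

    def __post_init__(self) -> None:
        if self.regime not in ("free", "partially_free", "restricted"):
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.n_testers < 2:
            raise ValidationError("agreement analyses need n_testers >= 2")
        if self.n_symptoms < 8:
            raise ValidationError("need at least 8 symptom concepts")
        if self.rounds not in (1, 2):
            raise ValidationError("rounds must be 1 or 2")
        if not 0.0 <= self.symptom_overlap <= 1.0:
            raise ValidationError("symptom_overlap must be in [0, 1]")
        if self.profiles is None:
            self.profiles = [TesterProfile() for _ in range(self.n_testers)]
        if len(self.profiles) != self.n_testers:
            raise ValidationError("need one TesterProfile per tester")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        profiles = d.pop("profiles", None)
        if profiles is not None:
            profiles = [TesterProfile(**p) for p in profiles]
        return cls(profiles=profiles, **d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profiles"] = [asdict(p) for p in self.profiles]
        return d


_SYNONYM_PATTERNS = ("{} feeling", "trouble with {}", "{} discomfort")


def generate_world(
    cfg: SimConfig,
) -> tuple[ConceptLexicon, SyntheticSC, list[Vignette]]:
    """Build the lexicon, toy SC and vignette set for one study.

    Fully deterministic given ``cfg.seed``.  Raises if the requested
    number of conditions cannot receive distinct symptom sets.
    """
    rng = np.random.default_rng([cfg.seed, 7919])  # world stream

    # --- lexicon: base symptoms under a 3-level broader-category tree -----
    base = [f"sym{i:02d}" for i in range(cfg.n_symptoms)]
    group = 4  # siblings per direct parent
    cats = [f"cat{i:02d}" for i in range((cfg.n_symptoms + group - 1) // group)]
    regions = [f"region{i}" for i in range((len(cats) + 1) // 2)]
    comorb = [f"com{i}" for i in range(cfg.n_comorbidities)]
    concepts = set(base) | set(cats) | set(regions) | set(comorb)
    parent: dict[str, str] = {}
    for i, s in enumerate(base):
        parent[s] = cats[i // group]
    for i, c in enumerate(cats):
        parent[c] = regions[i // 2]
    synonyms = {
        s: {pat.format(s.replace("sym", "symptom ")) for pat in _SYNONYM_PATTERNS}
        for s in base
    }
    for c in cats:
        synonyms[c] = {c.replace("cat", "category ")}
    lexicon = ConceptLexicon(concepts=concepts, synonyms=synonyms, parent=parent)

    # --- toy SC conditions with controllable symptom overlap --------------
    shared_pool = base[: max(3, int(round(0.25 * cfg.n_symptoms)))]
    rest = base[len(shared_pool):]
    conditions: dict[str, tuple[frozenset, TriageLevel]] = {}
    seen_sets: set[frozenset] = set()
    for i in range(cfg.n_conditions):
        code = f"cond{i:02d}"
        placed = False
        for _ in range(200):
            size = int(rng.integers(3, 6))
            chosen: set[str] = set()
            while len(chosen) < size:
                pool = shared_pool if rng.random() < cfg.symptom_overlap else rest
                chosen.add(pool[int(rng.integers(0, len(pool)))])
            fs = frozenset(chosen)
            if fs not in seen_sets:
                seen_sets.add(fs)
                triage = TriageLevel(int(rng.integers(1, 10)))
                conditions[code] = (fs, triage)
                placed = True
                break
        if not placed:
            raise ValidationError(
                "infeasible config: cannot draw distinct symptom sets for "
                f"{cfg.n_conditions} conditions from {cfg.n_symptoms} symptoms"
            )
    question_order = list(base)
    rng.shuffle(question_order)
    sc = SyntheticSC(conditions=conditions, lam=cfg.lam, question_order=question_order)

    # --- vignettes drawn from the condition space --------------------------
    codes = sorted(conditions)
    vignettes: list[Vignette] = []
    for i in range(cfg.n_vignettes):
        code = codes[i % len(codes)]
        symptoms, triage = conditions[code]
        n_complaints = min(int(rng.integers(1, 3)), len(symptoms))
        complaint_syms = sorted(symptoms)[:n_complaints]
        prescribed = [lexicon.canonical_surface(s) for s in complaint_syms]
        n_com = int(rng.integers(0, 3))
        coms = set(rng.choice(comorb, size=n_com, replace=False)) if n_com else set()
        vignettes.append(
            Vignette(
                id=f"v{i:03d}",
                age=int(rng.integers(18, 91)),
                sex="female" if rng.random() < 0.5 else "male",
                duration=int(rng.integers(1, 31)),
                symptoms=set(symptoms),
                comorbidities={str(c) for c in coms},
                prescribed_complaints=prescribed,
                gold_condition=code,
                gold_triage=triage,
            )
        )
    return lexicon, sc, vignettes


def consult(
    sc: SyntheticSC, answers: set[str]
) -> tuple[Union[str, _AbsentType], Union[TriageLevel, _AbsentType], list[str]]:
    """The toy SC's decision rule on a set of affirmed symptom concepts.

    Returns (top condition, its triage, ranked condition list); a
    non-positive best score (including empty answers) returns ABSENT.
    Ties break toward the lexicographically smaller condition code.
    """
    if not answers:
        return ABSENT, ABSENT, []
    scored = []
    for code in sorted(sc.conditions):
        symptoms, _ = sc.conditions[code]
        s = len(answers & symptoms) - sc.lam * len(answers - symptoms)
        scored.append((-s, code))
    scored.sort()
    ranked = [code for negs, code in scored if -negs > 0]
    if not ranked:
        return ABSENT, ABSENT, []
    top = ranked[0]
    return top, sc.conditions[top][1], ranked[:3]


def _questions_for(sc: SyntheticSC, complaint_concepts: set[str]) -> list[str]:
    """Symptoms the SC asks about: those of conditions matching a complaint."""
    relevant: set[str] = set()
    for symptoms, _ in sc.conditions.values():
        if symptoms & complaint_concepts:
            relevant |= symptoms
    return [q for q in sc.question_order if q in relevant and q not in complaint_concepts]


def simulate_consultation(
    v: Vignette,
    sc: SyntheticSC,
    lexicon: ConceptLexicon,
    profile: TesterProfile,
    regime: str,
    rng: np.random.Generator,
    tester_id: str = "t0",
    round: int = 1,
) -> ConsultationRecord:
    """One stochastic tester pass through one vignette under a regime."""
    # --- chief complaints ---------------------------------------------------
    if regime == "free":
        syms = sorted(v.symptoms)
        k = min(int(rng.integers(1, 4)), len(syms))
        picked = [syms[i] for i in sorted(rng.choice(len(syms), size=k, replace=False))]
        complaints = []
        for s in picked:
            # free testers interpret the vignette themselves: a complaint
            # can be misread as a sibling concept before it is ever typed
            if rng.random() < profile.p_misinterpret:
                sibs = lexicon.siblings(s)
                if sibs:
                    s = sibs[int(rng.integers(0, len(sibs)))]
            syns = sorted(lexicon.synonyms.get(s, {s}))
            if len(syns) > 1 and rng.random() < profile.p_complaint_rephrase:
                complaints.append(syns[int(rng.integers(0, len(syns)))])
            else:
                complaints.append(lexicon.canonical_surface(s))
    else:
        if not v.prescribed_complaints:
            raise ValidationError(
                f"vignette {v.id!r} lacks prescribed complaints required by "
                f"the {regime} regime"
            )
        complaints = list(v.prescribed_complaints)
    complaint_concepts = {
        c for c in (lexicon.resolve(s) for s in complaints) if c is not None
    }

    # --- answer the SC's questions ------------------------------------------
    answered: list[AnsweredSymptom] = []
    selected: set[str] = set(complaint_concepts)
    for q in _questions_for(sc, complaint_concepts):
        present = q in v.symptoms
        if present and rng.random() < profile.p_misinterpret:
            sibs = lexicon.siblings(q)
            if sibs:
                sib = sibs[int(rng.integers(0, len(sibs)))]
                answered.append(AnsweredSymptom(sib, "selected"))
                answered.append(AnsweredSymptom(q, "declined"))
                selected.add(sib)
                continue
        if (
            not present
            and regime != "restricted"
            and rng.random() < profile.p_misinterpret
            and any(lexicon.parent.get(q) == lexicon.parent.get(t) for t in v.symptoms)
        ):
            answered.append(AnsweredSymptom(q, "selected"))
            selected.add(q)
            continue
        ans = present
        if rng.random() < profile.p_human_error:
            ans = not ans
        answered.append(AnsweredSymptom(q, "selected" if ans else "declined"))
        if ans:
            selected.add(q)

    # --- transcription of the remaining data points -------------------------
    duration = v.duration
    if isinstance(duration, int) and rng.random() < profile.p_human_error:
        duration = max(1, duration + (1 if rng.random() < 0.5 else -1))

    top, triage, ranked = consult(sc, selected)
    return ConsultationRecord(
        vignette_id=v.id,
        tester_id=tester_id,
        round=round,
        regime=regime,
        entered_complaints=complaints,
        answered_symptoms=answered,
        entered_duration=duration,
        entered_age=v.age,
        entered_sex=v.sex,
        entered_comorbidities=set(v.comorbidities),
        outcome_condition=top,
        outcome_condition_list=ranked,
        outcome_triage=triage,
    )


def intrinsic_accuracy(
    sc: SyntheticSC, vignettes: list[Vignette]
) -> dict[str, float]:
    """Noise-free toy-SC accuracy: consult each vignette's exact symptom set."""
    hit_c = hit_t = 0
    for v in vignettes:
        top, triage, _ = consult(sc, set(v.symptoms))
        if top is not ABSENT and top == v.gold_condition:
            hit_c += 1
        if triage is not ABSENT and triage == v.gold_triage:
            hit_t += 1
    n = len(vignettes)
    return {"condition": 100.0 * hit_c / n, "triage": 100.0 * hit_t / n}


def simulate_study(cfg: SimConfig) -> StudyDataset:
    """Generate a full rectangular study (every tester x vignette x round).

    The dataset's metadata records the generating parameters and the
    toy SC's intrinsic (noise-free) accuracy for parameter-recovery
    tests.
    """
    lexicon, sc, vignettes = generate_world(cfg)
    consultations: list[ConsultationRecord] = []
    for t_idx in range(cfg.n_testers):
        tester_id = f"tester{t_idx + 1}"
        profile = cfg.profiles[t_idx]
        for rnd in range(1, cfg.rounds + 1):
            for v_idx, v in enumerate(vignettes):
                rng = np.random.default_rng([cfg.seed, t_idx, v_idx, rnd])
                consultations.append(
                    simulate_consultation(
                        v, sc, lexicon, profile, cfg.regime, rng,
                        tester_id=tester_id, round=rnd,
                    )
                )
    metadata = {
        "synthetic": True,
        "regime": cfg.regime,
        "seed": cfg.seed,
        "testers": [f"tester{i + 1}" for i in range(cfg.n_testers)],
        "config": cfg.to_dict(),
        "truth": {
            "intrinsic_accuracy": intrinsic_accuracy(sc, vignettes),
            "lam": cfg.lam,
            "n_conditions": cfg.n_conditions,
        },
    }
    return StudyDataset(
        vignettes={v.id: v for v in vignettes},
        consultations=consultations,
        lexicon=lexicon,
        metadata=metadata,
    )
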