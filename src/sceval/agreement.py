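"""Inter- and intratester agreement statistics.

Vignette studies with a handful of testers live or die on tester
consistency, so the first analysis is always chance-corrected
agreement: Fleiss' kappa across the tester panel for each outcome
(most-likely condition and triage), Cohen's kappa per tester for the
test-retest round, and a per-vignette full / partial / no-agreement
breakdown.

Category coding
---------------
Condition labels are opaque strings; distinct normalized labels get
distinct positive integer codes in first-appearance order, and a
consultation that produced no condition (the ABSENT sentinel) is coded
0 — "no outcome" is a real category, so two testers who both got
nothing agree.  Triage uses its fixed 9-level coding (1..9), again
with 0 for ABSENT.  Kappa is invariant to the particular labels.

Uncertainty
-----------
Standard errors are large-sample (asymptotic): for Fleiss' kappa the
Fleiss-Nee-Landis variance, for Cohen's kappa the
Fleiss-Cohen-Everitt variance (with the null-hypothesis form used for
the test of kappa = 0).  A seeded percentile bootstrap over subjects is
available as a sensitivity check on the confidence interval.

Degenerate data — every rating in a single category — makes expected
agreement 1 and kappa undefined; this is reported explicitly
(``kappa is None``, observed agreement 1.0) rather than leaking NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    ABSENT,
    ConceptLexicon,
    IncompleteDesignError,
    StudyDataset,
    ValidationError,
    normalize_surface,
)

LANDIS_KOCH_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost_perfect"),
)


def landis_koch_band(kappa: float) -> str:
    """Landis-Koch qualitative band for a kappa value.

    The published scale starts at 0.00; negative kappa is reported as
    ``"negative"``.
    """
    if kappa < 0:
        return "negative"
    for cut, name in LANDIS_KOCH_BANDS:
        if kappa <= cut:
            return name
    return "almost_perfect"


@dataclass
class RatingMatrix:
    """Subjects x raters nominal codes (0 reserved for ABSENT)."""

    subjects: list[str]
    raters: list[str]
    codes: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        n, r = self.codes.shape
        if n != len(self.subjects) or r != len(self.raters):
            raise ValidationError("codes shape does not match subjects x raters")
        if r < 2:
            raise ValidationError("agreement needs at least 2 raters")


@dataclass
class AgreementResult:
    """A kappa estimate with its uncertainty.

    ``kappa is None`` signals the degenerate single-category case where
    expected agreement is 1 and kappa is undefined.  ``po`` is the raw
    observed (pairwise) agreement — for two ratings this is the plain
    match proportion.
    """

    kappa: Optional[float]
    se: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    po: float
    pe: float
    n_subjects: int
    n_raters: int
    statistic_name: str = "fleiss_kappa"

    @property
    def defined(self) -> bool:
        return self.kappa is not None

    @property
    def landis_koch_band(self) -> str:
        if self.kappa is None:
            return "undefined"
        return landis_koch_band(self.kappa)


@dataclass
class AgreementBreakdown:
    """Per-subject full / partial / no-agreement counts (publication-style table rows)."""

    n_full: int
    n_partial: int
    n_none: int

    @property
    def total(self) -> int:
        return self.n_full + self.n_partial + self.n_none

    @property
    def pct_full(self) -> float:
        return 100.0 * self.n_full / self.total

    @property
    def pct_partial(self) -> float:
        return 100.0 * self.n_partial / self.total

    @property
    def pct_none(self) -> float:
        return 100.0 * self.n_none / self.total


def _code_of(value, code_map: dict[str, int]) -> int:
    """Nominal code for an outcome value; ABSENT -> 0, new labels get fresh codes."""
    if value is ABSENT:
        return 0
    key = normalize_surface(str(value))
    if key not in code_map:
        code_map[key] = len(code_map) + 1
    return code_map[key]


def encode_outcomes(
    ds: StudyDataset,
    field: str = "condition",
    round: int = 1,
    testers: Optional[Sequence[str]] = None,
) -> RatingMatrix:
    """Build the subjects x raters code matrix for an outcome field.

    ``field="condition"``: distinct normalized condition labels are
    numbered 1, 2, ... in row-major first-appearance order; ABSENT is 0.
    ``field="triage"``: the 9-level triage code (1..9); ABSENT is 0.
    """
    if field not in ("condition", "triage"):
        raise ValueError("field must be 'condition' or 'triage'")
    raters = list(testers) if testers is not None else ds.testers()
    ds.require_rectangular(round=round, testers=raters)
    subjects = list(ds.vignettes)
    code_map: dict[str, int] = {}
    labels: dict[int, str] = {0: "ABSENT"}
    codes = np.zeros((len(subjects), len(raters)), dtype=int)
    for i, vid in enumerate(subjects):
        for j, t in enumerate(raters):
            c = ds.consultation(t, vid, round)
            if c is None:  # require_rectangular should have caught this
                raise IncompleteDesignError(f"missing consultation {t} x {vid}")
            if field == "condition":
                codes[i, j] = _code_of(c.outcome_condition, code_map)
                if codes[i, j] != 0:
                    labels.setdefault(codes[i, j], normalize_surface(str(c.outcome_condition)))
            else:
                codes[i, j] = 0 if c.outcome_triage is ABSENT else int(c.outcome_triage)
                if codes[i, j] != 0:
                    labels.setdefault(codes[i, j], c.outcome_triage.label)
    return RatingMatrix(subjects=subjects, raters=raters, codes=codes, labels=labels)


def _count_table(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subjects x categories count table and the category code vector."""
    cats = np.unique(codes)
    table = (codes[:, :, None] == cats[None, None, :]).sum(axis=1)
    return table.astype(float), cats


def fleiss_kappa(
    m: RatingMatrix,
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> AgreementResult:
    """Fleiss' multi-rater kappa with asymptotic SE, 95% CI and p-value.

    Observed agreement is the mean per-subject pairwise agreement;
    expected agreement comes from the pooled category proportions.
    The SE is the Fleiss-Nee-Landis large-sample form (also used for
    the null test).  ``bootstrap > 0`` replaces the CI with a seeded
    percentile bootstrap over subjects.
    """
    codes = m.codes
    n_subj, n_rat = codes.shape
    table, _ = _count_table(codes)
    po, pe, kappa = _fleiss_point(table, n_rat)
    if kappa is None:
        return AgreementResult(None, None, None, None, None, po, pe, n_subj, n_rat)
    p_j = table.sum(axis=0) / (n_subj * n_rat)
    # Fleiss-Nee-Landis asymptotic variance
    num = pe - (2 * n_rat - 3) * pe**2 + 2 * (n_rat - 2) * float(np.sum(p_j**3))
    var = 2.0 * num / (n_subj * n_rat * (n_rat - 1) * (1 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    z = kappa / se if se > 0 else (0.0 if kappa == 0 else np.inf * np.sign(kappa))
    p_value = float(2 * stats.norm.sf(abs(z)))
    if bootstrap > 0:
        ci_low, ci_high = _bootstrap_ci(
            codes, lambda sub: _fleiss_point(_count_table(sub)[0], n_rat)[2], bootstrap, seed
        )
    else:
        ci_low = kappa - 1.959963984540054 * se
        ci_high = kappa + 1.959963984540054 * se
    return AgreementResult(
        kappa, se, ci_low, ci_high, p_value, po, pe, n_subj, n_rat, "fleiss_kappa"
    )


def _fleiss_point(table: np.ndarray, n_rat: int) -> tuple[float, float, Optional[float]]:
    n_subj = table.shape[0]
    p_i = (np.sum(table**2, axis=1) - n_rat) / (n_rat * (n_rat - 1))
    po = float(np.mean(p_i))
    p_j = table.sum(axis=0) / (n_subj * n_rat)
    pe = float(np.sum(p_j**2))
    if pe >= 1.0 - 1e-12:
        return po, pe, None
    return po, pe, (po - pe) / (1 - pe)


def _bootstrap_ci(codes, point_fn, n_boot: int, seed) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = codes.shape[0]
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        k = point_fn(codes[idx])
        if k is not None:
            vals.append(k)
    if not vals:
        return (np.nan, np.nan)
    return (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))


def cohen_kappa(
    a: Sequence[int],
    b: Sequence[int],
    bootstrap: int = 0,
    seed: Optional[int] = None,
) -> AgreementResult:
    """Cohen's kappa between two rating sequences (e.g. round 1 vs round 2).

    Expected agreement uses the product of the two marginal
    distributions.  The CI uses the Fleiss-Cohen-Everitt large-sample
    SE around the estimate; the p-value tests kappa = 0 with the
    null-hypothesis SE.  ``result.po`` is the raw match proportion
    (the "Matches" column of test-retest tables).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("cohen_kappa needs two equal-length 1-D code sequences")
    n = a.size
    if n < 1:
        raise ValidationError("cohen_kappa needs at least one pair")
    cats = np.unique(np.concatenate([a, b]))
    k = cats.size
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1.0)
    table /= n
    po = float(np.trace(table))
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    pe = float(np.sum(row * col))
    if pe >= 1.0 - 1e-12:
        return AgreementResult(None, None, None, None, None, po, pe, n, 2, "cohen_kappa")
    kappa = (po - pe) / (1 - pe)
    # Fleiss-Cohen-Everitt large-sample variance around the estimate
    diag = np.diag(table)
    term1 = float(np.sum(diag * (1 - (row + col) * (1 - kappa)) ** 2))
    off = table * (col[None, :] + row[:, None]) ** 2
    np.fill_diagonal(off, 0.0)
    term2 = (1 - kappa) ** 2 * float(np.sum(off))
    term3 = (kappa - pe * (1 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    # null-hypothesis variance for the test of kappa = 0
    var0 = (pe + pe**2 - float(np.sum(row * col * (row + col)))) / (n * (1 - pe) ** 2)
    se0 = float(np.sqrt(max(var0, 0.0)))
    z = kappa / se0 if se0 > 0 else (0.0 if kappa == 0 else np.inf * np.sign(kappa))
    p_value = float(2 * stats.norm.sf(abs(z)))
    if bootstrap > 0:
        both = np.stack([a, b], axis=1)

        def _point(sub):
            return _cohen_point(sub[:, 0], sub[:, 1])

        ci_low, ci_high = _bootstrap_ci(both, _point, bootstrap, seed)
    else:
        ci_low = kappa - 1.959963984540054 * se
        ci_high = kappa + 1.959963984540054 * se
    return AgreementResult(
        kappa, se, ci_low, ci_high, p_value, po, pe, n, 2, "cohen_kappa"
    )


def _cohen_point(a, b) -> Optional[float]:
    n = a.size
    cats = np.unique(np.concatenate([a, b]))
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    table = np.zeros((cats.size, cats.size))
    np.add.at(table, (ai, bi), 1.0)
    table /= n
    po = float(np.trace(table))
    pe = float(np.sum(table.sum(axis=1) * table.sum(axis=0)))
    if pe >= 1.0 - 1e-12:
        return None
    return (po - pe) / (1 - pe)


def categorize_agreement(m: RatingMatrix) -> AgreementBreakdown:
    """Classify each subject as full (all raters equal), none (all
    pairwise distinct) or partial agreement."""
    n_full = n_partial = n_none = 0
    for row in m.codes:
        distinct = len(set(row.tolist()))
        if distinct == 1:
            n_full += 1
        elif distinct == len(row):
            n_none += 1
        else:
            n_partial += 1
    return AgreementBreakdown(n_full=n_full, n_partial=n_partial, n_none=n_none)


def _complaint_category(
    complaints: Sequence[str], level: str, lexicon: Optional[ConceptLexicon]
):
    """Reduce a tester's chief-complaint list to a hashable nominal category.

    exact_wording: the multiset of normalized strings.  concept: the
    set of lexicon concepts; strings with no lexicon entry become
    unique pseudo-concepts so they never accidentally collide.
    """
    if level == "exact_wording":
        return tuple(sorted(normalize_surface(s) for s in complaints))
    if level == "concept":
        out = set()
        for s in complaints:
            c = lexicon.resolve(s)
            out.add(c if c is not None else f"unresolved::{normalize_surface(s)}")
        return frozenset(out)
    raise ValueError("level must be 'exact_wording' or 'concept'")


def complaint_agreement(
    ds: StudyDataset,
    level: str = "exact_wording",
    round: int = 1,
) -> tuple[RatingMatrix, AgreementResult, AgreementBreakdown]:
    """Agreement of the chief complaints entered by free-regime testers.

    Each tester's complaint list is reduced to a nominal category —
    the multiset of normalized strings (``exact_wording``) or the set
    of resolved lexicon concepts (``concept``) — and identical
    categories share a code; kappa and the full/partial/none breakdown
    are computed on the resulting matrix.
    """
    if level == "concept" and ds.lexicon is None:
        raise ValidationError("concept-level complaint agreement needs a lexicon")
    raters = ds.testers()
    ds.require_rectangular(round=round)
    subjects = list(ds.vignettes)
    cat_codes: dict = {}
    codes = np.zeros((len(subjects), len(raters)), dtype=int)
    for i, vid in enumerate(subjects):
        for j, t in enumerate(raters):
            c = ds.consultation(t, vid, round)
            cat = _complaint_category(c.entered_complaints, level, ds.lexicon)
            if cat not in cat_codes:
                cat_codes[cat] = len(cat_codes) + 1
            codes[i, j] = cat_codes[cat]
    m = RatingMatrix(subjects=subjects, raters=raters, codes=codes)
    return m, fleiss_kappa(m), categorize_agreement(m)


def intratester_agreement(
    ds: StudyDataset, field: str = "condition"
) -> dict[str, AgreementResult]:
    """Per-tester Cohen's kappa between round 1 and round 2 outcomes.

    Category codes are shared across the two rounds so the same label
    always gets the same code.
    """
    if 2 not in ds.rounds():
        raise ValidationError("intratester agreement needs a round-2 repeat")
    results: dict[str, AgreementResult] = {}
    subjects = list(ds.vignettes)
    for t in ds.testers():
        code_map: dict[str, int] = {}
        seqs = {1: [], 2: []}
        for rnd in (1, 2):
            ds.require_rectangular(round=rnd, testers=[t])
            for vid in subjects:
                c = ds.consultation(t, vid, rnd)
                if field == "condition":
                    seqs[rnd].append(_code_of(c.outcome_condition, code_map))
                elif field == "triage":
                    seqs[rnd].append(0 if c.outcome_triage is ABSENT else int(c.outcome_triage))
                else:
                    raise ValueError("field must be 'condition' or 'triage'")
        results[t] = cohen_kappa(seqs[1], seqs[2])
    return results


def intratester_complaint_agreement(
    ds: StudyDataset, level: str = "exact_wording"
) -> dict[str, AgreementResult]:
    """Per-tester test-retest kappa for chief-complaint categories."""
    if 2 not in ds.rounds():
        raise ValidationError("intratester agreement needs a round-2 repeat")
    results: dict[str, AgreementResult] = {}
    subjects = list(ds.vignettes)
    for t in ds.testers():
        cat_codes: dict = {}
        seqs = {1: [], 2: []}
        for rnd in (1, 2):
            ds.require_rectangular(round=rnd, testers=[t])
            for vid in subjects:
                c = ds.consultation(t, vid, rnd)
                cat = _complaint_category(c.entered_complaints, level, ds.lexicon)
                if cat not in cat_codes:
                    cat_codes[cat] = len(cat_codes) + 1
                seqs[rnd].append(cat_codes[cat])
        results[t] = cohen_kappa(seqs[1], seqs[2])
    return results
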