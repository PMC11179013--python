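"""Crude accuracy against the gold standard and between-group comparisons.

A tester's accuracy is the percentage of vignettes where the SC's
most-likely condition (or its triage recommendation) exactly matched
the vignette's expert gold standard.  Condition labels are compared
after surface normalization; triage requires equality on the 9-level
scale; a consultation with no outcome (ABSENT) never matches.  The
group summary averages the per-tester accuracies and reports the
population standard deviation (divisor n), which is the convention
needed to reproduce a 3-tester panel summary exactly.  Group
comparisons use one-way fixed-effects ANOVA or the pooled-variance
two-tailed Student t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    ABSENT,
    IncompleteDesignError,
    StudyDataset,
    ValidationError,
    normalize_surface,
)


@dataclass
class GroupAccuracy:
    """Per-tester accuracies with their mean and spread."""

    per_tester: dict[str, float]
    mean: float
    sd: float          # population SD (divisor n) — the reporting default
    sd_sample: float   # sample SD (divisor n-1), exposed for sensitivity
    n_testers: int
    n_vignettes: Optional[int] = None


@dataclass
class ComparisonResult:
    """A between-group test statistic."""

    statistic: float
    df: tuple
    p_value: float
    test_name: str


def _matches_gold(c, v, target: str) -> bool:
    if target == "condition":
        if c.outcome_condition is ABSENT:
            return False
        return normalize_surface(str(c.outcome_condition)) == normalize_surface(
            v.gold_condition
        )
    if target == "triage":
        if c.outcome_triage is ABSENT:
            return False
        return c.outcome_triage == v.gold_triage
    raise ValueError("target must be 'condition' or 'triage'")


def tester_accuracy(
    ds: StudyDataset, tester: str, target: str = "condition", round: int = 1
) -> float:
    """Percentage of vignettes where *tester*'s outcome met the gold standard."""
    ds.require_rectangular(round=round, testers=[tester])
    hits = 0
    for vid, v in ds.vignettes.items():
        c = ds.consultation(tester, vid, round)
        if c is None:
            raise IncompleteDesignError(f"tester {tester!r} missing vignette {vid!r}")
        if _matches_gold(c, v, target):
            hits += 1
    return 100.0 * hits / len(ds.vignettes)


def group_summary(
    accuracies: Sequence[float],
    testers: Optional[Sequence[str]] = None,
    n_vignettes: Optional[int] = None,
) -> GroupAccuracy:
    """Summarize per-tester accuracy percentages (mean, population SD)."""
    vals = np.asarray(list(accuracies), dtype=float)
    if vals.size == 0:
        raise ValidationError("group_summary needs at least one accuracy value")
    if np.any((vals < 0) | (vals > 100)):
        raise ValidationError("accuracies must be percentages in [0, 100]")
    names = list(testers) if testers is not None else [str(i + 1) for i in range(vals.size)]
    if len(names) != vals.size:
        raise ValidationError("testers and accuracies must align")
    sd_pop = float(np.std(vals))  # divisor n
    sd_samp = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return GroupAccuracy(
        per_tester=dict(zip(names, vals.tolist())),
        mean=float(np.mean(vals)),
        sd=sd_pop,
        sd_sample=sd_samp,
        n_testers=int(vals.size),
        n_vignettes=n_vignettes,
    )


def group_accuracy(
    ds: StudyDataset, target: str = "condition", round: int = 1
) -> GroupAccuracy:
    """Per-tester accuracies for every tester in the study, summarized."""
    testers = ds.testers()
    accs = [tester_accuracy(ds, t, target, round) for t in testers]
    return group_summary(accs, testers=testers, n_vignettes=len(ds.vignettes))


def any_tester_accuracy(
    ds: StudyDataset, target: str = "condition", round: int = 1
) -> float:
    """Percentage of vignettes where at least one tester met the gold standard."""
    testers = ds.testers()
    if len(testers) < 2:
        raise ValidationError("any-tester accuracy needs at least 2 testers")
    ds.require_rectangular(round=round)
    hits = 0
    for vid, v in ds.vignettes.items():
        if any(
            _matches_gold(ds.consultation(t, vid, round), v, target) for t in testers
        ):
            hits += 1
    return 100.0 * hits / len(ds.vignettes)


def compare_groups(
    groups: Sequence[Sequence[float]], test: str = "anova"
) -> ComparisonResult:
    """Compare per-tester accuracy distributions between tester groups.

    ``test="anova"``: one-way fixed-effects ANOVA over >= 2 groups.
    ``test="t_test"``: two-sample Student t (pooled variance, two-tailed)
    over exactly 2 groups.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs at least 2 values")
    if test == "anova":
        if len(arrays) < 2:
            raise ValidationError("ANOVA needs at least 2 groups")
        f, p = stats.f_oneway(*arrays)
        k = len(arrays)
        n = sum(a.size for a in arrays)
        return ComparisonResult(float(f), (k - 1, n - k), float(p), "anova")
    if test == "t_test":
        if len(arrays) != 2:
            raise ValidationError("the t test compares exactly 2 groups")
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        df = arrays[0].size + arrays[1].size - 2
        return ComparisonResult(float(t), (df,), float(p), "t_test")
    raise ValueError("test must be 'anova' or 't_test'")
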