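"""Publication-style table rendering for analysis results.

Percentages are rendered to 1 decimal and kappa values to 2 decimals
("0.72 (0.65-0.79)"); counts carry their percentage in parentheses
("73 (64.0)").  Machine-readable JSON output always carries full
precision.
"""

from __future__ import annotations

import io
import json
import csv as _csv
from dataclasses import dataclass, field

from .accuracy import ComparisonResult, GroupAccuracy
from .agreement import AgreementBreakdown, AgreementResult
from .comprehension import ComprehensionScore
from .fidelity import AdjustedAccuracyResult, FidelityCrossTab


@dataclass
class ReportTable:
    """A rectangular table with a title and optional footnotes."""

    title: str
    headers: list[str]
    rows: list[list[str]]
    footnotes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.rows:
            if len(r) != len(self.headers):
                raise ValueError("table rows must match header width")

    def to_markdown(self) -> str:
        out = [f"### {self.title}", ""]
        out.append("| " + " | ".join(self.headers) + " |")
        out.append("|" + "|".join(" --- " for _ in self.headers) + "|")
        for r in self.rows:
            out.append("| " + " | ".join(r) + " |")
        for fn in self.footnotes:
            out.append("")
            out.append(f"*{fn}*")
        return "\n".join(out) + "\n"

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = _csv.writer(buf, lineterminator="\n")
        w.writerow(self.headers)
        for r in self.rows:
            w.writerow(r)
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {
                "title": self.title,
                "headers": self.headers,
                "rows": self.rows,
                "footnotes": self.footnotes,
            },
            indent=1,
        )

    def render(self, format: str = "markdown") -> str:
        if format == "markdown":
            return self.to_markdown()
        if format == "csv":
            return self.to_csv()
        if format == "json":
            return self.to_json()
        raise ValueError(f"unknown format {format!r}; use markdown, csv or json")


def fmt_pct(x: float) -> str:
    return f"{x:.1f}"


def fmt_kappa(res: AgreementResult) -> str:
    if not res.defined:
        return "undefined"
    return f"{res.kappa:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f})"


def fmt_p(p) -> str:
    if p is None:
        return "n/a"
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") or ".000"


def fmt_count(n: int, total: int) -> str:
    return f"{n} ({100.0 * n / total:.1f})"


def agreement_table(
    rows: list[tuple[str, AgreementResult, AgreementBreakdown]],
    title: str = "Intertester agreement",
) -> ReportTable:
    """Table-1-style layout: kappa (95% CI), p, full/partial/none n (%)."""
    out = []
    for label, res, br in rows:
        out.append(
            [
                label,
                fmt_kappa(res),
                fmt_p(res.p_value),
                fmt_count(br.n_full, br.total),
                fmt_count(br.n_partial, br.total),
                fmt_count(br.n_none, br.total),
            ]
        )
    return ReportTable(
        title=title,
        headers=[
            "Group",
            "Kappa (95% CI)",
            "P value",
            "Full agreement, n (%)",
            "Partial agreement, n (%)",
            "No agreement, n (%)",
        ],
        rows=out,
    )


def retest_table(
    results: dict[str, AgreementResult], title: str = "Intratester agreement"
) -> ReportTable:
    """Test-retest layout: per-tester kappa (95% CI), p, matches n (%)."""
    rows = []
    for tester, res in results.items():
        matches = round(res.po * res.n_subjects)
        rows.append(
            [tester, fmt_kappa(res), fmt_p(res.p_value), fmt_count(matches, res.n_subjects)]
        )
    return ReportTable(
        title=title,
        headers=["Tester", "Kappa (95% CI)", "P value", "Matches, n (%)"],
        rows=rows,
    )


def accuracy_table(
    group: GroupAccuracy,
    any_tester: float | None = None,
    adjusted: list[AdjustedAccuracyResult] = (),
    title: str = "Most likely condition accuracy",
) -> ReportTable:
    rows = [[t, fmt_pct(a)] for t, a in group.per_tester.items()]
    rows.append([f"Average of {group.n_testers} testers (SD)", f"{group.mean:.1f} ({group.sd:.2f})"])
    if any_tester is not None:
        rows.append(["If any tester met the gold standard", fmt_pct(any_tester)])
    for adj in adjusted:
        name = "Accuracy_Excluded" if adj.metric == "accuracy_excluded" else "Accuracy_Retested"
        rows.append([name, fmt_pct(adj.accuracy)])
    return ReportTable(title=title, headers=["Measure", "Accuracy (%)"], rows=rows)


def crosstab_table(
    ct: FidelityCrossTab, title: str = "Consultations identical to the vignette"
) -> ReportTable:
    headers = ["Outcome agreement"] + [
        f"{k} identical, n (%)" for k in range(ct.n_testers + 1)
    ] + ["Total, n (%)"]
    rows = []
    for row_key, label in (
        ("not_all_match", "2 or no testers match each other in outcome"),
        ("all_match", "All testers match each other in outcome"),
    ):
        cells = [fmt_count(ct.cell(row_key, k), ct.total) for k in range(ct.n_testers + 1)]
        rows.append([label] + cells + [fmt_count(ct.row_total(row_key), ct.total)])
    col_totals = ct.column_totals()
    rows.append(
        ["Total"]
        + [fmt_count(c, ct.total) for c in col_totals]
        + [fmt_count(ct.total, ct.total)]
    )
    return ReportTable(title=title, headers=headers, rows=rows)


def comprehension_table(
    scores: list[ComprehensionScore], title: str = "Percentage of inputs understood"
) -> ReportTable:
    rows = [
        [
            " / ".join(str(g) for g in s.group),
            str(s.raw),
            str(s.max),
            fmt_pct(s.percent),
        ]
        for s in scores
    ]
    return ReportTable(
        title=title, headers=["Group", "Score", "Max", "Understood (%)"], rows=rows
    )


def comparison_table(res: ComparisonResult, title: str = "Group comparison") -> ReportTable:
    stat = "F" if res.test_name == "anova" else "t"
    df = ", ".join(str(d) for d in res.df)
    return ReportTable(
        title=title,
        headers=["Test", stat, "df", "P value"],
        rows=[[res.test_name, f"{res.statistic:.3f}", df, fmt_p(res.p_value)]],
    )


def render_table(result, **kwargs) -> ReportTable:
    """Dispatch a module result object to its table layout."""
    if isinstance(result, FidelityCrossTab):
        return crosstab_table(result, **kwargs)
    if isinstance(result, GroupAccuracy):
        return accuracy_table(result, **kwargs)
    if isinstance(result, ComparisonResult):
        return comparison_table(result, **kwargs)
    if isinstance(result, list) and result and isinstance(result[0], ComprehensionScore):
        return comprehension_table(result, **kwargs)
    if isinstance(result, tuple) and len(result) == 3 and isinstance(result[1], AgreementResult):
        _, res, br = result
        return agreement_table([("", res, br)], **kwargs)
    if isinstance(result, dict) and result and all(
        isinstance(v, AgreementResult) for v in result.values()
    ):
        return retest_table(result, **kwargs)
    raise TypeError(f"no table layout for {type(result).__name__}")
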