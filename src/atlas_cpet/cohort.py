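"""Cohort-level comparison of trajectory-based vs peak-score severity.

Given a cohort of subjects, each carrying a trajectory-based (ATLAS)
classification and a conventional peak-score classification for one or
both symptoms, this module builds the comparative analyses used to
judge the two approaches against each other:

- a 4x4 cross-tabulation of severity categories assigned by the two
  methods;
- McNemar's test for systematic disagreement after dichotomizing the
  scale (default cut: severe-or-worse vs below);
- Pearson chi-squared tests of whether severity categories discriminate
  clinically defined patient groups (airflow-obstruction stage,
  presence of critical lung-mechanical constraint, reduced peak oxygen
  uptake), reported per method with a monotone-trend summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ClassificationResult, SeverityCategory, classify_peak

__all__ = [
    "CohortRecord",
    "ContingencyTable",
    "crosstab_severity",
    "dichotomize",
    "mcnemar_test",
    "chi_squared_test",
    "discrimination_report",
    "GROUP_LABELS",
]

#: Recognized grouping variables and their (reference, adverse) level order.
GROUP_LABELS: dict[str, tuple[str, str]] = {
    "gold_stage": ("I_II", "III_IV"),
    "mechanical_constraint": ("no", "yes"),
    "low_peak_vo2": ("no", "yes"),
}

_SEVERITY_ORDER = list(SeverityCategory)


@dataclass
class CohortRecord:
    """One subject's classifications plus grouping labels."""

    subject_id: str
    peak_dyspnea: float
    peak_leg_effort: float
    atlas_dyspnea: ClassificationResult | None = None
    atlas_leg_effort: ClassificationResult | None = None
    gold_stage: str | None = None
    mechanical_constraint: str | None = None
    low_peak_vo2: str | None = None

    def __post_init__(self) -> None:
        for name, score in (
            ("peak_dyspnea", self.peak_dyspnea),
            ("peak_leg_effort", self.peak_leg_effort),
        ):
            if not 0 <= score <= 10:
                raise ValueError(f"{name} must lie in [0, 10]; got {score}")
        for name, allowed in GROUP_LABELS.items():
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}; got {value!r}")

    def severity(self, symptom: str, method: str) -> SeverityCategory | None:
        """Severity under one method ('atlas' or 'peak') for one symptom."""
        if method == "peak":
            score = self.peak_dyspnea if symptom == "dyspnea" else self.peak_leg_effort
            return classify_peak(score)
        if method == "atlas":
            result = self.atlas_dyspnea if symptom == "dyspnea" else self.atlas_leg_effort
            return None if result is None else result.severity
        raise ValueError(f"method must be 'atlas' or 'peak'; got {method!r}")


@dataclass
class ContingencyTable:
    """Labelled table of non-negative integer counts (>= 2x2)."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match the label lists")
        if min(self.counts.shape) < 2:
            raise ValueError("table must be at least 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)


def crosstab_severity(
    cohort: list[CohortRecord],
    symptom: str,
    method_a: str = "atlas",
    method_b: str = "peak",
) -> ContingencyTable:
    """4x4 cross-tabulation of severity by two classification methods.

    Rows are ``method_a`` categories, columns ``method_b``; the grand
    total equals the cohort size.  Subjects missing either
    classification raise an error naming them.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    missing = [
        rec.subject_id
        for rec in cohort
        if rec.severity(symptom, method_a) is None
        or rec.severity(symptom, method_b) is None
    ]
    if missing:
        raise ValueError(f"subjects missing a classification: {missing}")
    labels = [str(s) for s in _SEVERITY_ORDER]
    counts = np.zeros((4, 4), dtype=int)
    for rec in cohort:
        i = int(rec.severity(symptom, method_a))
        j = int(rec.severity(symptom, method_b))
        counts[i, j] += 1
    return ContingencyTable(labels, list(labels), counts)


def dichotomize(
    table: ContingencyTable, cut: SeverityCategory = SeverityCategory.SEVERE
) -> ContingencyTable:
    """Collapse a 4x4 severity crosstab to 2x2 at ``cut``-or-worse."""
    k = int(cut)
    c = table.counts
    counts = np.array(
        [
            [c[:k, :k].sum(), c[:k, k:].sum()],
            [c[k:, :k].sum(), c[k:, k:].sum()],
        ]
    )
    labels = [f"below_{cut}", f"{cut}_or_worse"]
    return ContingencyTable(labels, list(labels), counts)


def mcnemar_test(table: ContingencyTable, exact: bool | None = None) -> dict:
    """McNemar's test for marginal disagreement on a paired 2x2 table.

    With ``b`` and ``c`` the two discordant counts: if ``b + c < 25``
    the two-sided exact binomial p-value (success probability 0.5) is
    used; otherwise the continuity-corrected statistic
    ``(|b - c| - 1)^2 / (b + c)`` referred to chi-squared with 1 df.
    ``exact`` overrides the automatic switch.  ``b + c = 0`` yields
    p = 1 with a ``degenerate`` flag.
    """
    if table.counts.shape != (2, 2):
        raise ValueError("McNemar's test needs a 2x2 table")
    b = int(table.counts[0, 1])
    c = int(table.counts[1, 0])
    n = b + c
    if n == 0:
        return {"method": "degenerate", "statistic": None, "p_value": 1.0, "b": b, "c": c}
    if exact is None:
        exact = n < 25
    if exact:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return {"method": "exact", "statistic": None, "p_value": float(p), "b": b, "c": c}
    statistic = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return {"method": "corrected", "statistic": float(statistic), "p_value": p, "b": b, "c": c}


def chi_squared_test(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence.

    Returns ``(statistic, df, p_value)``.  Zero row or column marginals
    make expected counts undefined and raise.
    """
    c = table.counts
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column marginal is zero")
    statistic, p, df, _ = stats.chi2_contingency(c, correction=False)
    return float(statistic), int(df), float(p)


def discrimination_report(
    cohort: list[CohortRecord], symptom: str, grouping: str
) -> dict:
    """Does each method's severity discriminate a clinical grouping?

    For each method, builds the 4x2 severity-by-group table, runs the
    chi-squared test (p = 1 with a note when the grouping is constant),
    computes the adverse-group share within each severity category, and
    reports whether that share is non-decreasing with severity — the
    qualitative signature of a method that tracks true impairment.
    """
    if grouping not in GROUP_LABELS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {list(GROUP_LABELS)}")
    reference, adverse = GROUP_LABELS[grouping]
    missing = [r.subject_id for r in cohort if getattr(r, grouping) is None]
    if missing:
        raise ValueError(f"subjects missing {grouping}: {missing}")

    report: dict = {"symptom": symptom, "grouping": grouping, "n": len(cohort), "methods": {}}
    for method in ("atlas", "peak"):
        counts = np.zeros((4, 2), dtype=int)
        for rec in cohort:
            sev = rec.severity(symptom, method)
            if sev is None:
                raise ValueError(f"subject {rec.subject_id} missing {method} classification")
            counts[int(sev), 0 if getattr(rec, grouping) == reference else 1] += 1
        table = ContingencyTable(
            [str(s) for s in _SEVERITY_ORDER], [reference, adverse], counts
        )
        entry: dict = {"table": table.to_frame().to_dict()}
        # unoccupied severity rows carry no information; drop them so they
        # cannot void the test
        occupied = counts.sum(axis=1) > 0
        try:
            if occupied.sum() < 2:
                raise ValueError("fewer than two occupied severity categories")
            trimmed = ContingencyTable(
                [str(s) for s, keep in zip(_SEVERITY_ORDER, occupied) if keep],
                [reference, adverse],
                counts[occupied],
            )
            statistic, df, p = chi_squared_test(trimmed)
            entry.update(statistic=statistic, df=df, p_value=p)
        except ValueError:
            entry.update(statistic=None, df=None, p_value=1.0, note="degenerate grouping")
        row_totals = counts.sum(axis=1)
        share = np.divide(
            counts[:, 1], row_totals, out=np.full(4, np.nan), where=row_totals > 0
        )
        entry["adverse_share"] = [None if math.isnan(s) else float(s) for s in share]
        observed = share[~np.isnan(share)]
        entry["monotone_trend"] = bool(np.all(np.diff(observed) >= 0))
        report["methods"][method] = entry
    return report
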