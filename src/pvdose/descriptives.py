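"""Descriptive analysis of dosing-error report counts.

Given a validated dataset and a dosing-error taxonomy this module tallies
reports per (drug, category) cell, turns the tallies into shares of the
dosing-error total (by category or by drug), relates each cell to the
drug's all-cause ADR total, computes fatal and not-recovered/not-resolved
outcome proportions, and measures the Pearson correlation between
per-category counts and total ADR counts across drugs.

Percentages are rounded half-up to two decimals, the convention used for
published pharmacovigilance summaries; unrounded values are available via
``ndigits=None`` and always sum to exactly 100 along the chosen axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError
from .io_counts import Dataset, OutcomeClass
from .taxonomy import DoseErrorCategory, PTCategoryMap, classify_pt

__all__ = [
    "CategoryCountMatrix",
    "CorrelationResult",
    "round_half_up",
    "category_counts",
    "share_of_dosing_errors",
    "share_of_total_adrs",
    "group_share_of_totals",
    "outcome_proportion",
    "pearson_r",
    "pearson_p",
    "correlation_table",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.125 -> 0.13 at 2 digits).

    Python's builtin ``round`` is banker's rounding; published percentage
    tables in this field round half up, so shares use this instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _maybe_round(x: float, ndigits: Optional[int]) -> float:
    return x if ndigits is None else round_half_up(x, ndigits)


@dataclass
class CategoryCountMatrix:
    """Report counts per (drug, dosing-error category) plus drug totals."""

    cells: dict[tuple[str, DoseErrorCategory], int] = field(default_factory=dict)
    drug_totals: dict[str, int] = field(default_factory=dict)

    def cell(self, drug_id: str, cat: DoseErrorCategory) -> int:
        return self.cells.get((drug_id, cat), 0)

    def drugs(self) -> list[str]:
        return sorted(self.drug_totals)

    def category_total(self, cat: DoseErrorCategory) -> int:
        return sum(v for (_, c), v in self.cells.items() if c is cat)

    def drug_total_errors(self, drug_id: str) -> int:
        return sum(v for (d, _), v in self.cells.items() if d == drug_id)

    def grand_total(self) -> int:
        return sum(self.cells.values())


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson correlation with its two-sided t-based p-value."""

    r: float
    n: int
    p_two_sided: Optional[float] = None


def category_counts(ds: Dataset, taxonomy: PTCategoryMap) -> CategoryCountMatrix:
    """Tally reports per (drug, category), ignoring uncategorized PTs.

    Excluded terms (e.g. anything "intentional") raise from
    :func:`classify_pt`; run :func:`pvdose.io_counts.validate_dataset`
    first to surface them as findings instead.
    """
    m = CategoryCountMatrix()
    for prof in ds.profiles:
        m.drug_totals[prof.drug_id] = prof.total_adrs
        for ptc in prof.pt_counts:
            cat = classify_pt(ptc.pt_name, taxonomy)
            if cat is None:
                continue
            key = (prof.drug_id, cat)
            m.cells[key] = m.cells.get(key, 0) + ptc.n_reports
    return m


def share_of_dosing_errors(
    m: CategoryCountMatrix,
    axis: str = "by_category",
    ndigits: Optional[int] = 2,
) -> dict:
    """Percent of the grand dosing-error total, by category or by drug.

    Unrounded shares sum to exactly 100; the default half-up rounding to
    two decimals can move the sum by up to a few hundredths.
    """
    grand = m.grand_total()
    if grand == 0:
        raise DegenerateInputError("no dosing-error reports to take shares of")
    if axis == "by_category":
        raw = {cat: m.category_total(cat) for cat in DoseErrorCategory}
    elif axis == "by_drug":
        raw = {d: m.drug_total_errors(d) for d in m.drugs()}
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return {k: _maybe_round(100.0 * v / grand, ndigits) for k, v in raw.items()}


def share_of_total_adrs(
    m: CategoryCountMatrix,
    drug: str,
    cat: DoseErrorCategory,
    ndigits: Optional[int] = 2,
) -> float:
    """Percent of the drug's all-cause ADR total in one error category."""
    total = m.drug_totals.get(drug)
    if total is None:
        raise KeyError(drug)
    if total == 0:
        raise DegenerateInputError(f"{drug} has zero total ADRs")
    return _maybe_round(100.0 * m.cell(drug, cat) / total, ndigits)


def group_share_of_totals(
    ds: Dataset, group: Sequence[str], ndigits: Optional[int] = 2
) -> float:
    """Percent of all reports in the dataset belonging to ``group`` drugs.

    Used e.g. for the share of direct oral anticoagulant reports among all
    anticoagulant-class reports when the dataset carries a pooled
    comparator profile.
    """
    denom = sum(p.total_adrs for p in ds.profiles)
    if denom == 0:
        raise DegenerateInputError("dataset has zero total reports")
    num = sum(ds.profile(d).total_adrs for d in group)
    return _maybe_round(100.0 * num / denom, ndigits)


def outcome_proportion(
    ds: Dataset,
    taxonomy: PTCategoryMap,
    drug: str,
    cat: DoseErrorCategory,
    outcome: OutcomeClass,
    ndigits: Optional[int] = 2,
) -> float:
    """Percent of a drug×category's dosing-error reports with an outcome.

    The denominator is the drug's dosing-error count in that category, not
    its all-cause ADR total.  Raises if the category count is zero or if
    any contributing PT has an unknown count for the requested outcome.
    """
    denom = 0
    num = 0
    for ptc in ds.profile(drug).pt_counts:
        if classify_pt(ptc.pt_name, taxonomy) is not cat:
            continue
        denom += ptc.n_reports
        k = ptc.outcome_count(outcome)
        if k is None:
            raise DegenerateInputError(
                f"{outcome} count unknown for ({drug}, {ptc.pt_name!r})"
            )
        num += k
    if denom == 0:
        raise DegenerateInputError(f"{drug} has no {cat} dosing-error reports")
    return _maybe_round(100.0 * num / denom, ndigits)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson product-moment correlation of two aligned vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise DegenerateInputError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector has undefined correlation")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n=n)


def pearson_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation.

    Uses the exact small-sample transform t = r sqrt(n-2) / sqrt(1-r^2)
    referred to Student's t with n-2 degrees of freedom; returns 0 at
    |r| = 1.
    """
    if abs(r) > 1:
        raise ValueError(f"|r| = {abs(r)} exceeds 1")
    if n < 3:
        raise DegenerateInputError("need n >= 3")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


#: correlation_table row labels, in output order
_CORR_SERIES = (
    ("improper_dose", DoseErrorCategory.IMPROPER_DOSE),
    ("overdose", DoseErrorCategory.OVERDOSE),
    ("underdose", DoseErrorCategory.UNDERDOSE),
    ("fatal", None),
    ("nr_ns", None),
)


def correlation_table(
    ds: Dataset, taxonomy: PTCategoryMap
) -> dict[str, Optional[CorrelationResult]]:
    """Correlate each per-drug dosing-error series with total ADR counts.

    Five series are attempted across the drugs that carry dosing-error
    counts: the three error categories plus per-drug fatal and NR/NS
    dosing-error totals.  A series whose counts are not fully known for
    every drug (unrecorded outcome tallies) yields ``None`` rather than a
    correlation computed on a silently shrunken sample.
    """
    m = category_counts(ds, taxonomy)
    drugs = [d for d in m.drugs() if m.drug_total_errors(d) > 0]
    totals = [m.drug_totals[d] for d in drugs]

    out: dict[str, Optional[CorrelationResult]] = {}
    for label, cat in _CORR_SERIES:
        if cat is not None:
            series: list[Optional[int]] = [m.cell(d, cat) for d in drugs]
        else:
            outcome = (
                OutcomeClass.FATAL
                if label == "fatal"
                else OutcomeClass.NOT_RECOVERED_NOT_RESOLVED
            )
            series = []
            for d in drugs:
                tally: Optional[int] = 0
                for ptc in ds.profile(d).pt_counts:
                    if classify_pt(ptc.pt_name, taxonomy) is None:
                        continue
                    k = ptc.outcome_count(outcome)
                    if k is None:
                        tally = None
                        break
                    tally += k
                series.append(tally)
        if any(v is None for v in series) or len(drugs) < 3:
            out[label] = None
            continue
        try:
            res = pearson_r([float(v) for v in series], totals)
        except DegenerateInputError:
            out[label] = None
            continue
        out[label] = CorrelationResult(
            r=res.r, n=res.n, p_two_sided=pearson_p(res.r, res.n)
        )
    return out
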