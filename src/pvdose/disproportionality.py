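"""Case/non-case disproportionality analysis via the reporting odds ratio.

For a target drug and one comparator, reports are cross-classified into a
2×2 contingency table:

====================  ==============  ==================
                      dosing-error     all other reports
                      reports (cases)  (non-cases)
====================  ==============  ==================
target drug            a               b = N_target − a
comparator drug        c               d = N_comp  − c
====================  ==============  ==================

The reporting odds ratio is ROR = (a·d)/(b·c).  Its confidence interval
uses the Woolf log-normal method: SE = sqrt(1/a + 1/b + 1/c + 1/d) and
CI = exp(ln ROR ± z_{1−α/2}·SE); the p-value is the two-sided normal tail
of |ln ROR|/SE, the unique test dual to this interval (the interval
excludes 1 exactly when p < α).  Tables containing a zero cell optionally
receive the Haldane–Anscombe +0.5 correction on all four cells.

A *signal* follows the EMA rule for spontaneous-report screening: at least
``min_cases`` uncorrected cases **and** a 95% CI lower bound above 1.
The ROR screens for disproportionate reporting only; it is not a risk
estimate and supports no causal reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import math

import pandas as pd
import yaml
from scipy import stats

from .errors import DegenerateInputError, MissingDrugError
from .io_counts import Dataset, Finding
from .taxonomy import DoseErrorCategory, PTCategoryMap, classify_pt

__all__ = [
    "ContingencyTable",
    "RORResult",
    "ComparatorPanel",
    "DEFAULT_PANEL",
    "PanelResults",
    "build_contingency",
    "ror_estimate",
    "ema_signal",
    "significance_stars",
    "panel_analysis",
]

#: z quantile for a 95% interval, fixed to the conventional 6-figure value
Z_975 = 1.959964


@dataclass(frozen=True)
class ContingencyTable:
    """A 2×2 case/non-case table; entries are floats once corrected."""

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False
    n_cases: int = 0  # uncorrected target-case count, kept for the signal rule

    def swapped(self) -> "ContingencyTable":
        """Exchange target and comparator rows."""
        return ContingencyTable(
            self.c, self.d, self.a, self.b, self.corrected, int(self.c)
        )


@dataclass(frozen=True)
class RORResult:
    """Reporting odds ratio with Woolf CI, z-test p-value and signal verdict."""

    ror: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    n_cases: int
    alpha: float = 0.05
    corrected: bool = False
    is_signal: bool = False
    target: str = ""
    comparator: str = ""
    category: Optional[DoseErrorCategory] = None
    table: Optional[ContingencyTable] = None


def build_contingency(
    target_cases: int,
    target_total: int,
    comp_cases: int,
    comp_total: int,
    zero_policy: str = "haldane",
) -> ContingencyTable:
    """Build the 2×2 table from case counts and all-cause report totals.

    ``zero_policy`` controls tables with an empty cell: ``"haldane"`` adds
    0.5 to all four cells and flags the table as corrected; ``"reject"``
    raises :class:`DegenerateInputError`.
    """
    if zero_policy not in ("haldane", "reject"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    for label, cases, total in (
        ("target", target_cases, target_total),
        ("comparator", comp_cases, comp_total),
    ):
        if cases < 0 or total < 0:
            raise ValueError(f"negative counts for {label}")
        if cases > total:
            raise ValueError(
                f"{label} cases ({cases}) exceed total reports ({total})"
            )
    a, b = float(target_cases), float(target_total - target_cases)
    c, d = float(comp_cases), float(comp_total - comp_cases)
    if min(a, b, c, d) == 0.0:
        if zero_policy == "reject":
            raise DegenerateInputError(
                "contingency table has an empty cell; odds ratio undefined"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return ContingencyTable(a, b, c, d, corrected=True, n_cases=target_cases)
    return ContingencyTable(a, b, c, d, corrected=False, n_cases=target_cases)


def ror_estimate(
    t: ContingencyTable,
    alpha: float = 0.05,
    min_cases: int = 5,
) -> RORResult:
    """Point estimate, Woolf CI and dual z-test for one 2×2 table."""
    if min(t.a, t.b, t.c, t.d) <= 0:
        raise DegenerateInputError(
            "all four cells must be positive (apply the Haldane correction "
            "or drop the comparator)"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)
    z = Z_975 if alpha == 0.05 else float(stats.norm.ppf(1.0 - alpha / 2.0))
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - z * se)
    ci_high = math.exp(log_ror + z * se)
    p = float(2.0 * stats.norm.sf(abs(log_ror) / se))
    res = RORResult(
        ror=ror,
        ci_low=ci_low,
        ci_high=ci_high,
        p_two_sided=p,
        n_cases=t.n_cases,
        alpha=alpha,
        corrected=t.corrected,
        table=t,
    )
    return RORResult(**{**res.__dict__, "is_signal": ema_signal(res, min_cases)})


def ema_signal(r: RORResult, min_cases: int = 5) -> bool:
    """EMA screening rule: ≥ ``min_cases`` cases and CI lower bound > 1.

    The case floor applies to the uncorrected target-case count, so a
    Haldane-corrected table with 4 real cases never signals at the
    default floor.
    """
    return r.n_cases >= min_cases and r.ci_low > 1.0


def significance_stars(p: float) -> str:
    """Conventional significance stars: ``*`` p<0.05 up to ``****`` p≤1e-4."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# comparator panel
# ---------------------------------------------------------------------------

@dataclass
class ComparatorPanel:
    """An ordered list of comparator drugs with pharmacologic class labels."""

    comparators: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [c for c, _ in self.comparators]
        if not ids:
            raise ValueError("panel must be non-empty")
        if len(set(ids)) != len(ids):
            raise ValueError("panel contains duplicate comparator ids")

    def ids(self) -> list[str]:
        return [c for c, _ in self.comparators]

    def __len__(self) -> int:
        return len(self.comparators)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ComparatorPanel":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls([(str(e["drug"]), str(e.get("class", ""))) for e in doc])

    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = [{"drug": d, "class": c} for d, c in self.comparators]
        Path(path).write_text(
            yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
        )


def _default_panel() -> ComparatorPanel:
    ac = [
        ("heparin", "unfractionated heparin"),
        ("dalteparin", "low molecular weight heparin"),
        ("enoxaparin", "low molecular weight heparin"),
        ("nadroparin", "low molecular weight heparin"),
        ("tinzaparin", "low molecular weight heparin"),
        ("reviparin", "low molecular weight heparin"),
        ("parnaparin", "low molecular weight heparin"),
        ("certoparin", "low molecular weight heparin"),
        ("bemiparin", "low molecular weight heparin"),
        ("semuloparin", "low molecular weight heparin"),
        ("deligoparin", "low molecular weight heparin"),
        ("fondaparinux", "parenteral direct factor Xa inhibitor"),
        ("danaparoid", "heparinoid"),
        ("pentosan polysulphate", "heparinoid"),
        ("argatroban", "parenteral direct thrombin inhibitor"),
        ("desirudin", "parenteral direct thrombin inhibitor"),
        ("lepirudin", "parenteral direct thrombin inhibitor"),
        ("bivalirudin", "parenteral direct thrombin inhibitor"),
        ("warfarin", "vitamin K antagonist"),
        ("acenocoumarol", "vitamin K antagonist"),
        ("dicumarol", "vitamin K antagonist"),
        ("phenindione", "vitamin K antagonist"),
        ("anisindione", "vitamin K antagonist"),
        ("fluindione", "vitamin K antagonist"),
    ]
    ap = [
        ("clopidogrel", "platelet aggregation inhibitor"),
        ("ticagrelor", "platelet aggregation inhibitor"),
        ("prasugrel", "platelet aggregation inhibitor"),
        ("ticlopidine", "platelet aggregation inhibitor"),
        ("cilostazol", "phosphodiesterase type 3 inhibitor"),
        ("triflusal", "platelet aggregation inhibitor"),
        ("abciximab", "glycoprotein IIb/IIIa inhibitor"),
        ("eptifibatide", "glycoprotein IIb/IIIa inhibitor"),
        ("tirofiban", "glycoprotein IIb/IIIa inhibitor"),
        ("vorapaxar", "protease-activated receptor-1 antagonist"),
        ("dipyridamole", "nucleoside transport and PDE3 inhibitor"),
        ("dipyridamole and acetylsalicylic acid", "fixed combination"),
        ("acetylsalicylic acid and clopidogrel", "fixed combination"),
    ]
    return ComparatorPanel(ac + ap)


#: Default reference set for anticoagulant dosing-error screening:
#: 24 anticoagulants plus 13 antiplatelet agents (two fixed combinations
#: carried as distinct drugs).
DEFAULT_PANEL: ComparatorPanel = _default_panel()


# ---------------------------------------------------------------------------
# panel analysis
# ---------------------------------------------------------------------------

@dataclass
class PanelResults:
    """Results of one target drug screened against a comparator panel.

    ``results`` holds one :class:`RORResult` per comparator present in the
    dataset, in panel order; comparators missing from the dataset are
    reported in ``skipped`` rather than silently dropped.
    """

    target: str
    category: DoseErrorCategory
    results: list[RORResult] = field(default_factory=list)
    skipped: list[Finding] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Forest-table data frame (one comparator per row)."""
        rows = []
        for r in self.results:
            t = r.table
            rows.append(
                {
                    "target": r.target,
                    "comparator": r.comparator,
                    "category": str(r.category),
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "corrected": r.corrected,
                    "ror": r.ror,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p_two_sided,
                    "stars": significance_stars(r.p_two_sided),
                    "signal": r.is_signal,
                }
            )
        return pd.DataFrame(rows)

    def signals(self) -> list[RORResult]:
        return [r for r in self.results if r.is_signal]


def _category_cases(ds: Dataset, taxonomy: PTCategoryMap, drug: str,
                    cat: DoseErrorCategory) -> int:
    return sum(
        ptc.n_reports
        for ptc in ds.profile(drug).pt_counts
        if classify_pt(ptc.pt_name, taxonomy) is cat
    )


def panel_analysis(
    ds: Dataset,
    taxonomy: PTCategoryMap,
    target: str,
    panel: ComparatorPanel,
    cat: DoseErrorCategory,
    alpha: float = 0.05,
    min_cases: int = 5,
    zero_policy: str = "haldane",
) -> PanelResults:
    """Screen one target drug against every panel comparator for one category.

    All of a drug's reports count toward its total regardless of the
    drug's role in the report; cases are the reports carrying a preferred
    term of the requested dosing-error category.
    """
    if target not in ds:
        raise MissingDrugError(f"target drug {target!r} not in dataset")
    out = PanelResults(target=target, category=cat)
    t_cases = _category_cases(ds, taxonomy, target, cat)
    t_total = ds.profile(target).total_adrs
    for comp, _cls in panel.comparators:
        if comp not in ds:
            out.skipped.append(
                Finding("warning", f"comparator {comp!r} absent from dataset")
            )
            continue
        c_cases = _category_cases(ds, taxonomy, comp, cat)
        c_total = ds.profile(comp).total_adrs
        try:
            table = build_contingency(
                t_cases, t_total, c_cases, c_total, zero_policy
            )
            res = ror_estimate(table, alpha=alpha, min_cases=min_cases)
        except DegenerateInputError as exc:
            out.skipped.append(
                Finding("warning", f"comparator {comp!r}: {exc}")
            )
            continue
        out.results.append(
            RORResult(
                **{
                    **res.__dict__,
                    "target": target,
                    "comparator": comp,
                    "category": cat,
                }
            )
        )
    return out
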