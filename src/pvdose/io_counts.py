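"""Reading, validating and writing aggregated spontaneous-report count tables.

The input shape mirrors what a line listing aggregated from a
spontaneous-report portal looks like after tallying: one row per
(drug, preferred term) with the number of reports and per-outcome counts,
plus one total ADR count per drug covering *all* system organ classes (the
total is carried, never derived, because it spans far more than the
dosing-error terms).

Outcome labels are collapsed to three classes: ``fatal``,
``not_recovered_not_resolved`` (NR/NS) and ``other`` (which absorbs
recovered, recovering, resolved and unknown).  Outcome counts may be
missing (unknown) for a row; they are then stored as ``None`` and any
statistic needing them refuses to guess.

Formats
-------
CSV: header ``drug,pt,n_reports,n_fatal,n_nr_ns``; drug totals either in a
separate two-column file ``drug,total_adrs`` or as in-band rows with
``pt == "__TOTAL__"`` (the total carried in ``n_reports``).  Thousands
separators ("131,182") and Unicode minus signs are normalized on read.
JSON: a direct mirror of the :class:`Dataset` structure.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import DatasetValidationError, ExcludedTermError, ParseError
from .taxonomy import DoseErrorCategory, PTCategoryMap, classify_pt

__all__ = [
    "OutcomeClass",
    "PTCount",
    "DrugCountProfile",
    "Dataset",
    "Finding",
    "TOTAL_SENTINEL",
    "read_dataset",
    "validate_dataset",
    "write_table",
    "dataset_to_frames",
    "write_dataset",
]

TOTAL_SENTINEL = "__TOTAL__"

COUNT_COLUMNS = ["drug", "pt", "n_reports", "n_fatal", "n_nr_ns"]
TOTALS_COLUMNS = ["drug", "total_adrs"]


class OutcomeClass(str, Enum):
    """Collapsed reaction-outcome classes used throughout the analysis."""

    FATAL = "fatal"
    NOT_RECOVERED_NOT_RESOLVED = "not_recovered_not_resolved"
    OTHER = "other"

    def __str__(self) -> str:
        return self.value


@dataclass
class PTCount:
    """Report counts for one (drug, preferred term) pair.

    ``n_fatal`` / ``n_nr_ns`` are ``None`` when unknown; ``n_other`` is
    derived, never stored.
    """

    pt_name: str
    n_reports: int
    n_fatal: Optional[int] = None
    n_nr_ns: Optional[int] = None

    def outcome_count(self, outcome: OutcomeClass) -> Optional[int]:
        if outcome is OutcomeClass.FATAL:
            return self.n_fatal
        if outcome is OutcomeClass.NOT_RECOVERED_NOT_RESOLVED:
            return self.n_nr_ns
        if self.n_fatal is None or self.n_nr_ns is None:
            return None
        return self.n_reports - self.n_fatal - self.n_nr_ns


@dataclass
class DrugCountProfile:
    """Per-drug total ADR count plus per-PT tallies."""

    drug_id: str
    total_adrs: int
    pt_counts: list[PTCount] = field(default_factory=list)


@dataclass
class Dataset:
    """A validated collection of drug count profiles."""

    profiles: list[DrugCountProfile] = field(default_factory=list)
    provenance: str = ""

    def drug_ids(self) -> list[str]:
        return [p.drug_id for p in self.profiles]

    def profile(self, drug_id: str) -> DrugCountProfile:
        for p in self.profiles:
            if p.drug_id == drug_id:
                return p
        raise KeyError(drug_id)

    def __contains__(self, drug_id: str) -> bool:
        return any(p.drug_id == drug_id for p in self.profiles)


@dataclass(frozen=True)
class Finding:
    """A validation finding; ``level`` is 'error' or 'warning'."""

    level: str
    message: str

    def __str__(self) -> str:
        return f"{self.level}: {self.message}"


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_NUM_CLEAN = re.compile(r"[,\s ]")


def _parse_count(raw, where: str, allow_missing: bool = False) -> Optional[int]:
    """Parse one count cell; accepts '131,182' and U+2212 minus."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        if allow_missing:
            return None
        raise ParseError(f"missing count at {where}")
    text = _NUM_CLEAN.sub("", str(raw).strip()).replace("−", "-")
    if text == "":
        if allow_missing:
            return None
        raise ParseError(f"missing count at {where}")
    try:
        value = int(text)
    except ValueError as exc:
        raise ParseError(f"unparseable count {raw!r} at {where}") from exc
    return value


def _read_counts_frame(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.empty and df.columns.size == 0:
        raise ParseError(f"{path} is empty")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path} lacks required columns {missing}")
    return df


def read_dataset(
    path: Union[str, Path],
    format: str = "csv",
    totals_path: Optional[Union[str, Path]] = None,
    provenance: str = "",
) -> Dataset:
    """Read and structurally validate a count dataset.

    Parameters
    ----------
    path
        Counts table (CSV or JSON).  For CSV, drug totals come either from
        ``totals_path`` or from rows whose ``pt`` equals ``"__TOTAL__"``.
    format
        ``"csv"`` or ``"json"``.

    Raises
    ------
    ParseError
        On unreadable files, missing columns or unparseable numbers,
        naming the offending row.
    DatasetValidationError
        Listing *all* structural violations (negative counts, duplicate
        drug–PT pairs, missing totals, outcome sums exceeding reports).
    """
    path = Path(path)
    if format == "json":
        return _read_dataset_json(path, provenance)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    df = _read_counts_frame(path)
    totals: dict[str, int] = {}
    rows: list[tuple[str, str, int, Optional[int], Optional[int]]] = []

    for idx, rec in df.iterrows():
        where = f"{path.name} row {idx + 2}"  # +2: header + 1-based
        drug = str(rec["drug"]).strip()
        pt = str(rec["pt"]).strip()
        if not drug or not pt:
            raise ParseError(f"empty drug or pt at {where}")
        if pt == TOTAL_SENTINEL:
            totals[drug] = _parse_count(rec["n_reports"], where)
            continue
        rows.append(
            (
                drug,
                pt,
                _parse_count(rec["n_reports"], where),
                _parse_count(rec["n_fatal"], where, allow_missing=True),
                _parse_count(rec["n_nr_ns"], where, allow_missing=True),
            )
        )

    if totals_path is not None:
        tdf = pd.read_csv(totals_path, dtype=str)
        missing = [c for c in TOTALS_COLUMNS if c not in tdf.columns]
        if missing:
            raise ParseError(f"{totals_path} lacks required columns {missing}")
        for idx, rec in tdf.iterrows():
            where = f"{Path(totals_path).name} row {idx + 2}"
            totals[str(rec["drug"]).strip()] = _parse_count(
                rec["total_adrs"], where
            )

    return _assemble(rows, totals, provenance)


def _read_dataset_json(path: Path, provenance: str) -> Dataset:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    rows = []
    totals = {}
    for prof in doc.get("profiles", []):
        drug = prof["drug_id"]
        totals[drug] = int(prof["total_adrs"])
        for ptc in prof.get("pt_counts", []):
            rows.append(
                (
                    drug,
                    ptc["pt_name"],
                    int(ptc["n_reports"]),
                    None if ptc.get("n_fatal") is None else int(ptc["n_fatal"]),
                    None if ptc.get("n_nr_ns") is None else int(ptc["n_nr_ns"]),
                )
            )
    return _assemble(rows, totals, provenance or doc.get("provenance", ""))


def _assemble(rows, totals, provenance) -> Dataset:
    violations: list[str] = []
    seen: set[tuple[str, str]] = set()
    by_drug: dict[str, list[PTCount]] = {}

    for drug, pt, n, nf, nn in rows:
        key = (drug, pt.casefold())
        if key in seen:
            violations.append(f"duplicate drug–PT pair ({drug}, {pt})")
        seen.add(key)
        for label, v in (("n_reports", n), ("n_fatal", nf), ("n_nr_ns", nn)):
            if v is not None and v < 0:
                violations.append(f"negative {label}={v} for ({drug}, {pt})")
        if nf is not None and nn is not None and n is not None and nf + nn > n:
            violations.append(
                f"outcome counts exceed n_reports for ({drug}, {pt})"
            )
        by_drug.setdefault(drug, []).append(PTCount(pt, n, nf, nn))

    for drug in by_drug:
        if drug not in totals:
            violations.append(f"no total ADR count for drug {drug}")
    for drug, total in totals.items():
        if total < 0:
            violations.append(f"negative total_adrs for drug {drug}")

    if violations:
        raise DatasetValidationError(violations)

    profiles = [
        DrugCountProfile(drug, totals[drug], by_drug.get(drug, []))
        for drug in sorted(totals)
    ]
    return Dataset(profiles=profiles, provenance=provenance)


# ---------------------------------------------------------------------------
# semantic validation against a taxonomy
# ---------------------------------------------------------------------------

def validate_dataset(ds: Dataset, taxonomy: PTCategoryMap) -> list[Finding]:
    """Cross-check a dataset against a dosing-error taxonomy.

    Returns findings rather than raising: warnings for PTs absent from the
    taxonomy (retained but uncategorized), errors for excluded terms and
    for per-category sums exceeding a drug's total ADR count.  An empty
    list means the dataset is clean.
    """
    findings: list[Finding] = []
    for prof in ds.profiles:
        sums = {cat: 0 for cat in DoseErrorCategory}
        for ptc in prof.pt_counts:
            try:
                cat = classify_pt(ptc.pt_name, taxonomy)
            except ExcludedTermError as exc:
                findings.append(Finding("error", str(exc)))
                continue
            if cat is None:
                findings.append(
                    Finding(
                        "warning",
                        f"PT {ptc.pt_name!r} ({prof.drug_id}) is not a "
                        "dosing-error term; it will be ignored",
                    )
                )
            else:
                sums[cat] += ptc.n_reports
        for cat, s in sums.items():
            if s > prof.total_adrs:
                findings.append(
                    Finding(
                        "error",
                        f"{prof.drug_id}: {cat} count {s} exceeds total "
                        f"ADRs {prof.total_adrs}",
                    )
                )
    return findings


# ---------------------------------------------------------------------------
# result-table writing
# ---------------------------------------------------------------------------

_FOUR_DP = {"ror", "ci_low", "ci_high", "r"}
_TWO_DP_SUFFIXES = ("_pct", "_share", "percent")
_SORT_KEYS = ["drug", "drug_id", "target", "category", "comparator"]


def _format_p(p: float) -> str:
    if pd.isna(p):
        return ""
    return f"{p:.4e}" if 0 < p < 1e-4 else f"{p:.4f}"


def _format_cell(col: str, value):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if col in _FOUR_DP:
        return f"{float(value):.4f}"
    if col == "p" or col.startswith("p_"):
        return _format_p(float(value))
    if col.endswith(_TWO_DP_SUFFIXES) or col == "pct":
        return f"{float(value):.2f}"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_table(
    rows: Sequence[dict],
    path: Union[str, Path],
    format: str = "csv",
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Write homogeneous result rows with deterministic order and precision.

    Rows are sorted by whichever of drug/target/category/comparator columns
    are present; reporting-odds-ratio and CI columns print at 4 decimals,
    percentage columns at 2, p-values in scientific notation below 1e-4.
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("columns required when rows is empty")
        columns = list(rows[0].keys())
    sort_cols = [c for c in _SORT_KEYS if c in columns]
    rows = sorted(rows, key=lambda r: tuple(str(r.get(c, "")) for c in sort_cols))

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        payload = [
            {c: r.get(c) for c in columns} for r in rows
        ]
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    lines = [",".join(columns)]
    for r in rows:
        lines.append(",".join(_format_cell(c, r.get(c)) for c in columns))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# dataset serialization (used by the simulate command)
# ---------------------------------------------------------------------------

def dataset_to_frames(ds: Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (counts, totals) data frames in the canonical CSV layout."""
    crows = []
    trows = []
    for prof in sorted(ds.profiles, key=lambda p: p.drug_id):
        trows.append({"drug": prof.drug_id, "total_adrs": prof.total_adrs})
        for ptc in sorted(prof.pt_counts, key=lambda c: c.pt_name.casefold()):
            crows.append(
                {
                    "drug": prof.drug_id,
                    "pt": ptc.pt_name,
                    "n_reports": ptc.n_reports,
                    "n_fatal": "" if ptc.n_fatal is None else ptc.n_fatal,
                    "n_nr_ns": "" if ptc.n_nr_ns is None else ptc.n_nr_ns,
                }
            )
    return (
        pd.DataFrame(crows, columns=COUNT_COLUMNS),
        pd.DataFrame(trows, columns=TOTALS_COLUMNS),
    )


def write_dataset(ds: Dataset, counts_path: Union[str, Path],
                  totals_path: Union[str, Path]) -> None:
    counts, totals = dataset_to_frames(ds)
    Path(counts_path).parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(counts_path, index=False)
    totals.to_csv(totals_path, index=False)
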