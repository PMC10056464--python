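"""Dosing-error vocabulary: MedDRA preferred terms grouped into categories.

Medication errors related to drug dosing live under the MedDRA system organ
class "injury, poisoning and procedural complications".  For the analysis
implemented here each relevant preferred term (PT) belongs to exactly one of
three categories:

* **improper dose** — dosing errors not attributable to too much or too
  little drug (wrong formulation, titration errors, calculation errors...);
* **overdose** — more drug than intended;
* **underdose** — less drug than intended, including every PT containing
  "dose omission".

Terms describing *intentional* overdose/underdose/improper dosing are not
medication errors under EMA good-practice guidance and are actively
excluded: classifying such a term raises :class:`ExcludedTermError` rather
than silently returning nothing, so a pipeline cannot count them by
accident.

The default vocabulary ships embedded (24 PTs: 12 improper dose, 4
overdose, 8 underdose) and can be extended programmatically or from a YAML
file; the full MedDRA dictionary is deliberately not distributed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .errors import ExcludedTermError, TaxonomyConflictError

__all__ = [
    "DoseErrorCategory",
    "PreferredTerm",
    "PTCategoryMap",
    "load_default_taxonomy",
    "classify_pt",
    "extend_taxonomy",
    "load_taxonomy_yaml",
    "save_taxonomy_yaml",
]


class DoseErrorCategory(str, Enum):
    """The three-way grouping of dosing-error preferred terms."""

    IMPROPER_DOSE = "improper_dose"
    OVERDOSE = "overdose"
    UNDERDOSE = "underdose"

    def __str__(self) -> str:  # keeps CSV/YAML output plain
        return self.value


def normalize_pt(name: str) -> str:
    """Case-fold a PT label and collapse internal whitespace.

    MedDRA casing carries no meaning and database exports vary in spacing,
    so matching is performed on this normal form.
    """
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass(frozen=True)
class PreferredTerm:
    """A MedDRA preferred term together with its dosing-error category."""

    name: str
    category: DoseErrorCategory

    def __post_init__(self):
        if not self.name.strip():
            raise ValueError("preferred term name must be non-empty")


_DEFAULT_TERMS: dict[DoseErrorCategory, tuple[str, ...]] = {
    DoseErrorCategory.IMPROPER_DOSE: (
        "Dose calculation error",
        "Dose calculation error associated with device",
        "Drug dose titration not performed",
        "Drug titration error",
        "Incorrect dosage administered",
        "Incorrect dose administered",
        "Incorrect dose administered by device",
        "Incorrect dose administered by product",
        "Incorrect product dosage form administered",
        "Product dosage form confusion",
        "Wrong dosage formulation",
        "Wrong dose",
    ),
    DoseErrorCategory.OVERDOSE: (
        "Accidental overdose",
        "Extra dose administered",
        "Overdose",
        "Prescribed overdose",
    ),
    DoseErrorCategory.UNDERDOSE: (
        "Accidental underdose",
        "Drug dose omission by device",
        "Incomplete dose administered",
        "Prescribed underdose",
        "Product dose omission",
        "Product dose omission in error",
        "Product dose omission issue",
        "Underdose",
    ),
}

#: Markers whose presence in a PT label forces exclusion from the analysis.
#: Intentional overdose/underdose is not a medication error.
DEFAULT_EXCLUDED_MARKERS: tuple[str, ...] = ("intentional",)


@dataclass
class PTCategoryMap:
    """An immutable-by-convention mapping PT name -> dosing-error category.

    ``entries`` is keyed by the normalized PT name; the original label is
    kept on each :class:`PreferredTerm` for display and serialization.
    """

    entries: dict[str, PreferredTerm] = field(default_factory=dict)
    excluded_markers: tuple[str, ...] = DEFAULT_EXCLUDED_MARKERS

    def __post_init__(self):
        self.excluded_markers = tuple(
            normalize_pt(m) for m in self.excluded_markers
        )
        for key, term in self.entries.items():
            if self._marker_in(key):
                raise ExcludedTermError(
                    f"taxonomy entry {term.name!r} contains an excluded marker"
                )

    def _marker_in(self, normalized_name: str) -> Optional[str]:
        for marker in self.excluded_markers:
            if marker in normalized_name:
                return marker
        return None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt_name: str) -> bool:
        return normalize_pt(pt_name) in self.entries

    def category_sizes(self) -> dict[DoseErrorCategory, int]:
        sizes = {cat: 0 for cat in DoseErrorCategory}
        for term in self.entries.values():
            sizes[term.category] += 1
        return sizes

    def terms(self, category: Optional[DoseErrorCategory] = None) -> list[PreferredTerm]:
        out = [
            t for t in self.entries.values()
            if category is None or t.category is category
        ]
        return sorted(out, key=lambda t: normalize_pt(t.name))


def _build_map(
    terms: Iterable[PreferredTerm],
    excluded_markers: Iterable[str] = DEFAULT_EXCLUDED_MARKERS,
) -> PTCategoryMap:
    entries: dict[str, PreferredTerm] = {}
    for term in terms:
        key = normalize_pt(term.name)
        existing = entries.get(key)
        if existing is not None and existing.category is not term.category:
            raise TaxonomyConflictError(
                f"{term.name!r} assigned to both {existing.category} and "
                f"{term.category}"
            )
        entries[key] = existing or term
    return PTCategoryMap(entries=entries, excluded_markers=tuple(excluded_markers))


def load_default_taxonomy() -> PTCategoryMap:
    """Return the embedded default vocabulary (24 PTs; 12/4/8 split)."""
    terms = [
        PreferredTerm(name, cat)
        for cat, names in _DEFAULT_TERMS.items()
        for name in names
    ]
    return _build_map(terms)


def classify_pt(pt_name: str, pt_map: PTCategoryMap) -> Optional[DoseErrorCategory]:
    """Classify a preferred term into a dosing-error category.

    Matching is case-insensitive with internal whitespace collapsed.
    Returns ``None`` for terms absent from the map (e.g. "Headache").

    Raises
    ------
    ExcludedTermError
        If the name contains an exclusion marker such as "intentional",
        regardless of map contents — exclusion takes precedence.
    """
    if not pt_name or not pt_name.strip():
        raise ValueError("pt_name must be non-empty")
    key = normalize_pt(pt_name)
    marker = pt_map._marker_in(key)
    if marker is not None:
        raise ExcludedTermError(
            f"{pt_name!r} contains excluded marker {marker!r}; intentional "
            "dosing events are not medication errors"
        )
    term = pt_map.entries.get(key)
    return term.category if term is not None else None


def extend_taxonomy(
    pt_map: PTCategoryMap, additions: Iterable[PreferredTerm]
) -> PTCategoryMap:
    """Return a new map with ``additions`` merged in.

    Re-adding an existing term with the same category is a no-op; a
    conflicting category raises :class:`TaxonomyConflictError`; an addition
    containing an exclusion marker raises :class:`ExcludedTermError`.
    """
    additions = list(additions)
    for term in additions:
        if pt_map._marker_in(normalize_pt(term.name)):
            raise ExcludedTermError(
                f"cannot add {term.name!r}: contains an excluded marker"
            )
    return _build_map(
        list(pt_map.entries.values()) + additions, pt_map.excluded_markers
    )


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def save_taxonomy_yaml(pt_map: PTCategoryMap, path: Union[str, Path]) -> None:
    """Serialize a taxonomy to YAML (one list per category, sorted)."""
    doc = {
        cat.value: [t.name for t in pt_map.terms(cat)]
        for cat in DoseErrorCategory
    }
    doc["excluded_markers"] = list(pt_map.excluded_markers)
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )


def load_taxonomy_yaml(path: Union[str, Path]) -> PTCategoryMap:
    """Load a taxonomy from the YAML layout written by :func:`save_taxonomy_yaml`."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    terms = []
    for cat in DoseErrorCategory:
        for name in doc.get(cat.value, []) or []:
            terms.append(PreferredTerm(str(name), cat))
    markers = tuple(doc.get("excluded_markers", DEFAULT_EXCLUDED_MARKERS))
    return _build_map(terms, markers)
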