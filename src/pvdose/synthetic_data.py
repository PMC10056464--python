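"""Synthetic spontaneous-report count data with known planted structure.

The generator emulates the statistical shape of an aggregated
spontaneous-report extraction: each drug has a fixed total number of
reports, and each dosing-error preferred term occurs in a report with a
small baseline probability.  A *planted* effect multiplies the baseline
**odds** (not the probability) of every PT in a given category for a given
drug, so the exact implied odds ratio between any two drugs is known in
closed form at any baseline — that exact value is what confidence-interval
coverage and bias are measured against.  Outcome labels (fatal, NR/NS,
other) are multinomial per drug–PT cell.

Counts are generated at the aggregate (drug × PT) level, the shape the
analysis actually consumes; individual reports are never materialized.
All randomness flows through one explicitly seeded NumPy PCG64 generator,
so a fixed seed reproduces a bit-identical dataset.

The module also ships :func:`reference_fixture`, a deterministic dataset
encoding the published direct-oral-anticoagulant dosing-error counts used
by the worked examples and the acceptance checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .disproportionality import ComparatorPanel, panel_analysis
from .errors import ConfigError
from .io_counts import Dataset, DrugCountProfile, PTCount
from .taxonomy import (
    DoseErrorCategory,
    PTCategoryMap,
    classify_pt,
    load_default_taxonomy,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "RecoverySummary",
    "generate_dataset",
    "reference_fixture",
    "paper_fixture",
    "recovery_experiment",
]


@dataclass
class SimConfig:
    """Parameters of one synthetic extraction.

    Attributes
    ----------
    drugs
        ``(drug_id, total_reports)`` pairs; totals are all-cause report
        counts, typically 10^4–10^5 as for widely used drugs.
    pt_probs
        Baseline per-report event probability for each preferred term,
        shared across drugs before planting; dosing-error PTs in real
        spontaneous data sit around 10^-3–10^-2 of a drug's reports.
    planted_or
        Odds multipliers keyed by ``(drug_id, category)``; absent keys
        mean 1 (no effect).  The multiplier applies to every PT of that
        category for that drug.
    outcome_probs
        Per-drug ``(fatal, nr_ns, other)`` probability vector.
    seed
        Seed for the PCG64 generator; same seed, same dataset.
    """

    drugs: list[tuple[str, int]]
    pt_probs: dict[str, float]
    planted_or: dict[tuple[str, DoseErrorCategory], float] = field(
        default_factory=dict
    )
    outcome_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def validate(self, taxonomy: PTCategoryMap) -> None:
        if not self.drugs:
            raise ConfigError("no drugs configured")
        ids = [d for d, _ in self.drugs]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate drug ids")
        for d, n in self.drugs:
            if n <= 0:
                raise ConfigError(f"total_reports must be positive for {d}")
        for pt, p in self.pt_probs.items():
            if not 0.0 < p < 1.0:
                raise ConfigError(f"baseline probability for {pt!r} not in (0,1)")
        for key, m in self.planted_or.items():
            if m <= 0:
                raise ConfigError(f"planted odds multiplier for {key} not positive")
        for d, vec in self.outcome_probs.items():
            if len(vec) != 3 or any(v < 0 for v in vec):
                raise ConfigError(f"outcome probabilities for {d} malformed")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ConfigError(f"outcome probabilities for {d} do not sum to 1")
        for d, n in self.drugs:
            expected = sum(
                n * self.event_probability(d, pt, taxonomy)
                for pt in self.pt_probs
            )
            if expected >= n:
                raise ConfigError(
                    f"expected event count for {d} is not below its total"
                )

    def event_probability(
        self, drug_id: str, pt_name: str, taxonomy: PTCategoryMap
    ) -> float:
        """Per-report event probability after planting the odds shift."""
        p0 = self.pt_probs[pt_name]
        cat = classify_pt(pt_name, taxonomy)
        m = 1.0 if cat is None else self.planted_or.get((drug_id, cat), 1.0)
        odds = m * p0 / (1.0 - p0)
        return odds / (1.0 + odds)


@dataclass
class SimTruth:
    """Exact quantities implied by a :class:`SimConfig`.

    ``true_or[(target, comparator, category)]`` is the odds ratio of the
    aggregate per-report category probabilities of the two drugs —
    the estimand the reporting odds ratio targets in this design.
    """

    true_or: dict[tuple[str, str, DoseErrorCategory], float] = field(
        default_factory=dict
    )
    expected_counts: dict[tuple[str, str], float] = field(default_factory=dict)


def _aggregate_odds(cfg: SimConfig, taxonomy: PTCategoryMap, drug: str,
                    cat: DoseErrorCategory) -> Optional[float]:
    s = sum(
        cfg.event_probability(drug, pt, taxonomy)
        for pt in cfg.pt_probs
        if classify_pt(pt, taxonomy) is cat
    )
    if s == 0.0:
        return None
    return s / (1.0 - s)


def _truth(cfg: SimConfig, taxonomy: PTCategoryMap) -> SimTruth:
    truth = SimTruth()
    for drug, total in cfg.drugs:
        for pt in sorted(cfg.pt_probs):
            truth.expected_counts[(drug, pt)] = total * cfg.event_probability(
                drug, pt, taxonomy
            )
    ids = [d for d, _ in cfg.drugs]
    for cat in DoseErrorCategory:
        odds = {d: _aggregate_odds(cfg, taxonomy, d, cat) for d in ids}
        for t in ids:
            for c in ids:
                if t == c or odds[t] is None or odds[c] is None:
                    continue
                truth.true_or[(t, c, cat)] = odds[t] / odds[c]
    return truth


def generate_dataset(
    cfg: SimConfig, taxonomy: Optional[PTCategoryMap] = None
) -> tuple[Dataset, SimTruth]:
    """Draw one synthetic dataset and return it with its exact truth.

    Per drug and PT the event count is binomial in the drug's total
    reports at the planted probability; outcome counts are a multinomial
    split of that event count.  Identical seeds give bit-identical output.
    """
    taxonomy = taxonomy or load_default_taxonomy()
    cfg.validate(taxonomy)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    profiles = []
    for drug, total in cfg.drugs:
        fatal_p, nrns_p, other_p = cfg.outcome_probs.get(
            drug, (0.05, 0.15, 0.80)
        )
        pt_counts = []
        for pt in sorted(cfg.pt_probs):
            p = cfg.event_probability(drug, pt, taxonomy)
            n = int(rng.binomial(total, p))
            n_fatal, n_nrns, _ = rng.multinomial(
                n, [fatal_p, nrns_p, other_p]
            )
            pt_counts.append(PTCount(pt, n, int(n_fatal), int(n_nrns)))
        profiles.append(DrugCountProfile(drug, total, pt_counts))
    ds = Dataset(
        profiles=profiles,
        provenance=f"synthetic (seed={cfg.seed})",
    )
    return ds, _truth(cfg, taxonomy)


# ---------------------------------------------------------------------------
# published-count fixture
# ---------------------------------------------------------------------------

#: Representative PT used to carry each category's aggregate count in the
#: reference fixture (the per-PT breakdown behind the published category
#: totals is not public).
_CATEGORY_PT = {
    DoseErrorCategory.IMPROPER_DOSE: "Incorrect dose administered",
    DoseErrorCategory.OVERDOSE: "Overdose",
    DoseErrorCategory.UNDERDOSE: "Underdose",
}

# (drug, total, {cat: (n_reports, n_fatal, n_nr_ns)}); None = not public
_FIXTURE = [
    (
        "dabigatran",
        57627,
        {
            DoseErrorCategory.IMPROPER_DOSE: (72, 1, 7),
            DoseErrorCategory.OVERDOSE: (312, 31, 19),
            DoseErrorCategory.UNDERDOSE: (43, 0, None),
        },
    ),
    (
        "rivaroxaban",
        131182,
        {
            DoseErrorCategory.IMPROPER_DOSE: (1569, None, None),
            DoseErrorCategory.OVERDOSE: (415, 9, None),
            DoseErrorCategory.UNDERDOSE: (1703, None, None),
        },
    ),
    (
        "apixaban",
        70424,
        {
            DoseErrorCategory.IMPROPER_DOSE: (175, None, None),
            DoseErrorCategory.OVERDOSE: (482, 7, None),
            DoseErrorCategory.UNDERDOSE: (1637, None, None),
        },
    ),
    (
        "edoxaban",
        9318,
        {
            DoseErrorCategory.IMPROPER_DOSE: (225, 0, 87),
            DoseErrorCategory.OVERDOSE: (56, 5, None),
            DoseErrorCategory.UNDERDOSE: (136, 3, 19),
        },
    ),
]

#: Pooled total for the remaining anticoagulant-class drugs in the same
#: extraction window; no dosing-error breakdown is public for the pool.
_OTHER_AC = ("other_anticoagulants", 158767)


def reference_fixture() -> Dataset:
    """Deterministic dataset of published DOAC dosing-error counts.

    Encodes, for dabigatran, rivaroxaban, apixaban and edoxaban: the
    all-cause report totals, the dosing-error counts per category, and the
    fatal / not-recovered outcome counts wherever they are uniquely
    recoverable from published percentages (left unknown otherwise).  Each
    category's count rides on one representative preferred term because
    the per-PT breakdown was never published.  A pooled profile for the
    other anticoagulants carries only its report total.
    """
    profiles = []
    for drug, total, cats in _FIXTURE:
        pt_counts = [
            PTCount(_CATEGORY_PT[cat], n, nf, nn)
            for cat, (n, nf, nn) in cats.items()
        ]
        profiles.append(DrugCountProfile(drug, total, pt_counts))
    profiles.append(DrugCountProfile(_OTHER_AC[0], _OTHER_AC[1], []))
    return Dataset(
        profiles=profiles,
        provenance="published DOAC dosing-error counts (extraction to 2022-12-03)",
    )


#: Alias kept for discoverability: the fixture of in-publication counts.
paper_fixture = reference_fixture


# ---------------------------------------------------------------------------
# parameter-recovery experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of reporting-odds-ratio recovery."""

    replicates: int
    n_estimates: int
    bias_log_ror: float
    rmse_log_ror: float
    coverage: float
    signal_rate: float


def recovery_experiment(
    cfg: SimConfig,
    replicates: int,
    target: Optional[str] = None,
    taxonomy: Optional[PTCategoryMap] = None,
    alpha: float = 0.05,
    min_cases: int = 5,
) -> RecoverySummary:
    """Repeatedly simulate and re-estimate; summarize estimator behaviour.

    For each replicate a fresh dataset is drawn (seeds spawned
    deterministically from ``cfg.seed``) and the target drug — by default
    the first configured drug — is screened against all other drugs for
    every category with planted truth.  Reported are the mean error and
    RMSE of log ROR against the exact planted log odds ratio, the
    fraction of 95% CIs containing the truth, and the signal frequency.
    """
    if replicates < 1:
        raise ConfigError("need at least 1 replicate")
    taxonomy = taxonomy or load_default_taxonomy()
    cfg.validate(taxonomy)
    target = target or cfg.drugs[0][0]
    comparators = [d for d, _ in cfg.drugs if d != target]
    if not comparators:
        raise ConfigError("need at least one comparator drug")
    panel = ComparatorPanel([(c, "") for c in comparators])
    cats = sorted(
        {
            c
            for pt in cfg.pt_probs
            if (c := classify_pt(pt, taxonomy)) is not None
        },
        key=lambda c: c.value,
    )

    seeds = np.random.SeedSequence(cfg.seed).generate_state(replicates) % (2**31)
    errors: list[float] = []
    covered = 0
    signals = 0
    n_est = 0
    for rep_seed in seeds:
        rep_cfg = SimConfig(
            drugs=cfg.drugs,
            pt_probs=cfg.pt_probs,
            planted_or=cfg.planted_or,
            outcome_probs=cfg.outcome_probs,
            seed=int(rep_seed),
        )
        ds, truth = generate_dataset(rep_cfg, taxonomy)
        for cat in cats:
            res = panel_analysis(
                ds, taxonomy, target, panel, cat,
                alpha=alpha, min_cases=min_cases,
            )
            for r in res.results:
                theta = truth.true_or.get((target, r.comparator, cat))
                if theta is None:
                    continue
                n_est += 1
                errors.append(math.log(r.ror) - math.log(theta))
                if r.ci_low <= theta <= r.ci_high:
                    covered += 1
                if r.is_signal:
                    signals += 1
    err = np.asarray(errors)
    return RecoverySummary(
        replicates=replicates,
        n_estimates=n_est,
        bias_log_ror=float(err.mean()) if n_est else float("nan"),
        rmse_log_ror=float(np.sqrt((err**2).mean())) if n_est else float("nan"),
        coverage=covered / n_est if n_est else float("nan"),
        signal_rate=signals / n_est if n_est else float("nan"),
    )
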