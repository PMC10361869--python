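"""Cohort-level incompatibility analysis and report tables.

Every co-administered central-venous pair on every lumen of every included
patient receives exactly one resolved verdict.  Counting is by occurrence: a
pair found in k patients contributes k findings, and within one patient a
pair is counted once per (lumen, pair).  Not-evaluable findings are kept in a
separate ledger, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .charts import PatientChart, coadministered_pairs, meets_inclusion
from .kb import KnowledgeBase
from .resolution import Classification, DEFAULT_POLICY, ResolutionPolicy, Verdict, resolve_pair

#: quantile convention: weighted average at (n+1)p, the default of common
#: clinical statistics packages; switchable to any numpy method name
DEFAULT_QUANTILE_METHOD = "weibull"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent1(numerator: int, denominator: int) -> float:
    """Percentage with one decimal, half-up: percent1(64, 104) == 61.5."""
    if denominator == 0:
        raise ZeroDivisionError("percent1: denominator is zero")
    return round_half_up(100.0 * numerator / denominator, 1)


@dataclass(frozen=True)
class PairFinding:
    """One (patient, lumen, pair) co-administration with its resolved verdict."""

    patient_id: str
    lumen_id: int
    pair: tuple[str, str]
    verdict: Verdict

    @property
    def is_incompatible(self) -> bool:
        return self.verdict.classification is Classification.INCOMPATIBLE


@dataclass
class CohortSummary:
    n_admitted: int
    n_included: int
    n_patients_with_incompatibility: int
    per_patient_incompatible_counts: dict[str, int]
    n_incompatible_combinations: int
    n_not_evaluable: int

    def __post_init__(self):
        if self.n_included > self.n_admitted:
            raise ValueError("included patients exceed admitted patients")
        if self.n_patients_with_incompatibility > self.n_included:
            raise ValueError("patients with incompatibility exceed included patients")

    def to_dict(self) -> dict:
        d = {
            "n_admitted": self.n_admitted,
            "n_included": self.n_included,
            "n_patients_with_incompatibility": self.n_patients_with_incompatibility,
            "n_incompatible_combinations": self.n_incompatible_combinations,
            "n_not_evaluable": self.n_not_evaluable,
        }
        if self.n_included:
            d["pct_included"] = percent1(self.n_included, self.n_admitted)
            d["pct_patients_with_incompatibility"] = percent1(
                self.n_patients_with_incompatibility, self.n_included
            )
        return d


def analyze_cohort(
    charts: Sequence[PatientChart],
    kb: KnowledgeBase,
    policy: ResolutionPolicy = DEFAULT_POLICY,
    *,
    distinct_pairs: bool = False,
    co_admin_slack: int = 0,
) -> tuple[list[PairFinding], CohortSummary]:
    """Classify every co-administered pair of every included chart.

    ``distinct_pairs=True`` switches the aggregates from occurrence counting
    to one count per distinct pair across the whole cohort.
    """
    findings: list[PairFinding] = []
    included_ids: list[str] = []
    for chart in sorted(charts, key=lambda c: c.patient_id):
        ok, _ = meets_inclusion(chart, co_admin_slack=co_admin_slack)
        if not ok:
            continue
        included_ids.append(chart.patient_id)
        for lumen in range(1, chart.catheter.n_lumens + 1):
            for pair in sorted(coadministered_pairs(chart, lumen, co_admin_slack=co_admin_slack)):
                verdict = resolve_pair(kb, *pair, policy)
                findings.append(PairFinding(chart.patient_id, lumen, pair, verdict))

    counted = findings
    if distinct_pairs:
        seen: set[tuple[str, str]] = set()
        counted = []
        for f in findings:
            if f.pair not in seen:
                seen.add(f.pair)
                counted.append(f)

    incompat = [f for f in counted if f.is_incompatible]
    not_eval = [
        f for f in counted if f.verdict.classification is Classification.NOT_EVALUABLE
    ]
    per_patient = {pid: 0 for pid in included_ids}
    for f in incompat:
        per_patient[f.patient_id] += 1
    summary = CohortSummary(
        n_admitted=len(charts),
        n_included=len(included_ids),
        n_patients_with_incompatibility=sum(1 for v in per_patient.values() if v > 0),
        per_patient_incompatible_counts=per_patient,
        n_incompatible_combinations=len(incompat),
        n_not_evaluable=len(not_eval),
    )
    return findings, summary


def _incompatible(findings: Iterable[PairFinding]) -> list[PairFinding]:
    return [f for f in findings if f.is_incompatible]


def drug_frequency_table(findings: Iterable[PairFinding]) -> pd.DataFrame:
    """Per-drug involvement in incompatible findings.

    Each incompatible finding increments both member drugs; the percent
    denominator is the total number of incompatible findings, so the count
    column sums to twice that total.  Rows sort by count descending, ties
    alphabetical.
    """
    incompat = _incompatible(findings)
    counts: dict[str, int] = {}
    for f in incompat:
        for drug in f.pair:
            counts[drug] = counts.get(drug, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(incompat)
    return pd.DataFrame(
        [(d, c, percent1(c, n)) for d, c in rows],
        columns=["drug", "count", "percent"],
    )


def cross_table(findings: Iterable[PairFinding]) -> pd.DataFrame:
    """Symmetric drug x drug matrix of incompatible-pair occurrence counts.

    Only definitely-incompatible findings enter; not-evaluable pairs are
    excluded.  The upper-triangle sum equals the number of incompatible
    findings and the diagonal is zero.
    """
    incompat = _incompatible(findings)
    drugs = sorted({d for f in incompat for d in f.pair})
    mat = pd.DataFrame(0, index=drugs, columns=drugs, dtype=int)
    for f in incompat:
        a, b = f.pair
        mat.loc[a, b] += 1
        mat.loc[b, a] += 1
    return mat


def patient_level_stats(
    findings: Iterable[PairFinding],
    included_patient_ids: Sequence[str],
    *,
    quantile_method: str = DEFAULT_QUANTILE_METHOD,
) -> dict:
    """Distribution of per-patient incompatible-finding counts.

    Zero-count included patients are part of the distribution.
    """
    counts = {pid: 0 for pid in included_patient_ids}
    for f in _incompatible(findings):
        counts[f.patient_id] = counts.get(f.patient_id, 0) + 1
    values = np.array([counts[pid] for pid in included_patient_ids], dtype=float)
    if values.size == 0:
        return {"n_with_incompatibility": 0, "median": None, "q25": None, "q75": None}
    q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75], method=quantile_method)
    return {
        "n_with_incompatibility": int((values > 0).sum()),
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
    }


def findings_frame(findings: Iterable[PairFinding]) -> pd.DataFrame:
    """Long-form findings table (one row per patient-lumen-pair)."""
    return pd.DataFrame(
        [
            {
                "patient_id": f.patient_id,
                "lumen": f.lumen_id,
                "drug_a": f.pair[0],
                "drug_b": f.pair[1],
                "classification": f.verdict.classification.value,
                "reason": f.verdict.reason.value,
            }
            for f in findings
        ],
        columns=["patient_id", "lumen", "drug_a", "drug_b", "classification", "reason"],
    )
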