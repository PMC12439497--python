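"""Descriptive tables and the two-drug signal comparison.

Covers the baseline-characteristics table (sex / age band / outcome /
country counts with half-up percentages), top-k event ranking, daily-dose
strata, yearly report counts, and the cross-drug comparison exports
(signal table, forest-plot data restricted to shared signals, Sankey edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .dispro import DisproResult
from .faers_io import OUTCOME_LEVELS, AEReport
from .mapping import DEFAULT_ROLES, DrugDictionary, report_drugs

__all__ = [
    "AGE_BANDS",
    "LCM_DOSE_BINS",
    "CNB_DOSE_LEVELS",
    "BaselineTable",
    "ComparisonRow",
    "DoseStrata",
    "percentage",
    "age_band",
    "baseline_characteristics",
    "top_events",
    "dose_strata_counts",
    "yearly_counts",
    "compare_signals",
    "comparison_frame",
    "forest_frame",
    "sankey_edges",
    "count_strong_signals",
]

AGE_BANDS = ("<18", "18-49", "50-79", ">=80", "Unknown")

#: interval dose bins, half-open on the left: (label, low_exclusive, high_inclusive)
LCM_DOSE_BINS: tuple[tuple[str, float | None, float | None], ...] = (
    ("<=100 mg", None, 100.0),
    ("100-200 mg", 100.0, 200.0),
    ("200-400 mg", 200.0, 400.0),
    (">400 mg", 400.0, None),
)

#: exact titration dose levels
CNB_DOSE_LEVELS: tuple[float, ...] = (12.5, 25.0, 50.0, 100.0, 150.0)


def percentage(count: int, total: int) -> float:
    """100·count/total, rounded half-up to one decimal (as printed tables round)."""
    if total <= 0:
        raise ValueError("percentage requires a positive denominator")
    exact = Decimal(count) * 100 / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def age_band(age_years: float | None) -> str:
    if age_years is None:
        return "Unknown"
    if age_years < 18:
        return "<18"
    if age_years < 50:
        return "18-49"
    if age_years < 80:
        return "50-79"
    return ">=80"


@dataclass
class BaselineTable:
    """Per-drug descriptive counts; percentages share the drug's report total."""

    drug: str
    n_reports: int
    sex: dict[str, int]
    age: dict[str, int]
    outcomes: dict[str, int]
    country: dict[str, int]

    def pct(self, count: int) -> float:
        return percentage(count, self.n_reports)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"drug": self.drug, "block": "total", "label": "Number of events",
                 "count": self.n_reports, "pct": 100.0}]
        for block, counts in (("sex", self.sex), ("age", self.age),
                              ("outcome", self.outcomes), ("country", self.country)):
            for label, count in counts.items():
                rows.append({"drug": self.drug, "block": block, "label": label,
                             "count": count, "pct": self.pct(count)})
        return pd.DataFrame(rows, columns=["drug", "block", "label", "count", "pct"])


def baseline_characteristics(reports: Sequence[AEReport], drug: str) -> BaselineTable:
    """Descriptive counts for an already drug-selected report list.

    Sex, age-band and country blocks partition the reports (missing values in
    the Unknown row).  Outcome counts tally reports carrying each outcome; a
    report with several outcomes appears in each, and reports without any
    outcome record appear in none, so that block need not sum to the total.
    """
    if not reports:
        raise ValueError("baseline_characteristics requires at least one report")
    sex = {"female": 0, "male": 0, "unknown": 0}
    age = {band: 0 for band in AGE_BANDS}
    outcomes = {level: 0 for level in OUTCOME_LEVELS}
    country: dict[str, int] = {}
    for r in reports:
        sex[r.sex] += 1
        age[age_band(r.age_years)] += 1
        for outcome in r.outcomes:
            outcomes[outcome] += 1
        country[r.country or "Unknown"] = country.get(r.country or "Unknown", 0) + 1
    country = dict(sorted(country.items(), key=lambda kv: (-kv[1], kv[0])))
    return BaselineTable(
        drug=drug, n_reports=len(reports), sex=sex, age=age, outcomes=outcomes, country=country
    )


def top_events(reports: Iterable[AEReport], k: int) -> list[tuple[str, int]]:
    """PTs ranked by report count, ties broken alphabetically, truncated to k."""
    counts: dict[str, int] = {}
    for r in reports:
        for pt in r.events:
            counts[pt] = counts.get(pt, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[: max(k, 0)]


@dataclass
class DoseStrata:
    drug: str
    counts: list[tuple[str, int]]
    unparseable: int = 0  # adult reports with the drug but no usable daily dose
    unbinned: int = 0  # parseable doses falling in no bin / no exact level

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"drug": self.drug, "bin": label, "count": n} for label, n in self.counts],
            columns=["drug", "bin", "count"],
        )


def _report_dose(report: AEReport, drug: str, dictionary: DrugDictionary,
                 roles: frozenset[str]) -> float | None:
    from .mapping import normalize_drug_name

    for entry in report.drugs:
        if entry.role not in roles:
            continue
        if normalize_drug_name(entry.raw_name, dictionary) == drug and entry.daily_dose_mg is not None:
            return entry.daily_dose_mg
    return None


def dose_strata_counts(
    reports: Iterable[AEReport],
    drug: str,
    dictionary: DrugDictionary,
    bins: Sequence[tuple[str, float | None, float | None]] | Sequence[float] = LCM_DOSE_BINS,
    roles: frozenset[str] = DEFAULT_ROLES,
) -> DoseStrata:
    """Adult (age ≥ 18) report counts per daily-dose stratum.

    ``bins`` is either interval bins (label, low, high], half-open on the
    left, or a sequence of exact dose levels.  Reports without a parseable
    dose are tallied separately, not dropped silently elsewhere.
    """
    exact = bins and not isinstance(bins[0], tuple)
    if exact:
        labels = [f"{level:g} mg" for level in bins]
        counts = {label: 0 for label in labels}
    else:
        counts = {label: 0 for label, _, _ in bins}
    strata = DoseStrata(drug=drug, counts=[])
    for r in reports:
        if r.age_years is None or r.age_years < 18:
            continue
        dose = _report_dose(r, drug, dictionary, roles)
        if dose is None:
            strata.unparseable += 1
            continue
        if exact:
            for level, label in zip(bins, labels):
                if dose == level:
                    counts[label] += 1
                    break
            else:
                strata.unbinned += 1
        else:
            for label, low, high in bins:
                if (low is None or dose > low) and (high is None or dose <= high):
                    counts[label] += 1
                    break
            else:
                strata.unbinned += 1
    strata.counts = list(counts.items())
    return strata


def yearly_counts(reports: Iterable[AEReport]) -> list[tuple[int, int]]:
    """Report counts per FDA-receipt year, ascending."""
    counts: dict[int, int] = {}
    for r in reports:
        year = r.fda_date // 10000
        counts[year] = counts.get(year, 0) + 1
    return sorted(counts.items())


@dataclass
class ComparisonRow:
    soc: str
    pt: str
    result_a: DisproResult | None = None
    result_b: DisproResult | None = None
    shared: bool = field(default=False)


def compare_signals(
    results_a: Iterable[DisproResult],
    results_b: Iterable[DisproResult],
) -> list[ComparisonRow]:
    """Union of PT-level signals of two drugs, with the shared flag set.

    Only results with is_signal contribute.  ``shared`` means the PT is a
    signal for both drugs.
    """

    def signal_map(results: Iterable[DisproResult]) -> dict[str, DisproResult]:
        return {r.event: r for r in results if r.is_signal and r.table.level == "PT"}

    map_a, map_b = signal_map(results_a), signal_map(results_b)
    rows: list[ComparisonRow] = []
    for pt in sorted(map_a.keys() | map_b.keys()):
        ra, rb = map_a.get(pt), map_b.get(pt)
        rows.append(ComparisonRow(soc="", pt=pt, result_a=ra, result_b=rb,
                                  shared=ra is not None and rb is not None))
    return rows


def _soc_for(row: ComparisonRow, vocab) -> str:
    return vocab.soc_of(row.pt) if vocab is not None else row.soc


def comparison_frame(rows: Iterable[ComparisonRow], vocab=None) -> pd.DataFrame:
    """Published-table-style CSV: one line per PT with both drugs' statistics."""
    out = []
    for row in rows:
        rec: dict = {"soc": _soc_for(row, vocab), "pt": row.pt, "shared": row.shared}
        for tag, res in (("a", row.result_a), ("b", row.result_b)):
            if res is None:
                rec.update({f"drug_{tag}": "", f"N_{tag}": "", f"PRR_{tag}": "", f"chi2_{tag}": "",
                            f"ROR_{tag}": "", f"ROR_CI025_{tag}": "", f"IC_{tag}": "", f"IC_2SD_{tag}": ""})
            else:
                rec.update({
                    f"drug_{tag}": res.drug, f"N_{tag}": res.table.a, f"PRR_{tag}": res.prr,
                    f"chi2_{tag}": res.chi2, f"ROR_{tag}": res.ror, f"ROR_CI025_{tag}": res.ror_ci_low,
                    f"IC_{tag}": res.e_ic, f"IC_2SD_{tag}": res.ic_minus_2sd,
                })
        out.append(rec)
    return pd.DataFrame(out)


def forest_frame(rows: Iterable[ComparisonRow], vocab=None) -> pd.DataFrame:
    """ROR forest-plot data, restricted to PTs signalled by both drugs."""
    out = []
    for row in rows:
        if not row.shared:
            continue
        for res in (row.result_a, row.result_b):
            out.append({
                "pt": row.pt, "soc": _soc_for(row, vocab), "drug": res.drug,
                "ror": res.ror, "ci_low": res.ror_ci_low, "ci_high": res.ror_ci_high,
            })
    return pd.DataFrame(out, columns=["pt", "soc", "drug", "ror", "ci_low", "ci_high"])


def sankey_edges(rows: Iterable[ComparisonRow], vocab=None) -> pd.DataFrame:
    """Edge list drug → PT → SOC weighted by the pair's report count a."""
    edges = []
    for row in rows:
        soc = _soc_for(row, vocab)
        for res in (row.result_a, row.result_b):
            if res is None:
                continue
            edges.append({"source": res.drug, "target": row.pt, "count": res.table.a})
            edges.append({"source": row.pt, "target": soc, "count": res.table.a})
    frame = pd.DataFrame(edges, columns=["source", "target", "count"])
    if frame.empty:
        return frame
    return frame.groupby(["source", "target"], as_index=False, sort=True)["count"].sum()


def count_strong_signals(rows: Iterable, drug: str, threshold: float = 1.0) -> int:
    """Count rows for ``drug`` whose IC−2SD is at least ``threshold``.

    Accepts fixture rows or computed results — anything carrying ``drug``
    and ``ic_minus_2sd`` attributes.
    """
    return sum(1 for r in rows if r.drug == drug and r.ic_minus_2sd >= threshold)
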