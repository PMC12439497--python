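"""Report-level 2×2 contingency tables for (drug, event) pairs.

A report contributes at most 1 to any cell, however many matching drug rows
or PT rows it carries.  The background (cells c and d) is every analysed
report not listing the target drug, within whatever report universe was
ingested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .faers_io import AEReport
from .mapping import DEFAULT_ROLES, DrugDictionary, VocabMap, report_drugs

__all__ = ["ContingencyTable", "build_table", "build_all_tables", "tables_to_frame"]

Level = Literal["PT", "SOC"]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for one (drug, event) pair: a=drug&event, b=drug only, c=event only, d=neither."""

    a: int
    b: int
    c: int
    d: int
    drug: str
    event: str
    level: Level = "PT"
    counting_unit: str = "report"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def drug_total(self) -> int:
        return self.a + self.b

    @property
    def event_total(self) -> int:
        return self.a + self.c


def _event_labels(report: AEReport, level: Level, vocab: VocabMap | None) -> set[str]:
    if level == "PT":
        return set(report.events)
    if vocab is None:
        raise ValueError("SOC-level counting requires a vocabulary")
    return {vocab.soc_of(pt) for pt in report.events}


def build_table(
    reports: Iterable[AEReport],
    drug: str,
    event: str,
    dictionary: DrugDictionary,
    level: Level = "PT",
    vocab: VocabMap | None = None,
    roles: frozenset[str] = DEFAULT_ROLES,
) -> ContingencyTable:
    """Build the 2×2 table for one (drug, event) pair over the full report universe."""
    a = b = c = d = 0
    total = 0
    for report in reports:
        total += 1
        has_drug = drug in report_drugs(report, dictionary, roles)
        has_event = event in _event_labels(report, level, vocab)
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    if total == 0:
        raise ValueError("cannot build a contingency table from zero reports")
    return ContingencyTable(a=a, b=b, c=c, d=d, drug=drug, event=event, level=level)


def build_all_tables(
    reports: Iterable[AEReport],
    drug: str,
    dictionary: DrugDictionary,
    vocab: VocabMap | None = None,
    roles: frozenset[str] = DEFAULT_ROLES,
) -> list[ContingencyTable]:
    """One table per PT observed with the drug, plus one per SOC when a vocab is given.

    Tables with a = 0 (the event never co-occurs with the drug) are omitted.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("cannot build contingency tables from zero reports")

    has_drug = [drug in report_drugs(r, dictionary, roles) for r in reports]
    n_total = len(reports)
    n_drug = sum(has_drug)

    levels: list[tuple[Level, VocabMap | None]] = [("PT", None)]
    if vocab is not None:
        levels.append(("SOC", vocab))

    tables: list[ContingencyTable] = []
    for level, vmap in levels:
        label_sets = [_event_labels(r, level, vmap) for r in reports]
        drug_events: set[str] = set()
        for flag, labels in zip(has_drug, label_sets):
            if flag:
                drug_events.update(labels)
        counts_a: dict[str, int] = {e: 0 for e in drug_events}
        counts_event: dict[str, int] = {e: 0 for e in drug_events}
        for flag, labels in zip(has_drug, label_sets):
            for e in labels & drug_events:
                counts_event[e] += 1
                if flag:
                    counts_a[e] += 1
        for event in sorted(drug_events):
            a = counts_a[event]
            if a == 0:
                continue
            c = counts_event[event] - a
            tables.append(
                ContingencyTable(
                    a=a,
                    b=n_drug - a,
                    c=c,
                    d=n_total - n_drug - c,
                    drug=drug,
                    event=event,
                    level=level,
                )
            )
    return tables


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    """Flatten tables to the CSV export layout: drug,event,level,a,b,c,d."""
    return pd.DataFrame(
        [
            {"drug": t.drug, "event": t.event, "level": t.level, "a": t.a, "b": t.b, "c": t.c, "d": t.d}
            for t in tables
        ],
        columns=["drug", "event", "level", "a", "b", "c", "d"],
    )
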