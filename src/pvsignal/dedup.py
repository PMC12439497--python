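"""Case-level deduplication of spontaneous reports.

For reports sharing a CASE_ID only the version with the highest FDA_DT
survives; ties on FDA_DT are broken by the largest PRIMARY_ID.  Both keys are
compared numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .faers_io import AEReport

__all__ = ["DedupResult", "deduplicate"]


@dataclass
class DedupResult:
    reports: list[AEReport]
    removed: int
    rejects: list[AEReport] = field(default_factory=list)


def deduplicate(reports: list[AEReport]) -> DedupResult:
    """Keep one report per case_id, maximising (fda_date, primary_id).

    Survivors keep their relative input order.  Reports missing any of the
    three keys are routed to ``rejects`` rather than silently kept.
    """
    best: dict[int, AEReport] = {}
    rejects: list[AEReport] = []
    order: list[int] = []  # case_ids in first-seen order
    considered = 0
    for report in reports:
        if report.case_id is None or report.fda_date is None or report.primary_id is None:
            rejects.append(report)
            continue
        considered += 1
        current = best.get(report.case_id)
        if current is None:
            best[report.case_id] = report
            order.append(report.case_id)
        elif (report.fda_date, report.primary_id) > (current.fda_date, current.primary_id):
            best[report.case_id] = report
    survivors = [best[cid] for cid in order]
    return DedupResult(reports=survivors, removed=considered - len(survivors), rejects=rejects)
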