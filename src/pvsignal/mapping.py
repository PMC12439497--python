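"""Drug-name normalization, report selection, indication exclusion and PT→SOC mapping."""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .faers_io import AEReport

__all__ = [
    "DrugDictionary",
    "VocabMap",
    "AmbiguousDrugNameError",
    "UNMAPPED_SOC",
    "DEFAULT_ROLES",
    "normalize_drug_name",
    "report_drugs",
    "select_reports",
    "exclude_indications",
    "apply_indication_exclusion",
    "map_pt_to_soc",
    "load_drug_dictionary",
    "load_vocab",
    "default_drug_dictionary",
    "default_vocab",
]

UNMAPPED_SOC = "unmapped"

#: suspect-drug roles admitted by default
DEFAULT_ROLES = frozenset({"PS", "SS"})

_TOKEN_RE = re.compile(r"[^\w.]+")


class AmbiguousDrugNameError(ValueError):
    """A verbatim name matched synonyms of more than one canonical drug."""


def _tokens(text: str) -> tuple[str, ...]:
    return tuple(t for t in _TOKEN_RE.split(text.casefold().strip()) if t)


@dataclass
class DrugDictionary:
    """Canonical drug → synonym strings (generic and brand names).

    Synonym sets must be disjoint across canonical drugs; synonyms are stored
    case-folded.
    """

    entries: dict[str, frozenset[str]]
    _synonym_tokens: dict[str, list[tuple[str, ...]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        folded = {
            canonical: frozenset(s.casefold().strip() for s in synonyms)
            for canonical, synonyms in self.entries.items()
        }
        seen: dict[str, str] = {}
        for canonical, synonyms in folded.items():
            for syn in synonyms:
                if syn in seen and seen[syn] != canonical:
                    raise AmbiguousDrugNameError(
                        f"synonym {syn!r} claimed by both {seen[syn]!r} and {canonical!r}"
                    )
                seen[syn] = canonical
        self.entries = folded
        self._synonym_tokens = {
            canonical: sorted((_tokens(s) for s in synonyms), key=len, reverse=True)
            for canonical, synonyms in folded.items()
        }

    @property
    def drugs(self) -> list[str]:
        return sorted(self.entries)


def normalize_drug_name(raw: str, dictionary: DrugDictionary) -> str | None:
    """Map a verbatim drug name to its canonical drug, or ``None``.

    Matching case-folds, trims and tokenizes on whitespace/punctuation; a
    synonym matches when its token sequence equals the leading tokens of the
    verbatim name, so trailing dose/form noise ("100MG TABLETS") is ignored.
    """
    raw_tokens = _tokens(raw)
    if not raw_tokens:
        return None
    matches = []
    for canonical, synonym_tokens in dictionary._synonym_tokens.items():
        if any(raw_tokens[: len(st)] == st for st in synonym_tokens if st):
            matches.append(canonical)
    if len(matches) > 1:
        raise AmbiguousDrugNameError(f"{raw!r} matches {sorted(matches)}")
    return matches[0] if matches else None


def report_drugs(
    report: AEReport,
    dictionary: DrugDictionary,
    roles: frozenset[str] | Iterable[str] = DEFAULT_ROLES,
) -> set[str]:
    """Canonical drugs present in the report under one of the admitted roles."""
    roles = frozenset(roles)
    found: set[str] = set()
    for entry in report.drugs:
        if entry.role not in roles:
            continue
        canonical = normalize_drug_name(entry.raw_name, dictionary)
        if canonical is not None:
            found.add(canonical)
    return found


def select_reports(
    reports: Iterable[AEReport],
    drug: str,
    dictionary: DrugDictionary,
    roles: frozenset[str] | Iterable[str] = DEFAULT_ROLES,
) -> list[AEReport]:
    """Reports listing ``drug`` in one of the admitted roles.

    Selections for different drugs are independent: a report listing both
    study drugs appears in both selections.
    """
    roles = frozenset(roles)
    return [r for r in reports if drug in report_drugs(r, dictionary, roles)]


def exclude_indications(report: AEReport) -> AEReport:
    """Remove the report's own indication PTs from its event set (case-folded exact match)."""
    if not report.indications:
        return report
    folded = {i.casefold() for i in report.indications}
    kept = frozenset(e for e in report.events if e.casefold() not in folded)
    if kept == report.events:
        return report
    return replace(report, events=kept)


def apply_indication_exclusion(reports: Iterable[AEReport]) -> tuple[list[AEReport], int]:
    """Indication-exclude every report; drop those left with no events.

    Returns the kept reports and the number dropped (they can contribute no
    drug-event pair).
    """
    kept: list[AEReport] = []
    dropped = 0
    for report in reports:
        cleaned = exclude_indications(report)
        if cleaned.events:
            kept.append(cleaned)
        else:
            dropped += 1
    return kept, dropped


@dataclass
class VocabMap:
    """Flat PT → SOC lookup; unknown PTs fall into the explicit unmapped bucket."""

    pt_to_soc: dict[str, str]
    _folded: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._folded = {pt.casefold(): soc for pt, soc in self.pt_to_soc.items()}

    def soc_of(self, pt: str) -> str:
        return self._folded.get(pt.casefold(), UNMAPPED_SOC)


def map_pt_to_soc(pt: str, vocab: VocabMap) -> str:
    return vocab.soc_of(pt)


def load_drug_dictionary(path: str | Path) -> DrugDictionary:
    """Load a dictionary from YAML (canonical → synonym list) or two-column TSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a mapping of canonical drug -> synonyms")
        return DrugDictionary({k: frozenset(v) for k, v in data.items()})
    entries: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'canonical<TAB>synonym'")
        entries.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return DrugDictionary({k: frozenset(v) for k, v in entries.items()})


def load_vocab(path: str | Path) -> VocabMap:
    """Load a two-column ``pt<TAB>soc`` vocabulary file (header optional)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'pt<TAB>soc'")
        pt, soc = parts[0].strip(), parts[1].strip()
        if lineno == 1 and pt.lower() == "pt" and soc.lower() == "soc":
            continue
        mapping[pt] = soc
    return VocabMap(mapping)


def default_drug_dictionary() -> DrugDictionary:
    return load_drug_dictionary(Path(resources.files("pvsignal.data") / "drug_dictionary.yaml"))


def default_vocab() -> VocabMap:
    return load_vocab(Path(resources.files("pvsignal.data") / "demo_pt_soc.tsv"))
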