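"""Reading and writing the quarterly ASCII dialect used by spontaneous-report archives.

Tables are plain text, one record per line, fields separated by ``$`` with a
header line naming the columns.  The dialect has no quoting, so a field can
never contain the delimiter.  Missing values travel as empty strings.
"""

from __future__ import annotations

import csv
import enum
import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TableKind",
    "RawTableRow",
    "DrugEntry",
    "AEReport",
    "AssemblyResult",
    "SignalFixtureRow",
    "FaersFormatError",
    "FixtureValidationError",
    "DELIMITER",
    "TABLE_SCHEMAS",
    "OUTCOME_CODES",
    "read_faers_table",
    "write_faers_table",
    "assemble_reports",
    "read_signal_fixture",
    "default_fixture_path",
]

DELIMITER = "$"


class FaersFormatError(ValueError):
    """Raised when a table file does not conform to the dialect."""


class FixtureValidationError(ValueError):
    """Raised when the bundled signal fixture violates its invariants."""


class TableKind(str, enum.Enum):
    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    OUTC = "OUTC"
    THER = "THER"
    INDI = "INDI"


# Minimal column sets; extra columns pass through untouched and column names
# are matched case-insensitively because archive schemas drift across quarters.
TABLE_SCHEMAS: dict[TableKind, tuple[str, ...]] = {
    TableKind.DEMO: ("primaryid", "caseid", "fda_dt", "sex", "age", "age_cod", "occr_country"),
    TableKind.DRUG: ("primaryid", "caseid", "drug_seq", "role_cod", "drugname", "dose_amt", "dose_unit"),
    TableKind.REAC: ("primaryid", "caseid", "pt"),
    TableKind.OUTC: ("primaryid", "caseid", "outc_cod"),
    TableKind.THER: ("primaryid", "caseid", "dsg_drug_seq", "start_dt"),
    TableKind.INDI: ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
}

#: outcome code -> harmonised outcome label
OUTCOME_CODES: dict[str, str] = {
    "DE": "death",
    "DS": "disability",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "OT": "other",
}

OUTCOME_LEVELS = ("death", "disability", "life_threatening", "hospitalization", "other", "unknown")

#: age-unit codes interpreted as years; everything else becomes missing.
YEAR_AGE_CODES = frozenset({"YR", ""})


@dataclass
class RawTableRow:
    """One record of one table, column values kept verbatim as strings."""

    table_kind: TableKind
    fields: "OrderedDict[str, str]"

    def get(self, column: str) -> str:
        return self.fields.get(column.lower(), "")


@dataclass(frozen=True)
class DrugEntry:
    raw_name: str
    role: str  # PS, SS, C, I
    daily_dose_mg: float | None = None


@dataclass
class AEReport:
    """A single safety report after table assembly."""

    primary_id: int
    case_id: int
    fda_date: int
    sex: str = "unknown"  # female / male / unknown
    age_years: float | None = None
    country: str | None = None
    outcomes: frozenset[str] = frozenset()
    drugs: tuple[DrugEntry, ...] = ()
    events: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()

    def with_events(self, events: Iterable[str]) -> "AEReport":
        return replace(self, events=frozenset(events))


@dataclass
class AssemblyResult:
    reports: list[AEReport]
    rejects: list[str] = field(default_factory=list)
    orphan_rows: int = 0


def _normalise_header(raw: Sequence[str], kind: TableKind, path: Path) -> list[str]:
    header = [h.strip().lower() for h in raw]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise FaersFormatError(f"{path}: duplicate column(s) {dupes} in {kind.value} header")
    missing = [c for c in ("primaryid",) if c not in header]
    if missing:
        raise FaersFormatError(f"{path}: {kind.value} header missing required column '{missing[0]}'")
    return header


def read_faers_table(path: str | Path, table_kind: TableKind | str) -> list[RawTableRow]:
    """Read one dollar-delimited table file into raw rows.

    Raises :class:`FaersFormatError` naming the offending column or line for a
    malformed header or a record with the wrong field count.
    """
    kind = TableKind(table_kind)
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FaersFormatError(f"{path}: empty file, expected a header line")
    header = _normalise_header(lines[0].split(DELIMITER), kind, path)
    rows: list[RawTableRow] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        values = line.split(DELIMITER)
        if len(values) != len(header):
            raise FaersFormatError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(values)}"
            )
        rows.append(RawTableRow(kind, OrderedDict(zip(header, values))))
    return rows


def write_faers_table(
    path: str | Path,
    table_kind: TableKind | str,
    rows: Iterable[RawTableRow | Mapping[str, str]],
    columns: Sequence[str] | None = None,
) -> Path:
    """Write rows in the same dialect ``read_faers_table`` accepts (round-trip safe)."""
    kind = TableKind(table_kind)
    path = Path(path)
    rows = list(rows)
    if columns is None:
        if rows:
            first = rows[0].fields if isinstance(rows[0], RawTableRow) else rows[0]
            columns = list(first.keys())
        else:
            columns = list(TABLE_SCHEMAS[kind])
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(DELIMITER.join(columns) + "\n")
        for row in rows:
            mapping = row.fields if isinstance(row, RawTableRow) else row
            values = [str(mapping.get(c, "")) for c in columns]
            for col, val in zip(columns, values):
                if DELIMITER in val:
                    raise FaersFormatError(f"{path}: value for '{col}' contains the delimiter")
            fh.write(DELIMITER.join(values) + "\n")
    return path


def _parse_sex(code: str) -> str:
    return {"F": "female", "M": "male"}.get(code.strip().upper(), "unknown")


def _parse_age(age: str, age_cod: str) -> float | None:
    if age_cod.strip().upper() not in YEAR_AGE_CODES:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    if not math.isfinite(value) or value < 0:
        return None
    return value


def _parse_dose_mg(amount: str, unit: str) -> float | None:
    if unit.strip().upper() not in {"MG", ""} or not amount.strip():
        return None
    try:
        value = float(amount)
    except ValueError:
        return None
    if not math.isfinite(value) or value < 0:
        return None
    return value


def _group_by_primaryid(rows: Iterable[RawTableRow]) -> dict[int, list[RawTableRow]]:
    grouped: dict[int, list[RawTableRow]] = {}
    orphokey = "primaryid"
    for row in rows:
        try:
            pid = int(row.get(orphokey))
        except ValueError:
            continue
        grouped.setdefault(pid, []).append(row)
    return grouped


def assemble_reports(tables: Mapping[TableKind | str, list[RawTableRow]]) -> AssemblyResult:
    """Join child tables onto DEMO rows by PRIMARYID, one report per DEMO row.

    Child rows whose PRIMARYID matches no DEMO row are counted in
    ``orphan_rows``; DEMO rows with non-numeric keys go to ``rejects``.
    """
    normalised = {TableKind(k): v for k, v in tables.items()}
    if TableKind.DEMO not in normalised:
        raise ValueError("assemble_reports requires a DEMO table")

    children = {
        kind: _group_by_primaryid(normalised.get(kind, []))
        for kind in (TableKind.DRUG, TableKind.REAC, TableKind.OUTC, TableKind.THER, TableKind.INDI)
    }

    result = AssemblyResult(reports=[])
    seen_pids: set[int] = set()
    for idx, demo in enumerate(normalised[TableKind.DEMO]):
        try:
            pid = int(demo.get("primaryid"))
            cid = int(demo.get("caseid"))
            fda = int(demo.get("fda_dt"))
        except ValueError:
            result.rejects.append(
                f"DEMO row {idx}: non-numeric primaryid/caseid/fda_dt "
                f"({demo.get('primaryid')!r}, {demo.get('caseid')!r}, {demo.get('fda_dt')!r})"
            )
            continue
        seen_pids.add(pid)

        drugs = tuple(
            DrugEntry(
                raw_name=r.get("drugname"),
                role=r.get("role_cod").strip().upper() or "PS",
                daily_dose_mg=_parse_dose_mg(r.get("dose_amt"), r.get("dose_unit")),
            )
            for r in children[TableKind.DRUG].get(pid, [])
        )
        events = frozenset(
            r.get("pt").strip() for r in children[TableKind.REAC].get(pid, []) if r.get("pt").strip()
        )
        outcomes = frozenset(
            OUTCOME_CODES.get(r.get("outc_cod").strip().upper(), "unknown")
            for r in children[TableKind.OUTC].get(pid, [])
        )
        indications = frozenset(
            r.get("indi_pt").strip()
            for r in children[TableKind.INDI].get(pid, [])
            if r.get("indi_pt").strip()
        )
        country = demo.get("occr_country").strip() or None
        result.reports.append(
            AEReport(
                primary_id=pid,
                case_id=cid,
                fda_date=fda,
                sex=_parse_sex(demo.get("sex")),
                age_years=_parse_age(demo.get("age"), demo.get("age_cod")),
                country=country,
                outcomes=outcomes,
                drugs=drugs,
                events=events,
                indications=indications,
            )
        )

    for kind, grouped in children.items():
        for pid, rows in grouped.items():
            if pid not in seen_pids:
                result.orphan_rows += len(rows)
    return result


@dataclass(frozen=True)
class SignalFixtureRow:
    """One (PT, drug) row of the bundled published-signal table."""

    soc: str
    pt: str
    drug: str
    n: int
    prr: float
    chi2: float
    ror: float
    ror_ci025: float
    ic: float
    ic_minus_2sd: float


def default_fixture_path() -> Path:
    return Path(resources.files("pvsignal.data") / "table5_signals.csv")


def read_signal_fixture(path: str | Path | None = None) -> list[SignalFixtureRow]:
    """Load the bundled signal-table fixture, enforcing its row invariants."""
    path = Path(path) if path is not None else default_fixture_path()
    rows: list[SignalFixtureRow] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, rec in enumerate(reader, start=2):
            if any(rec[k] in ("", "/") for k in ("n", "prr", "chi2", "ror", "ror_ci025", "ic", "ic_minus_2sd")):
                continue  # '/' cells in the source table: no statistics for that drug
            row = SignalFixtureRow(
                soc=rec["soc"],
                pt=rec["pt"],
                drug=rec["drug"],
                n=int(rec["n"]),
                prr=float(rec["prr"]),
                chi2=float(rec["chi2"]),
                ror=float(rec["ror"]),
                ror_ci025=float(rec["ror_ci025"]),
                ic=float(rec["ic"]),
                ic_minus_2sd=float(rec["ic_minus_2sd"]),
            )
            if row.n < 6:
                raise FixtureValidationError(f"{path}:{lineno}: n={row.n} < 6 for {row.pt}/{row.drug}")
            if not row.ror_ci025 < row.ror:
                raise FixtureValidationError(f"{path}:{lineno}: ror_ci025 >= ror for {row.pt}/{row.drug}")
            if not row.ic_minus_2sd < row.ic:
                raise FixtureValidationError(f"{path}:{lineno}: ic_minus_2sd >= ic for {row.pt}/{row.drug}")
            rows.append(row)
    return rows
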