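"""Synthetic spontaneous-report generator with planted reporting-rate ratios.

Produces data in the same dollar-delimited dialect the ingest layer reads, so
every pipeline stage is testable without downloading anything.  The planted
(drug, event) relative reporting rates are the ground truth for recovery and
null-calibration checks.

Events are drawn independently per report given the report's drug set; a
report's probability of an event is ``base_rate × max(rr over its drugs)``.
Duplicate case versions are emitted with a strictly lower FDA date than the
canonical version, so deduplication must recover exactly the canonical set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .faers_io import OUTCOME_CODES as _CODE_MAP
from .faers_io import AEReport, DrugEntry, TableKind, write_faers_table

__all__ = [
    "DrugSpec",
    "EventSpec",
    "SyntheticConfig",
    "TruthRecord",
    "SyntheticConfigError",
    "simulate_reports",
    "generate",
    "truth_signals",
    "default_config",
]

_BACKGROUND_DRUG = "backgrounddrug"

#: PT given to reports whose event draw comes up empty, so every report enters
#: the analysis with at least one event without perturbing configured rates
FILLER_PT = "Drug ineffective"


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DrugSpec:
    name: str
    marginal: float
    synonyms: tuple[str, ...] = ()
    dose_levels_mg: tuple[float, ...] = (100.0,)

    def render_names(self) -> tuple[str, ...]:
        return tuple(s.upper() for s in (self.synonyms or (self.name,)))


@dataclass(frozen=True)
class EventSpec:
    pt: str
    soc: str
    base_rate: float


@dataclass
class SyntheticConfig:
    n_reports: int
    drugs: tuple[DrugSpec, ...]
    events: tuple[EventSpec, ...]
    rr: dict[tuple[str, str], float] = field(default_factory=dict)
    duplicate_fraction: float = 0.0
    missingness: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.1, "age": 0.2, "country": 0.1, "dose": 0.3}
    )
    indication_pt: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise SyntheticConfigError("n_reports must be >= 1")
        if not (0.0 <= self.duplicate_fraction <= 1.0):
            raise SyntheticConfigError("duplicate_fraction must be in [0, 1]")
        for spec in self.drugs:
            if not (0.0 <= spec.marginal <= 1.0):
                raise SyntheticConfigError(f"drug marginal for {spec.name!r} outside [0, 1]")
        for rate in self.missingness.values():
            if not (0.0 <= rate <= 1.0):
                raise SyntheticConfigError("missingness rates must be in [0, 1]")
        for event in self.events:
            if not (0.0 <= event.base_rate <= 1.0):
                raise SyntheticConfigError(f"base rate for {event.pt!r} outside [0, 1]")
            for spec in self.drugs:
                rr = self.rr.get((spec.name, event.pt), 1.0)
                if rr < 0 or not np.isfinite(rr):
                    raise SyntheticConfigError(f"rr for ({spec.name}, {event.pt}) must be finite >= 0")
                if event.base_rate * rr > 1.0:
                    raise SyntheticConfigError(
                        f"base_rate*rr > 1 for pair ({spec.name}, {event.pt})"
                    )


@dataclass
class TruthRecord:
    rr: dict[tuple[str, str], float]
    n_reports: int
    seed: int
    report_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rr": {f"{d}|{e}": v for (d, e), v in self.rr.items()},
                "n_reports": self.n_reports,
                "seed": self.seed,
                "report_counts": self.report_counts,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        data = json.loads(text)
        rr = {tuple(k.split("|", 1)): v for k, v in data["rr"].items()}
        return cls(
            rr=rr,
            n_reports=data["n_reports"],
            seed=data["seed"],
            report_counts=data.get("report_counts", {}),
        )


def truth_signals(truth: TruthRecord, rr_threshold: float) -> set[tuple[str, str]]:
    """Planted pairs with rr at or above the threshold — the recovery reference set."""
    return {pair for pair, rr in truth.rr.items() if rr >= rr_threshold}


_COUNTRIES = ("US", "DE", "JP", "GB")
_COUNTRY_P = (0.6, 0.15, 0.15, 0.1)
_OUTCOME_CODES = ("HO", "DE", "LT", "OT", "")
_OUTCOME_P = (0.2, 0.05, 0.03, 0.32, 0.4)


def simulate_reports(config: SyntheticConfig) -> tuple[list[AEReport], TruthRecord]:
    """Draw the full report stream (canonical reports plus duplicate versions).

    Returns reports in emission order — duplicate versions precede their
    canonical report, which carries the highest FDA date of its case — and
    the truth record for recovery checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    k_drugs = len(config.drugs)
    m_events = len(config.events)

    drug_matrix = rng.random((n, k_drugs)) < np.array([d.marginal for d in config.drugs])

    # per-report event probability: base_rate times the max rr over the drugs present
    base = np.array([e.base_rate for e in config.events])
    rr_matrix = np.ones((k_drugs, m_events))
    for i, spec in enumerate(config.drugs):
        for j, event in enumerate(config.events):
            rr_matrix[i, j] = config.rr.get((spec.name, event.pt), 1.0)
    multiplier = np.ones((n, m_events))
    for i in range(k_drugs):
        rows = drug_matrix[:, i]
        if rows.any():
            multiplier[rows] = np.maximum(multiplier[rows], rr_matrix[i])
    event_p = np.clip(base * multiplier, 0.0, 1.0)
    event_matrix = rng.random((n, m_events)) < event_p

    # reports must enter the analysis with at least one event: empty draws get
    # the filler PT, which is independent of the drug set and distinct from
    # every configured event, so planted rates are not diluted
    filler = ~event_matrix.any(axis=1)

    sex_draw = rng.random(n)
    age_draw = rng.uniform(1.0, 90.0, size=n)
    country_draw = rng.choice(len(_COUNTRIES), size=n, p=_COUNTRY_P)
    outcome_draw = rng.choice(len(_OUTCOME_CODES), size=n, p=_OUTCOME_P)
    miss = {
        key: rng.random(n) < config.missingness.get(key, 0.0)
        for key in ("sex", "age", "country", "dose")
    }
    name_choice = rng.integers(0, 1_000_000, size=(n, k_drugs))
    dose_choice = rng.integers(0, 1_000_000, size=(n, k_drugs))

    dup_flags = rng.random(n) < config.duplicate_fraction

    reports: list[AEReport] = []
    report_counts: dict[str, int] = {spec.name: 0 for spec in config.drugs}
    for idx in range(n):
        case_id = 9_000_000 + idx
        primary_id = 100_000_000 + idx * 10
        year = 2015 + idx % 9
        fda_date = year * 10000 + (1 + idx % 12) * 100 + (1 + idx % 28)

        drugs: list[DrugEntry] = []
        for i, spec in enumerate(config.drugs):
            if not drug_matrix[idx, i]:
                continue
            names = spec.render_names()
            name = names[name_choice[idx, i] % len(names)]
            dose = spec.dose_levels_mg[dose_choice[idx, i] % len(spec.dose_levels_mg)]
            drugs.append(
                DrugEntry(
                    raw_name=name,
                    role="PS",
                    daily_dose_mg=None if miss["dose"][idx] else dose,
                )
            )
            report_counts[spec.name] += 1
        drugs.append(DrugEntry(raw_name=_BACKGROUND_DRUG.upper(), role="PS", daily_dose_mg=None))

        events = frozenset(
            config.events[j].pt for j in range(m_events) if event_matrix[idx, j]
        )
        if filler[idx]:
            events = frozenset({FILLER_PT})
        indications = (
            frozenset({config.indication_pt})
            if config.indication_pt and len(drugs) > 1
            else frozenset()
        )
        outcome_code = _OUTCOME_CODES[outcome_draw[idx]]
        report = AEReport(
            primary_id=primary_id,
            case_id=case_id,
            fda_date=fda_date,
            sex="unknown" if miss["sex"][idx] else ("female" if sex_draw[idx] < 0.5 else "male"),
            age_years=None if miss["age"][idx] else float(np.round(age_draw[idx], 1)),
            country=None if miss["country"][idx] else _COUNTRIES[country_draw[idx]],
            outcomes=frozenset({_CODE_MAP[outcome_code]}) if outcome_code else frozenset(),
            drugs=tuple(drugs),
            events=events,
            indications=indications,
        )
        if dup_flags[idx]:
            # stale version: strictly earlier FDA date and a smaller primary id
            reports.append(
                AEReport(
                    primary_id=primary_id - 1,
                    case_id=case_id,
                    fda_date=(year - 1) * 10000 + fda_date % 10000,
                    sex=report.sex,
                    age_years=report.age_years,
                    country=report.country,
                    outcomes=report.outcomes,
                    drugs=report.drugs,
                    events=report.events,
                    indications=report.indications,
                )
            )
        reports.append(report)

    truth = TruthRecord(
        rr=dict(config.rr),
        n_reports=n,
        seed=config.seed,
        report_counts=report_counts,
    )
    return reports, truth


def _report_rows(reports: Iterable[AEReport]) -> dict[TableKind, list[dict[str, str]]]:
    rows: dict[TableKind, list[dict[str, str]]] = {kind: [] for kind in TableKind}
    for r in reports:
        pid, cid = str(r.primary_id), str(r.case_id)
        rows[TableKind.DEMO].append(
            {
                "primaryid": pid,
                "caseid": cid,
                "fda_dt": str(r.fda_date),
                "sex": {"female": "F", "male": "M"}.get(r.sex, ""),
                "age": "" if r.age_years is None else f"{r.age_years:g}",
                "age_cod": "" if r.age_years is None else "YR",
                "occr_country": r.country or "",
            }
        )
        for seq, entry in enumerate(r.drugs, start=1):
            rows[TableKind.DRUG].append(
                {
                    "primaryid": pid,
                    "caseid": cid,
                    "drug_seq": str(seq),
                    "role_cod": entry.role,
                    "drugname": entry.raw_name,
                    "dose_amt": "" if entry.daily_dose_mg is None else f"{entry.daily_dose_mg:g}",
                    "dose_unit": "" if entry.daily_dose_mg is None else "MG",
                }
            )
        for pt in sorted(r.events):
            rows[TableKind.REAC].append({"primaryid": pid, "caseid": cid, "pt": pt})
        code_map = {"death": "DE", "disability": "DS", "life_threatening": "LT",
                    "hospitalization": "HO", "other": "OT"}
        for outcome in sorted(r.outcomes):
            rows[TableKind.OUTC].append(
                {"primaryid": pid, "caseid": cid, "outc_cod": code_map.get(outcome, "")}
            )
        rows[TableKind.THER].append(
            {"primaryid": pid, "caseid": cid, "dsg_drug_seq": "1", "start_dt": str(r.fda_date)}
        )
        for seq, indi in enumerate(sorted(r.indications), start=1):
            rows[TableKind.INDI].append(
                {"primaryid": pid, "caseid": cid, "indi_drug_seq": str(seq), "indi_pt": indi}
            )
    return rows


def generate(config: SyntheticConfig, outdir: str | Path) -> tuple[dict[TableKind, Path], TruthRecord]:
    """Write the synthetic quarter to ``outdir`` plus a ``truth.json`` record.

    Byte-identical for identical (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports, truth = simulate_reports(config)
    rows = _report_rows(reports)
    paths: dict[TableKind, Path] = {}
    for kind in TableKind:
        from .faers_io import TABLE_SCHEMAS

        paths[kind] = write_faers_table(
            outdir / f"{kind.value}.txt", kind, rows[kind], columns=TABLE_SCHEMAS[kind]
        )
    (outdir / "truth.json").write_text(truth.to_json(), encoding="utf-8")
    return paths, truth


def default_config(
    n_reports: int = 5000,
    seed: int = 0,
    rr: Mapping[tuple[str, str], float] | None = None,
    duplicate_fraction: float = 0.1,
) -> SyntheticConfig:
    """A small two-study-drug configuration mirroring the bundled dictionary."""
    drugs = (
        DrugSpec("cenobamate", 0.05, ("cenobamate", "xcopri", "motpoly xr"),
                 dose_levels_mg=(12.5, 25.0, 50.0, 100.0, 150.0)),
        DrugSpec("lacosamide", 0.08, ("lacosamide", "vimpat"),
                 dose_levels_mg=(50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 600.0)),
    )
    events = (
        EventSpec("Somnolence", "Nervous system disorders", 0.02),
        EventSpec("Dizziness", "Nervous system disorders", 0.03),
        EventSpec("Fall", "Injury, poisoning and procedural complications", 0.02),
        EventSpec("Fatigue", "General disorders and administration site conditions", 0.03),
        EventSpec("Diplopia", "Eye disorders", 0.01),
        EventSpec("Bradycardia", "Cardiac disorders", 0.01),
        EventSpec("Irritability", "Psychiatric disorders", 0.015),
        EventSpec("Insomnia", "Psychiatric disorders", 0.02),
    )
    return SyntheticConfig(
        n_reports=n_reports,
        drugs=drugs,
        events=events,
        rr=dict(rr or {}),
        duplicate_fraction=duplicate_fraction,
        indication_pt="Epilepsy",
        seed=seed,
    )
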