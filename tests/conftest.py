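from __future__ import annotations

import pytest

from pvsignal.faers_io import AEReport, DrugEntry
from pvsignal.mapping import default_drug_dictionary, default_vocab


@pytest.fixture(scope="session")
def ddict():
    return default_drug_dictionary()


@pytest.fixture(scope="session")
def vocab():
    return default_vocab()


def make_report(
    primary_id=100001,
    case_id=9001,
    fda_date=20230101,
    drugs=(),
    events=(),
    indications=(),
    sex="unknown",
    age_years=None,
    country=None,
    outcomes=(),
):
    """Terse report factory: drugs may be raw-name strings or DrugEntry objects."""
    entries = tuple(
        d if isinstance(d, DrugEntry) else DrugEntry(raw_name=d, role="PS") for d in drugs
    )
    return AEReport(
        primary_id=primary_id,
        case_id=case_id,
        fda_date=fda_date,
        sex=sex,
        age_years=age_years,
        country=country,
        outcomes=frozenset(outcomes),
        drugs=entries,
        events=frozenset(events),
        indications=frozenset(indications),
    )
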