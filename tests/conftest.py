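import pytest

from ivcompat.charts import (
    AdminMode,
    AdministrationEvent,
    CatheterConfig,
    PatientChart,
    Route,
)
from ivcompat.analysis import PairFinding
from ivcompat.kb import SourceVerdict, pair_key
from ivcompat.resolution import Classification, Reason, TrailEntry, Verdict
from ivcompat.synthetic import fixture_kb, fixture_lexicon


@pytest.fixture(scope="session")
def kb():
    return fixture_kb()


@pytest.fixture(scope="session")
def lexicon():
    return fixture_lexicon()


def mk_verdict(classification: Classification) -> Verdict:
    """Minimal well-formed verdict for constructing findings in tests."""
    if classification is Classification.NOT_EVALUABLE:
        reason, sv = Reason.NO_DATA, SourceVerdict.NO_DATA
    else:
        reason = Reason.SINGLE_SOURCE
        sv = SourceVerdict(classification.value)
    return Verdict(classification, reason, (TrailEntry("KIK", sv, True),))


def mk_finding(pid: str, lumen: int, a: str, b: str,
               classification=Classification.INCOMPATIBLE) -> PairFinding:
    return PairFinding(pid, lumen, pair_key(a, b), mk_verdict(classification))


def mk_event(drug: str, start: int, end: int, lumen: int = 1,
             mode: AdminMode = AdminMode.INTERMITTENT, pid: str = "P001",
             route: Route = Route.CENTRAL_VENOUS) -> AdministrationEvent:
    return AdministrationEvent(pid, drug, route, lumen, start, end, mode)


def mk_chart(events, n_lumens: int = 3, pid: str = "P001", reserved=None,
             fluid_restricted: bool = False) -> PatientChart:
    return PatientChart(
        pid, CatheterConfig(n_lumens=n_lumens, reserved=reserved or {}),
        list(events), fluid_restricted,
    )
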