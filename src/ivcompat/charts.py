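"""Patient medication-administration records and lumen-resolved timing.

One chart covers one treatment day.  Events carry half-open integer-minute
intervals ``[start, end)``; two events are *simultaneous* iff their intervals
intersect with positive duration, so infusions that merely touch at an
endpoint do not overlap.  Only central-venous events enter the incompatibility
analysis — each catheter lumen is an independent fluid channel, so pairs never
span lumens.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .kb import Lexicon, UnknownDrugError, normalize_drug_name, pair_key

log = logging.getLogger(__name__)

#: one chart = one day; multi-day inputs must be pre-split
DEFAULT_MAX_HORIZON_MIN = 1600
#: events in BOLUS mode may not exceed this duration
DEFAULT_BOLUS_CAP_MIN = 15


class Route(str, Enum):
    CENTRAL_VENOUS = "CENTRAL_VENOUS"
    PERIPHERAL = "PERIPHERAL"
    OTHER = "OTHER"


class AdminMode(str, Enum):
    CONTINUOUS = "CONTINUOUS"
    INTERMITTENT = "INTERMITTENT"
    BOLUS = "BOLUS"


class ChartValidationError(ValueError):
    """Raised with a per-row error report when a chart file fails validation."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass(frozen=True)
class AdministrationEvent:
    patient_id: str
    drug: str
    route: Route
    lumen_id: int
    start: int
    end: int
    mode: AdminMode

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) for {self.drug}"
            )
        if self.lumen_id < 1:
            raise ValueError(f"lumen_id must be >= 1, got {self.lumen_id}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class CatheterConfig:
    """Number of lumens plus optional reserved-purpose tags per lumen."""

    n_lumens: int = 3
    reserved: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_lumens < 1:
            raise ValueError("catheter needs at least one lumen")
        object.__setattr__(self, "reserved", dict(self.reserved))
        if any(l > self.n_lumens or l < 1 for l in self.reserved):
            raise ValueError(f"reserved lumen outside 1..{self.n_lumens}")
        purposes = list(self.reserved.values())
        if len(set(purposes)) != len(purposes):
            raise ValueError("reserved purposes must be unique")


@dataclass
class PatientChart:
    patient_id: str
    catheter: CatheterConfig
    events: list[AdministrationEvent] = field(default_factory=list)
    fluid_restricted: bool = False  # disables flush-adding avoidance plans

    def __post_init__(self):
        for ev in self.events:
            if ev.route is Route.CENTRAL_VENOUS and ev.lumen_id > self.catheter.n_lumens:
                raise ValueError(
                    f"patient {self.patient_id}: event on lumen {ev.lumen_id} but "
                    f"catheter has {self.catheter.n_lumens} lumens"
                )

    def central_events(self, lumen_id: int | None = None) -> list[AdministrationEvent]:
        evs = [e for e in self.events if e.route is Route.CENTRAL_VENOUS]
        if lumen_id is not None:
            evs = [e for e in evs if e.lumen_id == lumen_id]
        return evs

    def central_drugs(self) -> set[str]:
        return {e.drug for e in self.central_events()}


CHART_CSV_HEADER = ["patient_id", "drug", "route", "lumen", "start_min", "end_min", "mode"]


def _parse_enum(cls, token: str, what: str):
    try:
        return cls(token.strip().upper())
    except ValueError:
        raise ValueError(f"unknown {what} token {token!r}") from None


def read_catheters(path: str | Path) -> dict[str, CatheterConfig]:
    """Read the catheter sidecar YAML: patient_id -> {n_lumens, reserved}."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    out = {}
    for pid, cfg in doc.items():
        cfg = cfg or {}
        out[str(pid)] = CatheterConfig(
            n_lumens=int(cfg.get("n_lumens", 3)),
            reserved={int(k): str(v) for k, v in (cfg.get("reserved") or {}).items()},
        )
    return out


def write_catheters(catheters: Mapping[str, CatheterConfig], path: str | Path) -> None:
    doc = {
        pid: {"n_lumens": c.n_lumens, "reserved": {int(k): v for k, v in sorted(c.reserved.items())}}
        for pid, c in sorted(catheters.items())
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


def write_charts(charts: Iterable[PatientChart], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CHART_CSV_HEADER)
        for chart in charts:
            for e in chart.events:
                w.writerow(
                    [e.patient_id, e.drug, e.route.value, e.lumen_id, e.start, e.end, e.mode.value]
                )


def read_charts(
    path: str | Path,
    lexicon: Lexicon,
    catheters: Mapping[str, CatheterConfig] | str | Path,
    *,
    skip_bad_rows: bool = False,
    max_horizon: int = DEFAULT_MAX_HORIZON_MIN,
    bolus_cap: int = DEFAULT_BOLUS_CAP_MIN,
) -> list[PatientChart]:
    """Parse the long-format chart CSV into per-patient charts.

    Rows are validated (interval, mode, lumen range, drug name); by default
    any invalid row aborts the load with a report naming each offending row,
    ``skip_bad_rows=True`` downgrades to logged warnings.  Peripheral and
    other-route events are kept on the chart but are excluded from the
    central-venous analysis downstream.
    """
    if not isinstance(catheters, Mapping):
        catheters = read_catheters(catheters)
    events: dict[str, list[AdministrationEvent]] = {}
    errors: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                pid = row["patient_id"].strip()
                route = _parse_enum(Route, row["route"], "route")
                mode = _parse_enum(AdminMode, row["mode"], "mode")
                start, end = int(row["start_min"]), int(row["end_min"])
                if end <= start:
                    raise ValueError(f"empty interval [{start}, {end})")
                if end > max_horizon:
                    raise ValueError(
                        f"event ends at {end} min, beyond the one-day horizon "
                        f"({max_horizon} min); split multi-day charts first"
                    )
                if mode is AdminMode.BOLUS and end - start > bolus_cap:
                    raise ValueError(f"bolus longer than {bolus_cap} min")
                lumen = int(row["lumen"])
                cath = catheters.get(pid, CatheterConfig())
                if route is Route.CENTRAL_VENOUS and not 1 <= lumen <= cath.n_lumens:
                    raise ValueError(f"lumen {lumen} out of range 1..{cath.n_lumens}")
                drug = normalize_drug_name(row["drug"], lexicon)
                events.setdefault(pid, []).append(
                    AdministrationEvent(pid, drug, route, lumen, start, end, mode)
                )
            except (ValueError, UnknownDrugError, KeyError) as exc:
                msg = f"{path} row {i}: {exc}"
                if skip_bad_rows:
                    log.warning("skipping bad row: %s", msg)
                else:
                    errors.append(msg)
    if errors:
        raise ChartValidationError(errors)
    charts = []
    for pid in sorted(events):
        cath = catheters.get(pid, CatheterConfig())
        chart = PatientChart(pid, cath, events[pid])
        n_periph = sum(1 for e in chart.events if e.route is not Route.CENTRAL_VENOUS)
        if n_periph:
            log.info("patient %s: %d non-central events parsed but excluded from analysis",
                     pid, n_periph)
        charts.append(chart)
    return charts


# ---------------------------------------------------------------------------
# Sweep-line co-administration
# ---------------------------------------------------------------------------

def _padded(ev: AdministrationEvent, slack: int) -> tuple[int, int]:
    # slack pads the end of each interval (residual line content after stop)
    return (ev.start, ev.end + slack)


def simultaneous_sets(
    chart: PatientChart, lumen_id: int, *, co_admin_slack: int = 0
) -> list[tuple[tuple[int, int], frozenset[str]]]:
    """Maximal constant-active-set windows on one lumen (sweep line).

    Returns ``[((start, end), drugs), ...]`` sorted by start; the windows are
    disjoint and cover exactly the union of the (slack-padded) event
    intervals.  Half-open semantics: touching endpoints do not overlap.
    """
    evs = chart.central_events(lumen_id)
    if not evs:
        return []
    intervals = [(_padded(e, co_admin_slack), e.drug) for e in evs]
    points = sorted({p for (s, e), _ in intervals for p in (s, e)})
    out = []
    for lo, hi in zip(points, points[1:]):
        active = frozenset(d for (s, e), d in intervals if s < hi and lo < e)
        if active:
            out.append(((lo, hi), active))
    # merge adjacent windows with identical active sets
    merged: list[tuple[tuple[int, int], frozenset[str]]] = []
    for (lo, hi), active in out:
        if merged and merged[-1][1] == active and merged[-1][0][1] == lo:
            merged[-1] = ((merged[-1][0][0], hi), active)
        else:
            merged.append(((lo, hi), active))
    return merged


def coadministered_pairs(
    chart: PatientChart, lumen_id: int, *, co_admin_slack: int = 0
) -> set[tuple[str, str]]:
    """Unordered pairs of distinct drugs simultaneously running on a lumen."""
    pairs: set[tuple[str, str]] = set()
    for _, drugs in simultaneous_sets(chart, lumen_id, co_admin_slack=co_admin_slack):
        ds = sorted(drugs)
        for i, a in enumerate(ds):
            for b in ds[i + 1:]:
                pairs.add(pair_key(a, b))
    return pairs


def meets_inclusion(
    chart: PatientChart, *, min_concurrent: int = 3, co_admin_slack: int = 0
) -> tuple[bool, tuple[int, tuple[int, int]] | None]:
    """Inclusion rule: some lumen carries >= 3 distinct drugs simultaneously.

    Returns ``(flag, witness)`` where the witness is the first (lumen, window)
    reaching the threshold, scanning lumens in ascending order.
    """
    for lumen in range(1, chart.catheter.n_lumens + 1):
        for window, drugs in simultaneous_sets(chart, lumen, co_admin_slack=co_admin_slack):
            if len(drugs) >= min_concurrent:
                return True, (lumen, window)
    return False, None
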