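"""Four-step avoidance engine for identified incompatibilities.

For every incompatible same-lumen co-administration the engine escalates
through four strategies, always choosing the lowest feasible step:

1. *Administer sequentially* — shift one short infusion after the other
   (both members non-continuous), separated by a flush gap.
2. *Use another lumen* — reassign drugs to lumens so that no incompatible
   pair overlaps on a shared lumen; a constrained graph-coloring problem
   (pinned reserved-purpose drugs keep their lumens, reserved lumens accept
   only their purpose's drugs).
3. *Take a break* — interrupt a pausable continuous infusion, flush, run the
   short infusion, flush, resume.
4. *Use catheters with more lumens* — escalate the lumen budget to the
   minimal count at which a conflict-free assignment exists.

The engine is deterministic (lexicographic tie-breaking) and transformational:
every recommendation carries a ``plan_delta`` which, applied to the chart,
removes its target pairs from simultaneous same-lumen co-administration
without creating new incompatible overlaps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import networkx as nx

from .analysis import PairFinding
from .charts import AdminMode, AdministrationEvent, CatheterConfig, PatientChart, \
    coadministered_pairs
from .kb import KnowledgeBase, pair_key
from .resolution import DEFAULT_POLICY, ResolutionPolicy, resolve_pair

STEP_NAMES = {
    1: "Administer sequentially",
    2: "Use another lumen",
    3: "Take a break",
    4: "Use catheters with more lumens",
}

#: exact backtracking is used up to this many graph nodes, greedy beyond
BACKTRACK_NODE_LIMIT = 12


@dataclass(frozen=True)
class RecommenderConfig:
    flush_gap: int = 5  # minutes of flush between incompatible drugs
    non_pausable_tags: frozenset[str] = frozenset({"catecholamine"})
    max_shift_search: int = 1600  # upper bound of the sequential-shift search
    horizon: int = 1600


@dataclass(frozen=True)
class Recommendation:
    patient_id: str
    pairs: frozenset[tuple[str, str]]
    step: int
    rationale: str
    plan_delta: dict

    def __post_init__(self):
        if self.step not in STEP_NAMES:
            raise ValueError(f"step must be 1..4, got {self.step}")

    @property
    def step_name(self) -> str:
        return STEP_NAMES[self.step]


IncompatPredicate = Callable[[str, str], bool]


def incompatibility_predicate(
    kb: KnowledgeBase, policy: ResolutionPolicy = DEFAULT_POLICY
) -> IncompatPredicate:
    """Resolver-backed predicate: is this pair definitely incompatible?"""

    cache: dict[tuple[str, str], bool] = {}

    def pred(a: str, b: str) -> bool:
        key = pair_key(a, b)
        if key not in cache:
            cache[key] = resolve_pair(kb, *key, policy).is_incompatible
        return cache[key]

    return pred


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _drug_intervals(chart: PatientChart, drug: str, lumen: int | None = None) -> list[tuple[int, int]]:
    return [e.interval for e in chart.central_events(lumen) if e.drug == drug]


def _drugs_overlap(chart: PatientChart, a: str, b: str) -> bool:
    return any(
        _overlap(ia, ib)
        for ia in _drug_intervals(chart, a)
        for ib in _drug_intervals(chart, b)
    )


def _is_continuous(chart: PatientChart, drug: str) -> bool:
    return any(
        e.mode is AdminMode.CONTINUOUS for e in chart.central_events() if e.drug == drug
    )


def current_conflicts(
    chart: PatientChart, is_incompatible: IncompatPredicate
) -> list[tuple[int, tuple[str, str]]]:
    """All (lumen, pair) with a definitely-incompatible simultaneous overlap."""
    out = []
    for lumen in range(1, chart.catheter.n_lumens + 1):
        for pair in sorted(coadministered_pairs(chart, lumen)):
            if is_incompatible(*pair):
                out.append((lumen, pair))
    return out


def build_graph(
    chart: PatientChart,
    findings: Iterable[PairFinding],
    *,
    kb: KnowledgeBase | None = None,
    policy: ResolutionPolicy = DEFAULT_POLICY,
    config: RecommenderConfig = RecommenderConfig(),
) -> nx.Graph:
    """Incompatibility graph of one patient's central-venous drugs.

    Nodes are drugs with mode/pausable/pinned attributes; edges are the
    incompatible same-lumen co-scheduled pairs from ``findings``.  When a
    knowledge base is supplied the graph additionally records, under
    ``graph.graph["conflicts"]``, every time-overlapping incompatible pair
    regardless of lumen — the constraint set for relocation.
    """
    g = nx.Graph()
    reserved_by_purpose = {p: l for l, p in chart.catheter.reserved.items()}
    for drug in sorted(chart.central_drugs()):
        tags = frozenset()
        if kb is not None and drug in kb.lexicon:
            tags = kb.lexicon.concepts[drug].class_tags
        pinned = None
        for tag in sorted(tags):
            if tag in reserved_by_purpose:
                pinned = reserved_by_purpose[tag]
                break
        g.add_node(
            drug,
            continuous=_is_continuous(chart, drug),
            pausable=not (tags & config.non_pausable_tags),
            pinned=pinned,
            class_tags=tags,
        )
    for f in findings:
        if f.patient_id == chart.patient_id and f.is_incompatible:
            g.add_edge(*f.pair, lumen=f.lumen_id)

    conflicts: set[tuple[str, str]] = set()
    if kb is not None:
        pred = incompatibility_predicate(kb, policy)
        drugs = sorted(g.nodes)
        for a, b in itertools.combinations(drugs, 2):
            if pred(a, b) and _drugs_overlap(chart, a, b):
                conflicts.add(pair_key(a, b))
    else:
        conflicts = {pair_key(a, b) for a, b in g.edges}
    g.graph["conflicts"] = conflicts
    return g


# ---------------------------------------------------------------------------
# Step 1: administer sequentially
# ---------------------------------------------------------------------------

def try_sequential(
    pair: tuple[str, str],
    chart: PatientChart,
    lumen: int,
    is_incompatible: IncompatPredicate,
    config: RecommenderConfig = RecommenderConfig(),
) -> tuple[bool, dict | None]:
    """Shift one member's infusions after the other's, plus a flush gap.

    Feasible only when neither member runs continuously (a continuous
    infusion cannot be sequenced) and the chart allows added flush volume.
    The mover is the member whose first event on the lumen starts later
    (ties: lexicographically later name); the shift is the minimal integer
    number of minutes that separates the pair by at least the flush gap
    without creating a new incompatible overlap on that lumen and without
    running past the horizon.
    """
    a, b = pair_key(*pair)
    if chart.fluid_restricted:
        return False, None
    if _is_continuous(chart, a) or _is_continuous(chart, b):
        return False, None
    ev_a = [e for e in chart.central_events(lumen) if e.drug == a]
    ev_b = [e for e in chart.central_events(lumen) if e.drug == b]
    if not ev_a or not ev_b:
        return False, None
    start_a = min(e.start for e in ev_a)
    start_b = min(e.start for e in ev_b)
    mover, anchor_evs, mover_evs = (
        (b, ev_a, ev_b) if (start_b, b) >= (start_a, a) else (a, ev_b, ev_a)
    )
    anchor = b if mover == a else a

    others = [
        e for e in chart.central_events(lumen) if e.drug not in (a, b)
    ]
    incompat_other_evs = [e for e in others if is_incompatible(mover, e.drug)]

    def ok(shift: int) -> bool:
        for m in mover_evs:
            s, e = m.start + shift, m.end + shift
            if e > config.horizon:
                return False
            for o in anchor_evs:  # flush-gap separation from the anchor drug
                if s < o.end + config.flush_gap and o.start < e + config.flush_gap:
                    return False
            for o in incompat_other_evs:  # no new incompatible overlap
                if _overlap((s, e), o.interval):
                    return False
        return True

    for shift in range(1, config.max_shift_search + 1):
        if ok(shift):
            return True, {
                "action": "shift",
                "drug": mover,
                "anchor": anchor,
                "lumen": lumen,
                "shift_min": shift,
                "events": [
                    [m.start, m.end, m.start + shift, m.end + shift] for m in mover_evs
                ],
            }
    return False, None


# ---------------------------------------------------------------------------
# Step 2: use another lumen (constrained graph coloring)
# ---------------------------------------------------------------------------

def _allowed_lumens(g: nx.Graph, drug: str, catheter: CatheterConfig) -> list[int]:
    pinned = g.nodes[drug].get("pinned")
    if pinned is not None:
        return [pinned] if pinned <= catheter.n_lumens else []
    tags = g.nodes[drug].get("class_tags", frozenset())
    allowed = []
    for lumen in range(1, catheter.n_lumens + 1):
        purpose = catheter.reserved.get(lumen)
        if purpose is None or purpose in tags:
            allowed.append(lumen)
    return allowed


def try_relocate(
    graph: nx.Graph, catheter: CatheterConfig
) -> tuple[bool, dict[str, int] | None]:
    """Seek a drug -> lumen assignment with no incompatible overlapping pair
    sharing a lumen.

    Uses greedy largest-degree-first coloring with an exact backtracking
    fallback for small graphs; deterministic (lexicographic tie-breaks).
    """
    conflicts: set[tuple[str, str]] = graph.graph.get(
        "conflicts", {pair_key(a, b) for a, b in graph.edges}
    )
    cg = nx.Graph()
    cg.add_nodes_from(graph.nodes)
    cg.add_edges_from(conflicts)
    nodes = sorted(cg.nodes, key=lambda d: (-cg.degree(d), d))
    allowed = {d: _allowed_lumens(graph, d, catheter) for d in nodes}
    if any(not a for a in allowed.values()):
        return False, None

    def greedy() -> dict[str, int] | None:
        assign: dict[str, int] = {}
        for d in nodes:
            taken = {assign[n] for n in cg.neighbors(d) if n in assign}
            free = [l for l in allowed[d] if l not in taken]
            if not free:
                return None
            assign[d] = free[0]
        return assign

    assign = greedy()
    if assign is None and len(nodes) <= BACKTRACK_NODE_LIMIT:
        assign = _backtrack(cg, nodes, allowed)
    if assign is None:
        return False, None
    return True, {d: assign[d] for d in sorted(assign)}


def _backtrack(
    cg: nx.Graph, nodes: list[str], allowed: dict[str, list[int]]
) -> dict[str, int] | None:
    assign: dict[str, int] = {}

    def rec(i: int) -> bool:
        if i == len(nodes):
            return True
        d = nodes[i]
        taken = {assign[n] for n in cg.neighbors(d) if n in assign}
        for l in allowed[d]:
            if l not in taken:
                assign[d] = l
                if rec(i + 1):
                    return True
                del assign[d]
        return False

    return dict(assign) if rec(0) else None


def minimal_lumen_count(graph: nx.Graph, catheter: CatheterConfig) -> tuple[int, dict[str, int]]:
    """Smallest lumen budget admitting a conflict-free assignment."""
    n = max(catheter.n_lumens, 1)
    while True:
        bigger = CatheterConfig(n_lumens=n, reserved=catheter.reserved)
        ok, assign = try_relocate(graph, bigger)
        if ok:
            return n, assign
        n += 1
        if n > catheter.n_lumens + len(graph.nodes) + 1:  # chromatic num <= |V|
            raise RuntimeError("no conflict-free assignment found at any lumen count")


# ---------------------------------------------------------------------------
# Step 3: take a break
# ---------------------------------------------------------------------------

def try_pause(
    pair: tuple[str, str],
    chart: PatientChart,
    lumen: int,
    graph: nx.Graph,
    config: RecommenderConfig = RecommenderConfig(),
) -> tuple[bool, dict | None]:
    """Interrupt a pausable continuous infusion around the short infusion.

    Feasible iff exactly one member is continuous, that member is flagged
    pausable, and the chart allows the added flush volume.
    """
    a, b = pair_key(*pair)
    if chart.fluid_restricted:
        return False, None
    cont_a, cont_b = _is_continuous(chart, a), _is_continuous(chart, b)
    if cont_a == cont_b:
        return False, None
    cont, short = (a, b) if cont_a else (b, a)
    if cont in graph.nodes and not graph.nodes[cont]["pausable"]:
        return False, None
    short_evs = [e for e in chart.central_events(lumen) if e.drug == short]
    cont_evs = [e for e in chart.central_events(lumen) if e.drug == cont]
    pauses = sorted(
        {
            (max(0, s.start - config.flush_gap), min(config.horizon, s.end + config.flush_gap))
            for s in short_evs
            for c in cont_evs
            if _overlap(s.interval, c.interval)
        }
    )
    if not pauses:
        return False, None
    return True, {
        "action": "pause",
        "drug": cont,
        "around": short,
        "lumen": lumen,
        "pauses": [list(p) for p in pauses],
    }


# ---------------------------------------------------------------------------
# Plan application
# ---------------------------------------------------------------------------

def apply_plan_delta(chart: PatientChart, delta: dict) -> PatientChart:
    """Pure transform: apply one recommendation's plan to the chart."""
    events = list(chart.events)
    catheter = chart.catheter
    action = delta["action"]
    if action == "shift":
        drug, lumen, shift = delta["drug"], delta["lumen"], delta["shift_min"]
        events = [
            replace(e, start=e.start + shift, end=e.end + shift)
            if e.drug == drug and e.lumen_id == lumen and e.route.value == "CENTRAL_VENOUS"
            else e
            for e in events
        ]
    elif action in ("relocate", "expand"):
        if action == "expand":
            catheter = CatheterConfig(n_lumens=delta["n_lumens"], reserved=catheter.reserved)
        assignment = delta["assignment"]
        events = [
            replace(e, lumen_id=assignment[e.drug])
            if e.route.value == "CENTRAL_VENOUS" and e.drug in assignment
            else e
            for e in events
        ]
    elif action == "pause":
        drug, lumen = delta["drug"], delta["lumen"]
        pauses = [tuple(p) for p in delta["pauses"]]
        new_events = []
        for e in events:
            if not (e.drug == drug and e.lumen_id == lumen and e.route.value == "CENTRAL_VENOUS"):
                new_events.append(e)
                continue
            segments = [e.interval]
            for ps, pe in pauses:
                segments = [
                    seg
                    for s, t in segments
                    for seg in ((s, min(t, ps)), (max(s, pe), t))
                    if seg[1] > seg[0]
                ]
            new_events.extend(replace(e, start=s, end=t) for s, t in segments)
        events = new_events
    else:
        raise ValueError(f"unknown plan action {action!r}")
    return PatientChart(chart.patient_id, catheter, events, chart.fluid_restricted)


def apply_recommendations(chart: PatientChart, recs: Sequence[Recommendation]) -> PatientChart:
    for rec in recs:
        chart = apply_plan_delta(chart, rec.plan_delta)
    return chart


# ---------------------------------------------------------------------------
# The escalation engine
# ---------------------------------------------------------------------------

def recommend(
    chart: PatientChart,
    findings: Iterable[PairFinding],
    catheter: CatheterConfig | None = None,
    *,
    kb: KnowledgeBase,
    policy: ResolutionPolicy = DEFAULT_POLICY,
    config: RecommenderConfig = RecommenderConfig(),
) -> list[Recommendation]:
    """Deterministic lowest-feasible-step escalation per incompatible pair.

    Recommendations are computed against a working copy of the chart that is
    transformed as each plan is adopted, so the emitted plans compose: after
    applying all of them, re-analysis finds no incompatible simultaneous
    same-lumen pair.  Pairs resolved by one shared relocation are grouped
    into a single Step-2 (or Step-4) recommendation.
    """
    catheter = catheter or chart.catheter
    pred = incompatibility_predicate(kb, policy)
    work = PatientChart(chart.patient_id, catheter, list(chart.events), chart.fluid_restricted)
    recs: list[Recommendation] = []
    findings = list(findings)

    for _ in range(1000):  # each iteration removes at least one conflict
        conflicts = current_conflicts(work, pred)
        if not conflicts:
            break
        lumen, pair = conflicts[0]

        ok, delta = try_sequential(pair, work, lumen, pred, config)
        if ok:
            recs.append(
                Recommendation(
                    chart.patient_id,
                    frozenset([pair]),
                    1,
                    f"both {pair[0]} and {pair[1]} are short infusions; give them "
                    f"one after the other with a {config.flush_gap}-min flush",
                    delta,
                )
            )
            work = apply_plan_delta(work, delta)
            continue

        graph = build_graph(work, findings, kb=kb, policy=policy, config=config)
        ok, assignment = try_relocate(graph, work.catheter)
        if ok:
            delta = {"action": "relocate", "assignment": assignment}
            covered = frozenset(p for _, p in conflicts)
            recs.append(
                Recommendation(
                    chart.patient_id,
                    covered,
                    2,
                    "reassign drugs to lumens so no incompatible pair shares a "
                    "lumen while running",
                    delta,
                )
            )
            work = apply_plan_delta(work, delta)
            continue

        ok, delta = try_pause(pair, work, lumen, graph, config)
        if ok:
            recs.append(
                Recommendation(
                    chart.patient_id,
                    frozenset([pair]),
                    3,
                    f"interrupt the continuous {delta['drug']} infusion, flush, "
                    f"run {delta['around']}, flush, resume",
                    delta,
                )
            )
            work = apply_plan_delta(work, delta)
            continue

        n_needed, assignment = minimal_lumen_count(graph, work.catheter)
        delta = {"action": "expand", "n_lumens": n_needed, "assignment": assignment}
        covered = frozenset(p for _, p in conflicts)
        recs.append(
            Recommendation(
                chart.patient_id,
                covered,
                4,
                f"no conflict-free plan exists on {work.catheter.n_lumens} lumens; "
                f"a catheter with {n_needed} lumens admits one",
                delta,
            )
        )
        work = apply_plan_delta(work, delta)
    else:
        raise RuntimeError("recommendation loop failed to converge")

    return recs
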