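"""Four-step avoidance engine: feasibility predicates, coloring oracle,
escalation minimality, and resolution completeness."""

import itertools
import random

import networkx as nx
import pytest

from conftest import mk_chart, mk_event
from ivcompat.analysis import analyze_cohort
from ivcompat.charts import AdminMode, CatheterConfig
from ivcompat.kb import pair_key
from ivcompat.recommender import (
    RecommenderConfig,
    apply_recommendations,
    build_graph,
    current_conflicts,
    incompatibility_predicate,
    minimal_lumen_count,
    recommend,
    try_pause,
    try_relocate,
    try_sequential,
)
from ivcompat.synthetic import CohortParams, generate_cohort


def all_incompatible(a, b):
    return True


def brute_force_relocation(graph, catheter):
    """Exhaustive oracle: enumerate every drug->lumen assignment."""
    from ivcompat.recommender import _allowed_lumens

    nodes = sorted(graph.nodes)
    conflicts = graph.graph.get("conflicts", {pair_key(a, b) for a, b in graph.edges})
    allowed = [_allowed_lumens(graph, d, catheter) for d in nodes]
    for combo in itertools.product(*allowed):
        assign = dict(zip(nodes, combo))
        if all(assign[a] != assign[b] for a, b in conflicts):
            return True
    return False if nodes else True


def random_conflict_graph(rng, n_nodes, n_lumens):
    g = nx.Graph()
    drugs = [f"d{i}" for i in range(n_nodes)]
    for d in drugs:
        pinned = rng.randrange(1, n_lumens + 1) if rng.random() < 0.15 else None
        g.add_node(d, continuous=False, pausable=True, pinned=pinned,
                   class_tags=frozenset())
    for a, b in itertools.combinations(drugs, 2):
        if rng.random() < 0.45:
            g.add_edge(a, b)
    g.graph["conflicts"] = {pair_key(a, b) for a, b in g.edges}
    return g


class TestBuildGraph:
    def test_no_findings_gives_edgeless_graph(self, kb):
        chart = mk_chart([mk_event("heparin", 0, 60), mk_event("furosemide", 0, 60)])
        g = build_graph(chart, [], kb=kb)
        assert set(g.nodes) == {"heparin", "furosemide"} and not g.edges

    def test_path_graph_from_chained_findings(self, kb):
        from conftest import mk_finding

        chart = mk_chart(
            [mk_event(d, 0, 60) for d in ("heparin", "pantoprazole", "furosemide")]
        )
        findings = [
            mk_finding("P001", 1, "heparin", "pantoprazole"),
            mk_finding("P001", 1, "pantoprazole", "furosemide"),
        ]
        g = build_graph(chart, findings, kb=kb)
        assert set(map(frozenset, g.edges)) == {
            frozenset({"heparin", "pantoprazole"}),
            frozenset({"pantoprazole", "furosemide"}),
        }

    def test_reserved_lumen_pins_catecholamine(self, kb):
        chart = mk_chart(
            [mk_event("adrenaline", 0, 60), mk_event("heparin", 0, 60, lumen=2)],
            reserved={1: "catecholamine"},
        )
        g = build_graph(chart, [], kb=kb)
        assert g.nodes["adrenaline"]["pinned"] == 1
        assert not g.nodes["adrenaline"]["pausable"]
        assert g.nodes["heparin"]["pinned"] is None


class TestSequential:
    def test_two_short_infusions_shift_apart(self):
        chart = mk_chart([mk_event("a", 0, 60), mk_event("b", 30, 90)])
        ok, delta = try_sequential(("a", "b"), chart, 1, all_incompatible)
        assert ok
        assert delta["drug"] == "b" and delta["shift_min"] == 35  # ends at 60 + 5 gap
        from ivcompat.charts import coadministered_pairs
        from ivcompat.recommender import apply_plan_delta

        shifted = apply_plan_delta(chart, delta)
        assert coadministered_pairs(shifted, 1) == set()

    def test_continuous_member_is_infeasible(self):
        chart = mk_chart(
            [mk_event("a", 0, 600, mode=AdminMode.CONTINUOUS), mk_event("b", 30, 90)]
        )
        assert try_sequential(("a", "b"), chart, 1, all_incompatible)[0] is False

    def test_dense_lumen_with_no_safe_shift(self):
        config = RecommenderConfig(horizon=200, max_shift_search=200)
        chart = mk_chart(
            [mk_event("a", 0, 50), mk_event("b", 30, 80), mk_event("x", 80, 200)]
        )
        ok, _ = try_sequential(("a", "b"), chart, 1, all_incompatible, config)
        assert ok is False

    def test_fluid_restriction_blocks_flush_plans(self):
        chart = mk_chart(
            [mk_event("a", 0, 60), mk_event("b", 30, 90)], fluid_restricted=True
        )
        assert try_sequential(("a", "b"), chart, 1, all_incompatible)[0] is False


class TestRelocate:
    def _triangle(self):
        g = nx.Graph()
        for d in "abc":
            g.add_node(d, continuous=True, pausable=True, pinned=None,
                       class_tags=frozenset())
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.graph["conflicts"] = {pair_key(x, y) for x, y in g.edges}
        return g

    def test_triangle_needs_three_lumens(self):
        g = self._triangle()
        ok, assign = try_relocate(g, CatheterConfig(n_lumens=3))
        assert ok and len(set(assign.values())) == 3
        assert try_relocate(g, CatheterConfig(n_lumens=2))[0] is False

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = random.Random(31)
        for _ in range(120):
            n = rng.randrange(2, 9)
            lumens = rng.randrange(1, 5)
            g = random_conflict_graph(rng, n, lumens)
            cath = CatheterConfig(n_lumens=lumens)
            assert try_relocate(g, cath)[0] == brute_force_relocation(g, cath)

    def test_reserved_lumen_excludes_other_drugs(self):
        g = nx.Graph()
        g.add_node("heparin", continuous=False, pausable=True, pinned=None,
                   class_tags=frozenset({"anticoagulant"}))
        g.add_node("noradrenaline", continuous=True, pausable=False, pinned=1,
                   class_tags=frozenset({"catecholamine"}))
        g.add_edge("heparin", "noradrenaline")
        g.graph["conflicts"] = {pair_key("heparin", "noradrenaline")}
        cath = CatheterConfig(n_lumens=2, reserved={1: "catecholamine"})
        ok, assign = try_relocate(g, cath)
        assert ok and assign == {"heparin": 2, "noradrenaline": 1}

    def test_step4_minimal_count_equals_chromatic_number(self):
        g = self._triangle()
        n, assign = minimal_lumen_count(g, CatheterConfig(n_lumens=2))
        assert n == 3 and len(set(assign.values())) == 3


class TestPause:
    def _cont_vs_short(self, kb, cont_drug="furosemide"):
        chart = mk_chart(
            [
                mk_event(cont_drug, 0, 1400, mode=AdminMode.CONTINUOUS),
                mk_event("pantoprazole", 300, 330),
            ]
        )
        g = build_graph(chart, [], kb=kb)
        return chart, g

    def test_pausable_continuous_vs_short_is_feasible(self, kb):
        chart, g = self._cont_vs_short(kb)
        ok, plan = try_pause(("furosemide", "pantoprazole"), chart, 1, g)
        assert ok
        assert plan["drug"] == "furosemide" and plan["pauses"] == [[295, 335]]

    def test_catecholamine_is_not_pausable(self, kb):
        chart, g = self._cont_vs_short(kb, cont_drug="adrenaline")
        assert try_pause(("adrenaline", "pantoprazole"), chart, 1, g)[0] is False

    def test_both_continuous_infeasible(self, kb):
        chart = mk_chart(
            [
                mk_event("furosemide", 0, 1400, mode=AdminMode.CONTINUOUS),
                mk_event("pantoprazole", 0, 1400, mode=AdminMode.CONTINUOUS),
            ]
        )
        g = build_graph(chart, [], kb=kb)
        assert try_pause(("furosemide", "pantoprazole"), chart, 1, g)[0] is False


class TestRecommend:
    def test_single_short_infusion_pair_gets_step1(self, kb):
        chart = mk_chart(
            [
                mk_event("piperacillin/tazobactam", 0, 120),
                mk_event("pantoprazole", 30, 90),
                mk_event("sodium chloride", 0, 200),
            ]
        )
        findings, _ = analyze_cohort([chart], kb)
        recs = recommend(chart, findings, kb=kb)
        assert [r.step for r in recs] == [1]
        assert recs[0].step_name == "Administer sequentially"

    def test_no_incompatible_findings_empty_list(self, kb):
        chart = mk_chart([mk_event("heparin", 0, 60), mk_event("furosemide", 0, 60)])
        recs = recommend(chart, [], kb=kb)
        assert recs == []

    def test_steps_1_to_3_all_infeasible_escalates_to_step4(self, kb):
        # complete graph of continuous non-pausable drugs over a 2-lumen budget
        chart = mk_chart(
            [
                mk_event("adrenaline", 0, 1400, mode=AdminMode.CONTINUOUS, lumen=1),
                mk_event("noradrenaline", 0, 1400, mode=AdminMode.CONTINUOUS, lumen=1),
                mk_event("heparin", 0, 1400, mode=AdminMode.CONTINUOUS, lumen=2),
            ],
            n_lumens=2,
        )
        g = build_graph(chart, [], kb=kb)
        g.graph["conflicts"] = {
            pair_key(a, b)
            for a, b in itertools.combinations(sorted(g.nodes), 2)
        }
        assert try_relocate(g, chart.catheter)[0] is False
        n, _ = minimal_lumen_count(g, chart.catheter)
        assert n == 3  # brute-force chromatic number of K3

    def test_escalation_minimality(self, kb):
        """A step-3 recommendation implies steps 1-2 were infeasible."""
        chart = mk_chart(
            [
                mk_event("furosemide", 0, 1400, mode=AdminMode.CONTINUOUS, lumen=1),
                mk_event("pantoprazole", 300, 330, lumen=1),
            ],
            n_lumens=1,
        )
        findings, _ = analyze_cohort([chart], kb)
        pred = incompatibility_predicate(kb)
        recs = recommend(chart, findings, kb=kb)
        step3 = [r for r in recs if r.step == 3]
        for rec in step3:
            (pair,) = rec.pairs
            lumen = rec.plan_delta["lumen"]
            assert try_sequential(pair, chart, lumen, pred)[0] is False
            g = build_graph(chart, findings, kb=kb)
            assert try_relocate(g, chart.catheter)[0] is False

    def test_determinism(self, kb):
        charts, _, _ = generate_cohort(CohortParams(seed=17, n_patients=25))
        findings, _ = analyze_cohort(charts, kb)
        for chart in charts:
            r1 = recommend(chart, findings, kb=kb)
            r2 = recommend(chart, findings, kb=kb)
            assert r1 == r2

    @pytest.mark.parametrize("seed", [4, 8])
    def test_resolution_completeness(self, kb, seed):
        """Applying every plan removes all incompatible same-lumen overlaps."""
        charts, _, _ = generate_cohort(CohortParams(seed=seed, n_patients=40))
        findings, _ = analyze_cohort(charts, kb)
        pred = incompatibility_predicate(kb)
        for chart in charts:
            recs = recommend(chart, findings, kb=kb)
            transformed = apply_recommendations(chart, recs)
            assert current_conflicts(transformed, pred) == []
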