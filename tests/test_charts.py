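"""Chart ingestion, sweep-line co-administration, and the inclusion rule."""

import random

import pytest

from conftest import mk_chart, mk_event
from ivcompat.charts import (
    AdminMode,
    ChartValidationError,
    coadministered_pairs,
    meets_inclusion,
    read_catheters,
    read_charts,
    simultaneous_sets,
    write_catheters,
    write_charts,
)
from ivcompat.kb import pair_key
from ivcompat.synthetic import CohortParams, generate_cohort


def minute_grid_sets(chart, lumen):
    """Brute-force oracle: evaluate the active drug set at every minute."""
    evs = chart.central_events(lumen)
    active = {}
    for t in range(0, 1600):
        s = frozenset(e.drug for e in evs if e.start <= t < e.end)
        if s:
            active[t] = s
    return active


def expand_windows(windows):
    return {t: drugs for (lo, hi), drugs in windows for t in range(lo, hi)}


class TestSimultaneousSets:
    def test_two_overlapping_intervals(self):
        chart = mk_chart([mk_event("a", 0, 60), mk_event("b", 30, 90)])
        assert simultaneous_sets(chart, 1) == [
            ((0, 30), frozenset({"a"})),
            ((30, 60), frozenset({"a", "b"})),
            ((60, 90), frozenset({"b"})),
        ]

    def test_touching_endpoints_do_not_overlap(self):
        chart = mk_chart([mk_event("a", 0, 60), mk_event("b", 60, 120)])
        assert all(len(drugs) == 1 for _, drugs in simultaneous_sets(chart, 1))

    def test_empty_lumen(self):
        chart = mk_chart([mk_event("a", 0, 60, lumen=1)])
        assert simultaneous_sets(chart, 2) == []

    def test_windows_partition_union(self):
        rng = random.Random(3)
        for _ in range(30):
            evs = [
                mk_event(f"d{rng.randrange(8)}", s, s + rng.randrange(1, 120))
                for s in (rng.randrange(0, 800) for _ in range(12))
            ]
            chart = mk_chart(evs)
            windows = simultaneous_sets(chart, 1)
            # sorted and disjoint
            for (w1, _), (w2, _) in zip(windows, windows[1:]):
                assert w1[1] <= w2[0]
            covered = set(expand_windows(windows))
            union = {t for e in evs for t in range(e.start, e.end)}
            assert covered == union

    def test_matches_minute_grid_oracle(self):
        rng = random.Random(7)
        for _ in range(50):
            evs = [
                mk_event(f"d{rng.randrange(10)}", s, s + rng.randrange(1, 200))
                for s in (rng.randrange(0, 1300) for _ in range(20))
            ]
            chart = mk_chart(evs)
            assert expand_windows(simultaneous_sets(chart, 1)) == minute_grid_sets(chart, 1)


class TestCoadministeredPairs:
    def test_three_pairwise_overlapping_drugs(self):
        chart = mk_chart(
            [mk_event("a", 0, 100), mk_event("b", 10, 90), mk_event("c", 20, 80)]
        )
        assert coadministered_pairs(chart, 1) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_single_drug(self):
        chart = mk_chart([mk_event("a", 0, 100)])
        assert coadministered_pairs(chart, 1) == set()

    def test_matches_all_pairs_brute_force(self):
        rng = random.Random(11)
        for _ in range(40):
            evs = [
                mk_event(f"d{rng.randrange(9)}", s, s + rng.randrange(1, 150),
                         lumen=rng.randrange(1, 4))
                for s in (rng.randrange(0, 1000) for _ in range(15))
            ]
            chart = mk_chart(evs)
            for lumen in (1, 2, 3):
                brute = {
                    pair_key(e1.drug, e2.drug)
                    for i, e1 in enumerate(chart.central_events(lumen))
                    for e2 in chart.central_events(lumen)[i + 1:]
                    if e1.drug != e2.drug
                    and e1.start < e2.end and e2.start < e1.end
                }
                assert coadministered_pairs(chart, lumen) == brute

    def test_pairs_never_span_lumens(self):
        chart = mk_chart([mk_event("a", 0, 100, lumen=1), mk_event("b", 0, 100, lumen=2)])
        assert coadministered_pairs(chart, 1) == set()
        assert coadministered_pairs(chart, 2) == set()


class TestInclusion:
    def test_max_two_concurrent_everywhere_excluded(self):
        chart = mk_chart(
            [mk_event("a", 0, 50), mk_event("b", 0, 50), mk_event("c", 50, 100)]
        )
        ok, witness = meets_inclusion(chart)
        assert not ok and witness is None

    def test_three_concurrent_included_with_witness(self):
        chart = mk_chart(
            [mk_event("a", 0, 20, lumen=3), mk_event("b", 5, 20, lumen=3),
             mk_event("c", 9, 15, lumen=3)]
        )
        ok, witness = meets_inclusion(chart)
        assert ok
        lumen, (lo, hi) = witness
        assert lumen == 3 and lo >= 9 and hi <= 15

    def test_generator_labels_match_decisions(self):
        charts, _, truth = generate_cohort(CohortParams(seed=5, n_patients=40))
        for chart in charts:
            assert meets_inclusion(chart)[0] == truth.included[chart.patient_id]


class TestReadWrite:
    def test_round_trip_on_generated_cohort(self, lexicon, tmp_path):
        charts, catheters, _ = generate_cohort(CohortParams(seed=3, n_patients=15))
        write_charts(charts, tmp_path / "charts.csv")
        write_catheters(catheters, tmp_path / "catheters.yaml")
        back = read_charts(
            tmp_path / "charts.csv", lexicon, read_catheters(tmp_path / "catheters.yaml")
        )
        assert len(back) == len(charts)
        for orig, loaded in zip(sorted(charts, key=lambda c: c.patient_id), back):
            assert loaded.patient_id == orig.patient_id
            assert sorted(loaded.events, key=repr) == sorted(orig.events, key=repr)
            assert loaded.catheter == orig.catheter

    def test_bad_rows_reported_with_row_numbers(self, lexicon, tmp_path):
        p = tmp_path / "charts.csv"
        p.write_text(
            "patient_id,drug,route,lumen,start_min,end_min,mode\n"
            "P1,heparin,CENTRAL_VENOUS,1,10,10,CONTINUOUS\n"      # empty interval
            "P1,heparin,CENTRAL_VENOUS,9,0,60,CONTINUOUS\n"       # lumen out of range
            "P1,xyzmab,CENTRAL_VENOUS,1,0,60,CONTINUOUS\n"        # unknown drug
            "P1,heparin,CENTRAL_VENOUS,1,0,60,SLOWLY\n"           # unknown mode
        )
        with pytest.raises(ChartValidationError) as exc:
            read_charts(p, lexicon, {})
        msgs = "\n".join(exc.value.errors)
        assert len(exc.value.errors) == 4
        for row in ("row 2", "row 3", "row 4", "row 5"):
            assert row in msgs

    def test_skip_bad_rows_downgrades(self, lexicon, tmp_path):
        p = tmp_path / "charts.csv"
        p.write_text(
            "patient_id,drug,route,lumen,start_min,end_min,mode\n"
            "P1,heparin,CENTRAL_VENOUS,1,10,10,CONTINUOUS\n"
            "P1,furosemide,CENTRAL_VENOUS,1,0,60,CONTINUOUS\n"
        )
        charts = read_charts(p, lexicon, {}, skip_bad_rows=True)
        assert len(charts) == 1 and len(charts[0].events) == 1

    def test_multi_day_horizon_rejected(self, lexicon, tmp_path):
        p = tmp_path / "charts.csv"
        p.write_text(
            "patient_id,drug,route,lumen,start_min,end_min,mode\n"
            "P1,heparin,CENTRAL_VENOUS,1,0,2000,CONTINUOUS\n"
        )
        with pytest.raises(ChartValidationError, match="horizon"):
            read_charts(p, lexicon, {})

    def test_bolus_duration_cap(self, lexicon, tmp_path):
        p = tmp_path / "charts.csv"
        p.write_text(
            "patient_id,drug,route,lumen,start_min,end_min,mode\n"
            "P1,heparin,CENTRAL_VENOUS,1,0,120,BOLUS\n"
        )
        with pytest.raises(ChartValidationError, match="[Bb]olus"):
            read_charts(p, lexicon, {})


def test_co_admin_slack_pads_intervals():
    chart = mk_chart([mk_event("a", 0, 60), mk_event("b", 60, 120)])
    assert coadministered_pairs(chart, 1) == set()
    assert coadministered_pairs(chart, 1, co_admin_slack=5) == {("a", "b")}
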