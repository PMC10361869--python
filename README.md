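# ivcompat

Algorithm-based screening of **physico-chemical drug incompatibilities in
central-venous catheters (CVCs)**, for clinical pharmacists and
medication-safety researchers in critical care.

When two IV drugs meet in the same catheter lumen they can precipitate,
degrade, or inactivate each other — a hazard distinct from pharmacological
drug–drug interaction. Critically ill patients routinely receive a dozen or
more central-venous drugs through 3- or 5-lumen catheters, and the published
compatibility evidence (commercial databases, the drug label, handbook
monographs) is patchy and often contradictory. `ivcompat` implements the
whole screening workflow as a tested library plus CLI:

1. **Knowledge base** (`ivcompat.kb`) — an open CSV/JSON format holding one
   compatibility assertion per unordered drug pair per evidence source
   (modelled abstractly as `KIK`, `STABILIS`, `SMPC`, `TRISSEL`), with a
   drug-name lexicon and strict exact-after-normalization name matching.
2. **Multi-source resolution** (`ivcompat.resolution`) — maps the four
   per-source answers (compatible / incompatible / internally conflicting /
   no data) to one of three final classes: *compatible*, *incompatible*, or
   *not evaluable* (sources conflict or no data exists), with a full
   evidence trail. Under the default strict-consensus policy, all
   data-bearing sources must agree; genuine disagreement is never silently
   overridden.
3. **Chart screening** (`ivcompat.charts`, `ivcompat.analysis`) — parses
   per-patient medication administration records with half-open
   integer-minute intervals, finds simultaneous co-administration per lumen
   by a sweep line, applies the inclusion rule (≥ 3 drugs simultaneously on
   one lumen), and classifies every co-administered pair. Aggregates:
   per-drug frequency table, symmetric cross-table of incompatible pairs,
   patient-level counts with quartiles.
4. **Four-step avoidance recommender** (`ivcompat.recommender`) — for every
   incompatible pair, the lowest feasible of: *1 administer sequentially*,
   *2 use another lumen* (constrained graph coloring with reserved/pinned
   lumens), *3 take a break* (pause a pausable continuous infusion), *4 use
   a catheter with more lumens* (minimal lumen count = chromatic number of
   the conflict graph). Every recommendation carries a machine-applicable
   `plan_delta`; applying all of them provably removes every incompatible
   same-lumen overlap.
5. **Staff survey scoring** (`ivcompat.survey`) — grades knowledge items
   (compatible vs incompatible) against the answer key and summarizes 0–5
   Likert assumption items (median, Q25/Q75, range).
6. **Synthetic data** (`ivcompat.synthetic`) — a bundled fixture knowledge
   base and seeded generators for ICU cohorts (with exact planted ground
   truth) and survey responses, so the entire pipeline is testable offline.

## Worked example

```python
import ivcompat as iv

kb = iv.fixture_kb()
v = iv.resolve_pair(kb, "piperacillin/tazobactam", "pantoprazole")
print(v.classification.value, v.reason.value)
print([(t.source, t.verdict.value) for t in v.trail])
```

```
INCOMPATIBLE SINGLE_SOURCE
[('KIK', 'NO_DATA'), ('STABILIS', 'INCOMPATIBLE'), ('SMPC', 'NO_DATA'), ('TRISSEL', 'NO_DATA')]
```

The pair is definitely incompatible, but the trail shows the call rests on a
single database — exactly the kind of thin evidence base the trail is there
to expose. Now a small synthetic cohort, screened end to end:

```python
charts, catheters, truth = iv.generate_cohort(iv.CohortParams(seed=7, n_patients=25))
findings, summary = iv.analyze_cohort(charts, kb)
print(summary.to_dict())
print(iv.drug_frequency_table(findings).head(5).to_string(index=False))
```

```
{'n_admitted': 25, 'n_included': 11, 'n_patients_with_incompatibility': 8,
 'n_incompatible_combinations': 13, 'n_not_evaluable': 93,
 'pct_included': 44.0, 'pct_patients_with_incompatibility': 72.7}
            drug  count  percent
    erythromycin      3     23.1
      furosemide      3     23.1
    pantoprazole      3     23.1
calcium chloride      2     15.4
      cefuroxime      2     15.4
```

Of 25 admitted synthetic patients, 11 met the inclusion rule; 13 incompatible
co-administrations were found (erythromycin, furosemide and pantoprazole each
involved in 3, i.e. 23.1 % of the 13), and 93 co-administered pairs were not
evaluable from the evidence. The recovered incompatible findings equal the
generator's planted ground truth exactly (`truth.planted_multiset()`).

The same pipeline from the shell:

```bash
ivcompat simulate --seed 7 --n-patients 25 --out-dir out/sim
ivcompat analyze  --charts out/sim/charts.csv --catheters out/sim/catheters.yaml \
                  --kb out/sim/kb.json --out-dir out/analysis
ivcompat recommend --charts out/sim/charts.csv --catheters out/sim/catheters.yaml \
                   --kb out/sim/kb.json --out out/recommendations.csv
ivcompat resolve --kb fixture --pair "Dipyrone+Vancomycin"
```

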