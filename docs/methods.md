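# Methods

## Problem and model

`ivcompat` screens central-venous drug administration for physico-chemical
incompatibility — precipitation, degradation or inactivation when two IV
drugs mix in a shared catheter lumen. The unit of analysis is the unordered
drug pair within one lumen of one patient on one treatment day. Three model
layers:

1. **Evidence model.** Each of several sources (two compatibility databases,
   the drug label, a handbook; abstract IDs `KIK`, `STABILIS`, `SMPC`,
   `TRISSEL`, extensible with a precedence rank) may assert one of
   `COMPATIBLE`, `INCOMPATIBLE`, or `CONFLICTING_WITHIN_SOURCE` for a pair;
   an absent assertion is implicitly `NO_DATA`. Assertions carry provenance
   (free-text evidence note and citation) because compatibility calls often
   rest on a single analytical study.
2. **Timing model.** Administration events are half-open integer-minute
   intervals `[start, end)` on a specific lumen, in one of three modes
   (continuous, intermittent, bolus; boluses capped at 15 min by default).
   Two drugs are *simultaneous* iff their intervals intersect with positive
   duration — touching endpoints do not overlap. This is the strictest
   defensible reading of "given simultaneously"; an optional
   `co_admin_slack` (default 0 min) pads interval ends to model residual
   line content.
3. **Catheter model.** A catheter has `n_lumens` independent channels;
   lumens may be reserved for a purpose (e.g. `catecholamine`, `analgesia`),
   which pins matching drugs to that lumen and excludes others from it.
   Lumen labels are opaque integers; proximal/medial/distal semantics are
   not modelled.

## Resolution policy

Let V be the data-bearing verdicts (`COMPATIBLE`/`INCOMPATIBLE`) in source
order. Two modes:

- **`STRICT_CONSENSUS`** (default). If V is empty: *not evaluable* (reason
  `NO_DATA`, or `CONFLICT` if some source is internally conflicting). If V
  contains both classes: *not evaluable / conflict* — genuine cross-source
  disagreement is never overridden, because silently picking a side is
  precisely the burden this tool removes from the bedside. If V agrees, the
  agreed class is returned (reason `AGREEMENT`, or `SINGLE_SOURCE` when only
  one source had data) — unless an internally conflicting source is present,
  which normally forces *not evaluable / conflict*; with
  `incompatible_dominates` (default on) an agreed `INCOMPATIBLE` survives
  such a self-conflicting counter-signal, because a safety tool should fail
  toward "incompatible".
- **`PRECEDENCE_FIRST`.** The first data-bearing source in
  `source_order` decides outright.

Both modes are pure, symmetric in the pair, and fully logged: the verdict
trail records all consulted sources in order, flagging consulted-but-unused
entries in precedence mode. The stopping rule of screening algorithms in
this domain is typically underdocumented; both plausible behaviours are
therefore first-class configurable modes rather than one hard-coded guess.
An exhaustive truth table over all 4⁴ source-verdict tuples
(`classify_policy_table`) doubles as the audit surface and the oracle
target in tests.

## Cohort analysis

A patient enters the analysis iff some lumen carries ≥ 3 distinct drugs
simultaneously at some moment (`meets_inclusion`, witness returned).
Co-administration is computed by a sweep line over event endpoints; the
resulting windows are disjoint, sorted, and partition the union of event
intervals, and are verified in tests against a minute-by-minute grid oracle
under the same half-open convention. Counting is by occurrence — a pair
counts once per (patient, lumen, pair), and k patients with the same pair
contribute k — with a `distinct_pairs` switch for the
once-per-cohort alternative reading. Not-evaluable findings are kept in a
separate ledger, never dropped. Percentages are rounded half-up (one decimal
for cohort reports, whole percents for survey tables); half-up rather than
banker's rounding is required to reproduce the published percentage style
(e.g. 18/130 → 13.8, 64/104 → 61.5). Quantiles default to the weighted
average at (n+1)p — the convention of the common clinical statistics
packages — and are switchable to any numpy method; with published quartiles
and no raw data, the convention must be explicit rather than implicit.

## The four-step recommender

For each incompatible same-lumen overlap, the engine picks the lowest
feasible step:

1. **Administer sequentially** — feasible iff neither member runs
   continuously and the patient is not fluid-restricted. The member whose
   first event starts later is shifted by the minimal integer number of
   minutes that separates the pair by the flush gap (default 5 min) without
   creating a new incompatible overlap on the lumen or running past the
   horizon (exhaustive integer search, bounded by the horizon).
2. **Use another lumen** — a constrained coloring of the conflict graph
   (nodes: the patient's central-venous drugs; forbidden same-lumen pairs:
   every time-overlapping incompatible pair, regardless of current lumen, so
   a relocation can never create a new conflict). Pinned drugs keep their
   reserved lumens; reserved lumens accept only their purpose's drugs.
   Solved greedily (largest degree first) with exact backtracking for
   graphs ≤ 12 nodes; tests verify exact agreement with exhaustive
   enumeration on graphs ≤ 8 nodes.
3. **Take a break** — feasible iff exactly one member is continuous, that
   member is pausable (catecholamines are non-pausable by default), and no
   fluid restriction applies; the continuous infusion is split around each
   overlapping short infusion ± flush gap.
4. **More lumens** — the minimal lumen budget admitting a conflict-free
   assignment (incremental search; equals the chromatic number of the
   conflict graph when no lumens are reserved).

The engine works on a transforming copy of the chart: each adopted plan is
applied before the next conflict is examined, so emitted plans compose.
Consequently, after applying all `plan_delta`s, re-analysis finds zero
incompatible simultaneous same-lumen pairs — checked on every generated
cohort seed. Pairs resolved by one shared relocation are grouped into a
single step-2 recommendation. Tie-breaking is lexicographic by drug name,
then lumen index, making the output deterministic. Fluid-restricted patients
(`fluid_restricted` flag, default off) skip the flush-adding steps 1 and 3.

## Survey scoring

Knowledge items are graded answer-equals-key; per-item results are whole
percents (half-up) of correct / incorrect / unanswered, and grand totals sum
over items. Because published survey tables print percents rather than raw
counts, `reconstruct_counts(pct, n) = round_half_up(pct·n/100)` inverts them;
reconstructing all per-item counts at 14 participants and rescoring them
reproduces the published grand tallies (154 responses: 103 correct, 49
incorrect, 2 unanswered) exactly, which serves as the module's self-test.
Likert items (0 never … 5 always) exclude "no answer possible" from all
statistics; a question with no answered responses reports missing values,
not zeros.

## Synthetic data

The fixture knowledge base covers every drug of the screening setting
(35 concepts with synonyms — e.g. dipyrone → metamizole — and class tags)
and encodes: the 11-pair answer key, the five not-evaluable combinations
(represented as cross-source conflicts, one database compatible vs the
handbook incompatible — whether they arose from conflict or absence is an
assumption of this fixture), the named definitely-incompatible pairs as
single-source database assertions (mirroring their thin real-world evidence
base), and a pool of explicitly compatible carrier/co-infusion pairs used as
distractors.

The cohort generator emulates one ICU treatment day per patient. Defaults
are the study-shaped conditions: 220 admitted patients of whom ≈ 47 % meet
the inclusion rule; drugs per patient from a discretized log-normal with
median 19 and quartiles ≈ 15.75/23 (σ = 0.283 on the log scale), of which
≈ 12/19 are central-venous; 3-lumen catheters with a 30 % share of 5-lumen
(post-surgery) catheters; 25 % continuous infusions and 10 % boluses; and
planted incompatible occurrences per included patient drawn Poisson with
mean 130/104 ≈ 1.25. Every drug on a lumen overlaps every other drug on
that lumen inside a common administration window ([480, 540) min), so the
maximal concurrent set, the inclusion decision and every co-administered
pair are known by construction; planted pairs come from the fixture's
incompatible set and all other same-lumen pairs are compatible or lack
data. The emitted `PlantedTruth` therefore describes the schedule exactly,
and the analyzer is required to recover it verbatim at every seed.

What the generator does **not** emulate: staggered partial overlaps within a
lumen (all same-lumen drugs co-occur by design), dose/concentration/flow
rates, multi-day courses, reserved-purpose lumens (exercised in unit tests
instead), and the real study's verbatim counts (130 findings, 64/104
patients), which depend on unavailable patient charts. Passing tests
demonstrate algorithmic correctness on schedules with known truth, not
epidemiological realism of incompatibility rates.

Problem sizes used by the validation runs: 200 random lumens for the
sweep-line oracle, all 512 policy-table entries, 150 random relocation
instances of ≤ 8 nodes, and 20 cohort seeds of 30 patients each for the
end-to-end completeness check.

## Numerical and degenerate-input choices

- Time is integer minutes; one chart = one day, enforced by a 1600-min
  horizon check (multi-day inputs must be pre-split).
- A pair of a drug with itself is undefined and raises.
- Unknown drug names are hard errors (no fuzzy matching — a silent
  mismatch is worse than a crash in a safety context); `skip_bad_rows`
  downgrades chart-row failures to logged warnings.
- Contradictory duplicate assertions for the same (pair, source) abort a
  KB load, naming both rows.
- Empty lumens, empty findings and all-zero counts return empty
  tables/lists, not errors; `percent1` with a zero denominator raises.
- All outputs are deterministic at a fixed seed; run metadata deliberately
  carries no wall-clock timestamps so repeated runs are byte-identical.

## Known limitations

- Verdicts are binary per source; concentration-, diluent- and
  contact-time-resolved compatibility is out of scope, as is evidence
  weighting.
- The recommender models only existing lumens plus the more-lumens
  escalation; adding tap distributors mid-chain, switching to peroral
  forms, and diluted-infusion strategies are not modelled.
- Peripheral-venous events are parsed but excluded from the analysis.
- Step feasibility predicates (sequential = both non-continuous; pause =
  continuous vs short with a pausable flag) are this package's
  operationalization of the clinical escalation ladder; real wards may
  apply softer criteria.
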