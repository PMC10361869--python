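"""Fixture knowledge base and seeded generators for cohorts and surveys.

The fixture KB encodes the compatibility facts of a published ICU screening
setting: an answer key of 11 frequently co-administered pairs, five
combinations on which the evidence sources conflict (hence *not evaluable*),
and the named definitely-incompatible pairs.  The cohort generator emits a
realistic one-day ICU medication schedule per patient — 3- or 5-lumen
central-venous catheters, continuous and intermittent infusions plus boluses,
peripheral extras — together with an exact ground truth of every planted
incompatible (lumen, pair) occurrence, so the whole screening pipeline is
testable without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .charts import AdminMode, AdministrationEvent, CatheterConfig, PatientChart, Route
from .kb import (
    CompatibilityAssertion,
    DrugConcept,
    KnowledgeBase,
    Lexicon,
    SourceVerdict,
    pair_key,
)
from .survey import Answer, KnowledgeItem, KnowledgeResponse

# ---------------------------------------------------------------------------
# Fixture lexicon
# ---------------------------------------------------------------------------

_CONCEPTS: list[tuple[str, tuple[str, ...], tuple[str, ...], bool]] = [
    # canonical, synonyms, class tags, combination product
    ("furosemide", ("lasix",), ("diuretic",), False),
    ("pantoprazole", (), ("proton-pump-inhibitor",), False),
    ("piperacillin/tazobactam", ("pip/tazo", "tazobac"), ("anti-infective",), True),
    ("heparin", ("heparine",), ("anticoagulant",), False),
    ("erythromycin", (), ("anti-infective",), False),
    ("cefuroxime", (), ("anti-infective",), False),
    ("ringer's acetate", ("ringer acetate",), ("carrier-solution",), False),
    ("ampicillin/sulbactam", (), ("anti-infective",), True),
    ("metoclopramide", (), ("antiemetic",), False),
    ("caspofungin", (), ("anti-infective",), False),
    ("metamizole", ("dipyrone", "novaminsulfone"), ("analgesic",), False),
    ("levetiracetam", (), ("anticonvulsant",), False),
    ("prednisolone", (), ("corticosteroid",), False),
    ("magnesium sulfate", (), ("electrolyte",), False),
    ("metronidazole", (), ("anti-infective",), False),
    ("meropenem", (), ("anti-infective",), False),
    ("ciprofloxacin", (), ("anti-infective",), False),
    ("amiodarone", (), ("antiarrhythmic",), False),
    ("linezolid", (), ("anti-infective",), False),
    ("calcium chloride", (), ("electrolyte",), False),
    ("esketamine", (), ("anesthetic",), False),
    ("dexmedetomidine", (), ("sedative",), False),
    ("sufentanil", (), ("analgesia",), False),
    ("adrenaline", ("epinephrine",), ("catecholamine",), False),
    ("noradrenaline", ("norepinephrine",), ("catecholamine",), False),
    ("propofol", (), ("anesthetic",), False),
    ("sodium chloride", ("nacl 0.9%", "saline"), ("electrolyte", "carrier-solution"), False),
    ("potassium chloride", (), ("electrolyte",), False),
    ("sodium bicarbonate", (), ("electrolyte",), False),
    ("parenteral nutrition", ("smofkabiven", "nutrition (smofkabiven)"), ("nutrition",), False),
    ("vancomycin", (), ("anti-infective",), False),
    ("clindamycin", (), ("anti-infective",), False),
    ("urapidil", (), ("antihypertensive",), False),
    ("glucose solution", ("glucose 5%",), ("nutrition", "carrier-solution"), False),
    ("multi-vitamin supplement", ("cernevit",), ("nutrition",), False),
]


def fixture_lexicon() -> Lexicon:
    return Lexicon(
        DrugConcept(name, frozenset(syn), frozenset(tags), combo)
        for name, syn, tags, combo in _CONCEPTS
    )


# ---------------------------------------------------------------------------
# Fixture assertions
# ---------------------------------------------------------------------------

#: definitely-incompatible pairs named in the screening results
NAMED_INCOMPATIBLE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    pair_key(a, b)
    for a, b in [
        ("erythromycin", "metoclopramide"),
        ("piperacillin/tazobactam", "pantoprazole"),
        ("prednisolone", "ampicillin/sulbactam"),
        ("cefuroxime", "ringer's acetate"),
        ("heparin", "calcium chloride"),
        ("erythromycin", "multi-vitamin supplement"),
        ("metamizole", "levetiracetam"),
        ("piperacillin/tazobactam", "ciprofloxacin"),
        ("heparin", "pantoprazole"),
        ("piperacillin/tazobactam", "erythromycin"),
        ("furosemide", "pantoprazole"),
    ]
)

#: combinations on which the sources conflict -> not evaluable
NOT_EVALUABLE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    pair_key(a, b)
    for a, b in [
        ("metamizole", "vancomycin"),
        ("metamizole", "clindamycin"),
        ("metamizole", "metoclopramide"),
        ("cefuroxime", "urapidil"),
        ("furosemide", "glucose solution"),
    ]
)

# Answer key of the staff knowledge questionnaire: pair, key, and the
# published per-item response shares (percent correct / incorrect / blank)
# at 14 participants.
KNOWLEDGE_TABLE: list[tuple[str, str, str, str, int, int, int]] = [
    ("k01", "amiodarone", "calcium chloride", "INCOMPATIBLE", 100, 0, 0),
    ("k02", "esketamine", "dexmedetomidine", "COMPATIBLE", 79, 21, 0),
    ("k03", "sufentanil", "adrenaline", "COMPATIBLE", 57, 43, 0),
    ("k04", "amiodarone", "sodium chloride", "INCOMPATIBLE", 100, 0, 0),
    ("k05", "propofol", "esketamine", "COMPATIBLE", 93, 7, 0),
    ("k06", "piperacillin/tazobactam", "pantoprazole", "INCOMPATIBLE", 14, 86, 0),
    ("k07", "heparin", "potassium chloride", "COMPATIBLE", 21, 79, 0),
    ("k08", "cefuroxime", "sodium bicarbonate", "INCOMPATIBLE", 79, 7, 14),
    ("k09", "parenteral nutrition", "metronidazole", "COMPATIBLE", 79, 21, 0),
    ("k10", "parenteral nutrition", "cefuroxime", "COMPATIBLE", 71, 29, 0),
    ("k11", "furosemide", "pantoprazole", "INCOMPATIBLE", 43, 57, 0),
]

N_SURVEY_PARTICIPANTS = 14


def knowledge_items() -> list[KnowledgeItem]:
    return [KnowledgeItem(iid, (a, b), Answer(key)) for iid, a, b, key, *_ in KNOWLEDGE_TABLE]


def knowledge_probabilities() -> dict[str, tuple[float, float, float]]:
    """Default per-item (correct, incorrect, blank) probabilities."""
    return {iid: (c / 100, i / 100, b / 100) for iid, _, _, _, c, i, b in KNOWLEDGE_TABLE}


# extra explicitly-compatible pairs so generated lumens contain data-backed
# distractors (carrier solutions and common co-infusions)
_EXTRA_COMPATIBLE: list[tuple[str, str]] = [
    ("sodium chloride", "furosemide"),
    ("sodium chloride", "pantoprazole"),
    ("sodium chloride", "heparin"),
    ("sodium chloride", "meropenem"),
    ("sodium chloride", "vancomycin"),
    ("sodium chloride", "cefuroxime"),
    ("sodium chloride", "piperacillin/tazobactam"),
    ("glucose solution", "amiodarone"),
    ("noradrenaline", "adrenaline"),
    ("sufentanil", "dexmedetomidine"),
    ("propofol", "sufentanil"),
    ("magnesium sulfate", "potassium chloride"),
    ("meropenem", "metronidazole"),
    ("linezolid", "caspofungin"),
    ("heparin", "furosemide"),
    ("pantoprazole", "metoclopramide"),
]


def fixture_kb() -> KnowledgeBase:
    """The bundled multi-source knowledge base.

    Under the default strict-consensus policy it resolves the full answer
    key, classifies exactly the five conflict pairs as not evaluable, and
    marks every named incompatible pair as definitely incompatible (these
    rest on a single database assertion, mirroring the thin evidence base
    typical for IV incompatibility data).
    """
    lex = fixture_lexicon()
    kb = KnowledgeBase(lex)

    for a, b in NAMED_INCOMPATIBLE_PAIRS:
        kb.add(
            CompatibilityAssertion(
                (a, b),
                "STABILIS",
                SourceVerdict.INCOMPATIBLE,
                evidence_note="single analytical study",
            )
        )

    for a, b in NOT_EVALUABLE_PAIRS:
        kb.add(CompatibilityAssertion((a, b), "KIK", SourceVerdict.COMPATIBLE))
        kb.add(CompatibilityAssertion((a, b), "TRISSEL", SourceVerdict.INCOMPATIBLE))

    incompat = set(NAMED_INCOMPATIBLE_PAIRS)
    for iid, a, b, key, *_ in KNOWLEDGE_TABLE:
        pk = pair_key(a, b)
        if key == "COMPATIBLE":
            kb.add(CompatibilityAssertion(pk, "KIK", SourceVerdict.COMPATIBLE))
            kb.add(CompatibilityAssertion(pk, "TRISSEL", SourceVerdict.COMPATIBLE))
        elif pk not in incompat:
            kb.add(CompatibilityAssertion(pk, "KIK", SourceVerdict.INCOMPATIBLE))
            kb.add(CompatibilityAssertion(pk, "TRISSEL", SourceVerdict.INCOMPATIBLE))

    for a, b in _EXTRA_COMPATIBLE:
        if a in lex and b in lex:
            kb.add(CompatibilityAssertion((a, b), "KIK", SourceVerdict.COMPATIBLE))
    return kb


def compatible_pairs(kb: KnowledgeBase) -> set[tuple[str, str]]:
    """Pairs with at least one COMPATIBLE assertion and no INCOMPATIBLE one."""
    verdicts: dict[tuple[str, str], set[SourceVerdict]] = {}
    for (pair, _), a in kb.assertions.items():
        verdicts.setdefault(pair, set()).add(a.verdict)
    return {
        p
        for p, vs in verdicts.items()
        if SourceVerdict.COMPATIBLE in vs and SourceVerdict.INCOMPATIBLE not in vs
    }


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Study-shaped defaults: an admitted cohort in which roughly half the
    patients reach the three-drugs-on-one-lumen inclusion threshold, a
    drugs-per-patient distribution with median 19 (Q25/75 ~ 15.75/23) for
    included patients, a 3-/5-lumen catheter mix, and on average 1.25
    planted incompatible pair occurrences per included patient."""

    n_patients: int = 220
    inclusion_rate: float = 104 / 220
    drugs_median: float = 19.0
    drugs_log_sigma: float = 0.283  # lognormal spread fitting Q25/75 = 15.75/23
    central_fraction: float = 12 / 19
    p_five_lumen: float = 0.3
    continuous_fraction: float = 0.25
    bolus_fraction: float = 0.1
    planted_rate: float = 130 / 104  # Poisson mean per included patient
    horizon: int = 1440
    seed: int = 0

    def validate(self) -> None:
        for name in ("inclusion_rate", "central_fraction", "p_five_lumen",
                     "continuous_fraction", "bolus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.planted_rate < 0:
            raise ValueError("planted_rate must be >= 0")
        if self.horizon < 700:
            raise ValueError("horizon too short for a one-day schedule")
        if self.planted_rate > 0 and self.drugs_median * self.central_fraction < 4:
            raise ValueError("too few central drugs per patient to plant pairs")


@dataclass
class PlantedTruth:
    """Exact by-construction ground truth of a generated cohort."""

    planted: dict[str, list[tuple[int, tuple[str, str]]]]
    max_simultaneous: dict[str, dict[int, int]]
    included: dict[str, bool]

    def planted_multiset(self) -> set[tuple[str, int, tuple[str, str]]]:
        return {
            (pid, lumen, pair)
            for pid, items in self.planted.items()
            for lumen, pair in items
        }

    def to_json(self) -> dict:
        return {
            "planted": {
                pid: [[lumen, list(pair)] for lumen, pair in items]
                for pid, items in self.planted.items()
            },
            "max_simultaneous": {
                pid: {str(l): n for l, n in lumens.items()}
                for pid, lumens in self.max_simultaneous.items()
            },
            "included": dict(self.included),
        }


def _conflicted(kb: KnowledgeBase) -> set[tuple[str, str]]:
    """Pairs that must not co-occur unplanted: incompatible or source-conflicting."""
    bad = set()
    verdicts: dict[tuple[str, str], set[SourceVerdict]] = {}
    for (pair, _), a in kb.assertions.items():
        verdicts.setdefault(pair, set()).add(a.verdict)
    for p, vs in verdicts.items():
        if SourceVerdict.INCOMPATIBLE in vs:
            bad.add(p)
    return bad


def generate_cohort(
    params: CohortParams,
) -> tuple[list[PatientChart], dict[str, CatheterConfig], PlantedTruth]:
    """Seeded, deterministic synthetic ICU cohort.

    Every drug on a lumen overlaps every other drug on that lumen inside a
    common administration window, so the per-lumen concurrent-set size (and
    hence the inclusion decision and every co-administered pair) is known by
    construction.  Planted incompatible pairs are drawn from the fixture
    KB's incompatible set; all other same-lumen pairs are compatible or
    lack data, never incompatible.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    kb = fixture_kb()
    lex_drugs = sorted(kb.lexicon.concepts)
    avoid = _conflicted(kb)
    incompat_list = sorted(NAMED_INCOMPATIBLE_PAIRS)

    charts: list[PatientChart] = []
    catheters: dict[str, CatheterConfig] = {}
    truth = PlantedTruth({}, {}, {})

    for i in range(params.n_patients):
        pid = f"P{i + 1:03d}"
        n_lumens = 5 if rng.random() < params.p_five_lumen else 3
        included = bool(rng.random() < params.inclusion_rate)
        n_drugs = max(4, int(round(float(rng.lognormal(math.log(params.drugs_median),
                                                       params.drugs_log_sigma)))))
        n_central = min(max(3, int(round(params.central_fraction * n_drugs))), len(lex_drugs))
        order = [lex_drugs[j] for j in rng.permutation(len(lex_drugs))]
        central_pool = order[:n_central]
        peripheral_pool = order[n_central:n_central + max(0, n_drugs - n_central)]

        # per-lumen drug sets; all drugs within a lumen will mutually overlap
        lumen_sets: list[list[str]] = [[] for _ in range(n_lumens)]
        caps = [2] * n_lumens
        if included:
            caps[0] = int(rng.integers(3, 6))  # the >=3-drug feeding lumen

        def fits(drug: str, members: list[str]) -> bool:
            return all(pair_key(drug, m) not in avoid for m in members if m != drug)

        planted_here: list[tuple[int, tuple[str, str]]] = []
        if included and params.planted_rate > 0:
            k = int(rng.poisson(params.planted_rate))
            pick = rng.permutation(len(incompat_list))
            used: set[str] = set()
            for idx in pick:
                if len(planted_here) >= k:
                    break
                a, b = incompat_list[idx]
                if a in used or b in used:
                    continue
                for l in range(n_lumens):
                    members = lumen_sets[l]
                    # feeding lumen takes pairs up to its cap; any other
                    # lumen may host one planted pair alone
                    room = (len(members) + 2 <= caps[l]) if l == 0 else not members
                    if room and fits(a, members) and fits(b, members):
                        lumen_sets[l].extend([a, b])
                        planted_here.append((l + 1, pair_key(a, b)))
                        used.update((a, b))
                        break

        # fill remaining drugs as distractors
        placed_drugs = {d for s in lumen_sets for d in s}
        for drug in central_pool:
            if drug in placed_drugs:
                continue
            placed = False
            for l in range(n_lumens):
                if len(lumen_sets[l]) < caps[l] and fits(drug, lumen_sets[l]):
                    lumen_sets[l].append(drug)
                    placed_drugs.add(drug)
                    placed = True
                    break
            if not placed:
                peripheral_pool.append(drug)

        # the inclusion label must match the realized sets
        if included and len(lumen_sets[0]) < 3:
            planted_drugs = {d for _, pair in planted_here for d in pair}
            for l in range(1, n_lumens):  # pull distractors over to lumen 1
                while len(lumen_sets[0]) < 3 and lumen_sets[l]:
                    cand = lumen_sets[l][-1]
                    if cand not in planted_drugs and fits(cand, lumen_sets[0]):
                        lumen_sets[l].pop()
                        lumen_sets[0].append(cand)
                    else:
                        break
            if len(lumen_sets[0]) < 3:
                included = False
                planted_here = []  # unreachable under default params; safety net
        if not included:
            lumen_sets = [s[:2] for s in lumen_sets]

        # schedule: common overlap window [480, 540) per lumen
        events: list[AdministrationEvent] = []
        for l, members in enumerate(lumen_sets, start=1):
            for drug in members:
                r = rng.random()
                if r < params.continuous_fraction:
                    ev = AdministrationEvent(
                        pid, drug, Route.CENTRAL_VENOUS, l, 0, params.horizon,
                        AdminMode.CONTINUOUS,
                    )
                elif r < params.continuous_fraction + params.bolus_fraction:
                    dur = int(rng.integers(5, 11))
                    ev = AdministrationEvent(
                        pid, drug, Route.CENTRAL_VENOUS, l, 500, 500 + dur, AdminMode.BOLUS
                    )
                else:
                    pre = int(rng.integers(0, 61))
                    post = int(rng.integers(0, 61))
                    ev = AdministrationEvent(
                        pid, drug, Route.CENTRAL_VENOUS, l, 480 - pre, 540 + post,
                        AdminMode.INTERMITTENT,
                    )
                events.append(ev)
        for j, drug in enumerate(peripheral_pool):
            start = int(rng.integers(0, params.horizon - 60))
            events.append(
                AdministrationEvent(
                    pid, drug, Route.PERIPHERAL, 1, start, start + 30, AdminMode.INTERMITTENT
                )
            )

        catheter = CatheterConfig(n_lumens=n_lumens)
        charts.append(PatientChart(pid, catheter, events))
        catheters[pid] = catheter
        truth.planted[pid] = sorted(planted_here)
        truth.max_simultaneous[pid] = {
            l: len(members) for l, members in enumerate(lumen_sets, start=1)
        }
        truth.included[pid] = included

    return charts, catheters, truth


# ---------------------------------------------------------------------------
# Survey generator
# ---------------------------------------------------------------------------

def generate_survey(
    items: list[KnowledgeItem] | None = None,
    n_participants: int = N_SURVEY_PARTICIPANTS,
    probabilities: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> list[KnowledgeResponse]:
    """Complete seeded response grid with per-item outcome probabilities.

    ``probabilities`` maps item_id to (p_correct, p_incorrect, p_blank);
    defaults are the published per-item shares.
    """
    items = items if items is not None else knowledge_items()
    probs = probabilities if probabilities is not None else knowledge_probabilities()
    rng = np.random.default_rng(seed)
    out: list[KnowledgeResponse] = []
    for p in range(1, n_participants + 1):
        for it in items:
            pc, pi, pb = probs[it.item_id]
            total = pc + pi + pb
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                pc, pi, pb = pc / total, pi / total, pb / total
            u = rng.random()
            if u < pc:
                ans = it.key
            elif u < pc + pi:
                ans = Answer.INCOMPATIBLE if it.key is Answer.COMPATIBLE else Answer.COMPATIBLE
            else:
                ans = Answer.BLANK
            out.append(KnowledgeResponse(f"p{p:02d}", it.item_id, ans))
    return out
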