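"""Staff-survey scoring: knowledge items and Likert assumption items.

Knowledge items ask whether a drug pair is compatible or incompatible and are
graded against an answer key; per-item results are reported as whole-percent
shares of correct / incorrect / unanswered (half-up rounding).  Assumption
items use a 0-5 Likert scale (0 never ... 5 always) with an optional
"no answer possible" that is excluded from the statistics.

Because published summaries often print percentages rather than raw counts,
:func:`reconstruct_counts` inverts a whole percent back to a count at a known
number of participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .analysis import DEFAULT_QUANTILE_METHOD, round_half_up
from .kb import pair_key


class Answer(str, Enum):
    COMPATIBLE = "COMPATIBLE"
    INCOMPATIBLE = "INCOMPATIBLE"
    BLANK = "BLANK"


@dataclass(frozen=True)
class KnowledgeItem:
    item_id: str
    pair: tuple[str, str]
    key: Answer  # COMPATIBLE or INCOMPATIBLE

    def __post_init__(self):
        object.__setattr__(self, "pair", pair_key(*self.pair))
        if self.key is Answer.BLANK:
            raise ValueError("answer key cannot be BLANK")


@dataclass(frozen=True)
class KnowledgeResponse:
    participant_id: str
    item_id: str
    answer: Answer


NO_ANSWER = None  # sentinel for "no answer possible" on Likert items


@dataclass(frozen=True)
class LikertResponse:
    participant_id: str
    question_id: int
    value: int | None  # 0..5, or None for "no answer possible"

    def __post_init__(self):
        if self.value is not None and not 0 <= self.value <= 5:
            raise ValueError(f"Likert value out of range: {self.value}")


def pct_whole(numerator: int, denominator: int) -> int:
    """Whole-percent share, half-up (published-table style)."""
    if denominator == 0:
        raise ZeroDivisionError("pct_whole: denominator is zero")
    return int(round_half_up(100.0 * numerator / denominator))


def reconstruct_counts(pct: float, n: int) -> int:
    """Invert a printed whole percent to a count at n participants (half-up)."""
    if not 0 <= pct <= 100:
        raise ValueError(f"percent out of range: {pct}")
    if n <= 0:
        raise ValueError("n must be positive")
    return int(round_half_up(pct * n / 100.0))


def score_knowledge(
    responses: Iterable[KnowledgeResponse], items: Sequence[KnowledgeItem]
) -> tuple[pd.DataFrame, dict]:
    """Grade responses against the key.

    Returns a per-item table (counts and whole-percent shares) plus grand
    totals.  A response is correct iff it equals the item's key; BLANK counts
    as unanswered.  Duplicate (participant, item) responses are an error.
    """
    by_item: dict[str, KnowledgeItem] = {it.item_id: it for it in items}
    seen: set[tuple[str, str]] = set()
    tallies = {it.item_id: {"correct": 0, "incorrect": 0, "blank": 0} for it in items}
    for r in responses:
        if r.item_id not in by_item:
            raise KeyError(f"response references unknown item {r.item_id!r}")
        dup_key = (r.participant_id, r.item_id)
        if dup_key in seen:
            raise ValueError(f"duplicate response for participant/item {dup_key}")
        seen.add(dup_key)
        if r.answer is Answer.BLANK:
            tallies[r.item_id]["blank"] += 1
        elif r.answer is by_item[r.item_id].key:
            tallies[r.item_id]["correct"] += 1
        else:
            tallies[r.item_id]["incorrect"] += 1

    rows = []
    for it in items:
        t = tallies[it.item_id]
        n = t["correct"] + t["incorrect"] + t["blank"]
        rows.append(
            {
                "item_id": it.item_id,
                "drug_a": it.pair[0],
                "drug_b": it.pair[1],
                "key": it.key.value,
                "n_correct": t["correct"],
                "n_incorrect": t["incorrect"],
                "n_blank": t["blank"],
                "pct_correct": pct_whole(t["correct"], n) if n else 0,
                "pct_incorrect": pct_whole(t["incorrect"], n) if n else 0,
                "pct_blank": pct_whole(t["blank"], n) if n else 0,
            }
        )
    table = pd.DataFrame(rows)
    totals = {
        "n_responses": int(table[["n_correct", "n_incorrect", "n_blank"]].to_numpy().sum()),
        "n_correct": int(table["n_correct"].sum()),
        "n_incorrect": int(table["n_incorrect"].sum()),
        "n_blank": int(table["n_blank"].sum()),
    }
    return table, totals


def summarize_likert(
    responses: Iterable[LikertResponse],
    *,
    quantile_method: str = DEFAULT_QUANTILE_METHOD,
) -> pd.DataFrame:
    """Per-question median, quartiles, range, and answered-n.

    "No answer possible" responses are excluded; a question with no answered
    responses reports missing statistics (NaN), not zeros.
    """
    by_q: dict[int, list[int]] = {}
    for r in responses:
        by_q.setdefault(r.question_id, [])
        if r.value is not None:
            by_q[r.question_id].append(r.value)
    rows = []
    for q in sorted(by_q):
        vals = np.array(by_q[q], dtype=float)
        if vals.size == 0:
            rows.append(
                {"question": q, "median": np.nan, "q25": np.nan, "q75": np.nan,
                 "min": np.nan, "max": np.nan, "n_answered": 0}
            )
            continue
        q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75], method=quantile_method)
        rows.append(
            {
                "question": q,
                "median": float(med),
                "q25": float(q25),
                "q75": float(q75),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n_answered": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def responses_from_counts(
    items: Sequence[KnowledgeItem], counts: Mapping[str, tuple[int, int, int]]
) -> list[KnowledgeResponse]:
    """Deterministic response grid realizing (correct, incorrect, blank) counts.

    Participants are labelled p01, p02, ... per item in key order; used to
    materialize a response set from published per-item tallies.
    """
    out = []
    for it in items:
        n_c, n_i, n_b = counts[it.item_id]
        wrong = (
            Answer.INCOMPATIBLE if it.key is Answer.COMPATIBLE else Answer.COMPATIBLE
        )
        seq = [it.key] * n_c + [wrong] * n_i + [Answer.BLANK] * n_b
        for j, ans in enumerate(seq, start=1):
            out.append(KnowledgeResponse(f"p{j:02d}", it.item_id, ans))
    return out
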