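"""Multi-source verdict resolution for one drug pair.

Each evidence source answers COMPATIBLE, INCOMPATIBLE, CONFLICTING_WITHIN_SOURCE
or NO_DATA for an unordered pair.  This module maps those four answers to a
single final classification — compatible, incompatible, or *not evaluable* —
with an auditable trail of everything consulted.

Two policy modes are provided:

``STRICT_CONSENSUS`` (default)
    All data-bearing sources must agree.  Disagreement between data-bearing
    sources is never overridden — the pair is not evaluable (reason CONFLICT).
    A source that contradicts itself (CONFLICTING_WITHIN_SOURCE) also forces
    CONFLICT, *unless* ``incompatible_dominates`` is on and every data-bearing
    source says INCOMPATIBLE: a safety tool should fail toward "incompatible"
    when the only counter-signal is a self-contradictory source.

``PRECEDENCE_FIRST``
    The first data-bearing source in ``source_order`` decides outright.

Both modes are symmetric in the pair and pure functions of (kb, pair, policy).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .kb import (
    BUILTIN_SOURCES,
    KBError,
    KnowledgeBase,
    SourceVerdict,
    pair_key,
    validate_source,
)


class Classification(str, Enum):
    COMPATIBLE = "COMPATIBLE"
    INCOMPATIBLE = "INCOMPATIBLE"
    NOT_EVALUABLE = "NOT_EVALUABLE"


class Reason(str, Enum):
    AGREEMENT = "AGREEMENT"
    SINGLE_SOURCE = "SINGLE_SOURCE"
    CONFLICT = "CONFLICT"
    NO_DATA = "NO_DATA"


@dataclass(frozen=True)
class TrailEntry:
    source: str
    verdict: SourceVerdict
    used: bool  # False for consulted-but-unused entries (PRECEDENCE_FIRST)


@dataclass(frozen=True)
class Verdict:
    """Resolved classification of a pair plus the evidence trail."""

    classification: Classification
    reason: Reason
    trail: tuple[TrailEntry, ...]

    def __post_init__(self):
        not_eval = self.classification is Classification.NOT_EVALUABLE
        if not_eval != (self.reason in (Reason.CONFLICT, Reason.NO_DATA)):
            raise ValueError(f"inconsistent verdict: {self.classification}/{self.reason}")
        if not self.trail:
            raise ValueError("verdict trail must be nonempty")

    @property
    def is_incompatible(self) -> bool:
        return self.classification is Classification.INCOMPATIBLE


class Mode(str, Enum):
    STRICT_CONSENSUS = "STRICT_CONSENSUS"
    PRECEDENCE_FIRST = "PRECEDENCE_FIRST"


@dataclass(frozen=True)
class ResolutionPolicy:
    source_order: tuple[str, ...] = BUILTIN_SOURCES
    mode: Mode = Mode.STRICT_CONSENSUS
    incompatible_dominates: bool = True

    def __post_init__(self):
        order = tuple(validate_source(s) for s in self.source_order)
        if len(set(order)) != len(order):
            raise KBError(f"duplicate sources in policy order: {order}")
        object.__setattr__(self, "source_order", order)
        object.__setattr__(self, "mode", Mode(self.mode))


DEFAULT_POLICY = ResolutionPolicy()

_DATA_BEARING = (SourceVerdict.COMPATIBLE, SourceVerdict.INCOMPATIBLE)


def resolve_verdicts(
    verdicts: Sequence[SourceVerdict], policy: ResolutionPolicy = DEFAULT_POLICY
) -> Verdict:
    """Resolve a tuple of per-source verdicts given in ``policy.source_order``."""
    if len(verdicts) != len(policy.source_order):
        raise KBError("one verdict per source in policy order is required")

    data = [(s, v) for s, v in zip(policy.source_order, verdicts) if v in _DATA_BEARING]
    has_self_conflict = any(v is SourceVerdict.CONFLICTING_WITHIN_SOURCE for v in verdicts)

    if policy.mode is Mode.PRECEDENCE_FIRST:
        used = data[0][0] if data else None
        trail = tuple(
            TrailEntry(s, v, used=(s == used))
            for s, v in zip(policy.source_order, verdicts)
        )
        if data:
            cls = Classification(data[0][1].value)
            return Verdict(cls, Reason.SINGLE_SOURCE, trail)
        reason = Reason.CONFLICT if has_self_conflict else Reason.NO_DATA
        return Verdict(Classification.NOT_EVALUABLE, reason, trail)

    trail = tuple(TrailEntry(s, v, used=True) for s, v in zip(policy.source_order, verdicts))
    if not data:
        reason = Reason.CONFLICT if has_self_conflict else Reason.NO_DATA
        return Verdict(Classification.NOT_EVALUABLE, reason, trail)

    classes = {v for _, v in data}
    if len(classes) > 1:
        # data-bearing sources genuinely disagree
        return Verdict(Classification.NOT_EVALUABLE, Reason.CONFLICT, trail)

    agreed = data[0][1]
    reason = Reason.SINGLE_SOURCE if len(data) == 1 else Reason.AGREEMENT
    if has_self_conflict:
        if policy.incompatible_dominates and agreed is SourceVerdict.INCOMPATIBLE:
            return Verdict(Classification.INCOMPATIBLE, reason, trail)
        return Verdict(Classification.NOT_EVALUABLE, Reason.CONFLICT, trail)
    return Verdict(Classification(agreed.value), reason, trail)


def resolve_pair(
    kb: KnowledgeBase, a: str, b: str, policy: ResolutionPolicy = DEFAULT_POLICY
) -> Verdict:
    """Resolve one unordered drug pair against the knowledge base.

    Deterministic and symmetric in (a, b); unknown drugs raise through lookup.
    """
    pair_key(a, b)  # validates a != b
    for drug in (a, b):
        if drug not in kb.lexicon:
            raise KBError(f"drug not in lexicon: {drug!r}")
    verdicts = tuple(kb.lookup(a, b, s) for s in policy.source_order)
    return resolve_verdicts(verdicts, policy)


def classify_policy_table(
    policy: ResolutionPolicy = DEFAULT_POLICY,
) -> dict[tuple[SourceVerdict, ...], Verdict]:
    """Exhaustive truth table over all source-verdict tuples (audit aid)."""
    table = {}
    for combo in itertools.product(list(SourceVerdict), repeat=len(policy.source_order)):
        table[combo] = resolve_verdicts(combo, policy)
    return table
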