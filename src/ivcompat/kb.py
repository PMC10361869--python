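"""Open storage model for multi-source IV compatibility evidence.

A :class:`KnowledgeBase` holds, for every unordered drug pair and every
evidence source, at most one :class:`CompatibilityAssertion`.  Sources are
modelled abstractly (two commercial compatibility databases, the drug label,
and a standard handbook) so that the same resolution machinery works for any
registry of sources.  Drug names are normalized against an explicit lexicon;
matching is exact after case-folding and whitespace collapse — no fuzzy
matching, because a silent mismatch in a medication-safety context is worse
than a hard error.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class KBError(ValueError):
    """Base class for knowledge-base validation errors."""


class UnknownDrugError(KBError):
    def __init__(self, raw: str):
        super().__init__(f"unknown drug: {raw!r}")
        self.raw = raw


class AmbiguousDrugError(KBError):
    def __init__(self, raw: str, candidates: Iterable[str]):
        cands = sorted(candidates)
        super().__init__(f"ambiguous drug name {raw!r}: matches {cands}")
        self.raw = raw
        self.candidates = cands


class DuplicateAssertionError(KBError):
    """Two input rows assert different verdicts for the same (pair, source)."""


class SourceVerdict(str, Enum):
    """What a single source says about one drug pair.

    ``NO_DATA`` is the implicit verdict of any absent assertion;
    ``CONFLICTING_WITHIN_SOURCE`` records a source that contradicts itself
    (e.g. different monographs of the same database disagree).
    """

    COMPATIBLE = "COMPATIBLE"
    INCOMPATIBLE = "INCOMPATIBLE"
    CONFLICTING_WITHIN_SOURCE = "CONFLICTING_WITHIN_SOURCE"
    NO_DATA = "NO_DATA"


#: Built-in evidence sources, in default precedence order.
BUILTIN_SOURCES = ("KIK", "STABILIS", "SMPC", "TRISSEL")

# source name -> precedence rank (lower = consulted earlier by default)
_SOURCE_REGISTRY: dict[str, int] = {s: i for i, s in enumerate(BUILTIN_SOURCES)}


def register_source(name: str, precedence: int) -> None:
    """Register a custom evidence source with an explicit precedence rank."""
    name = name.strip().upper()
    if not name:
        raise KBError("source name must be nonempty")
    _SOURCE_REGISTRY[name] = int(precedence)


def known_sources() -> tuple[str, ...]:
    return tuple(sorted(_SOURCE_REGISTRY, key=lambda s: (_SOURCE_REGISTRY[s], s)))


def validate_source(name: str) -> str:
    name = name.strip().upper()
    if name not in _SOURCE_REGISTRY:
        raise KBError(f"unknown source {name!r}; known: {known_sources()}")
    return name


_WS = re.compile(r"\s+")


def _normtext(raw: str) -> str:
    return _WS.sub(" ", raw.strip()).casefold()


@dataclass(frozen=True)
class DrugConcept:
    """One infusate concept: a drug, electrolyte, carrier or nutrition product.

    Combination products (e.g. piperacillin/tazobactam) are single concepts,
    never decomposed into components, because compatibility evidence is
    reported for the marketed combination.
    """

    canonical_name: str
    synonyms: frozenset[str] = frozenset()
    class_tags: frozenset[str] = frozenset()
    is_combination_product: bool = False

    def __post_init__(self):
        if not self.canonical_name or _normtext(self.canonical_name) != self.canonical_name:
            raise KBError(
                f"canonical name must be nonempty and normalized: {self.canonical_name!r}"
            )


class Lexicon:
    """Set of :class:`DrugConcept` with a name -> concept resolution index."""

    def __init__(self, concepts: Iterable[DrugConcept]):
        self.concepts: dict[str, DrugConcept] = {}
        self._index: dict[str, str] = {}  # normalized name/synonym -> canonical
        for c in concepts:
            self._add(c)

    def _add(self, c: DrugConcept) -> None:
        if c.canonical_name in self.concepts:
            raise KBError(f"duplicate concept {c.canonical_name!r}")
        names = {c.canonical_name} | {_normtext(s) for s in c.synonyms}
        for n in names:
            if n in self._index and self._index[n] != c.canonical_name:
                raise KBError(
                    f"name {n!r} maps to both {self._index[n]!r} and {c.canonical_name!r}"
                )
        self.concepts[c.canonical_name] = c
        for n in names:
            self._index[n] = c.canonical_name

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[DrugConcept]:
        return iter(self.concepts.values())

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.concepts

    def resolve(self, raw: str) -> str:
        """Return the canonical name for ``raw`` or raise."""
        if not self.concepts:
            raise KBError("lexicon is empty")
        key = _normtext(raw)
        try:
            return self._index[key]
        except KeyError:
            raise UnknownDrugError(raw) from None


def normalize_drug_name(raw: str, lexicon: Lexicon) -> str:
    """Map a raw drug name to its canonical lexicon name.

    Matching is exact after case-folding, trimming and internal-whitespace
    collapse; unknown names raise :class:`UnknownDrugError`.
    """
    return lexicon.resolve(raw)


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Order-independent key for an unordered drug pair; rejects self-pairs."""
    if a == b:
        raise KBError(f"pair of a drug with itself is undefined: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CompatibilityAssertion:
    """One source's verdict about one unordered drug pair, with provenance."""

    pair: tuple[str, str]
    source: str
    verdict: SourceVerdict
    evidence_note: str = ""
    citation: str = ""

    def __post_init__(self):
        object.__setattr__(self, "pair", pair_key(*self.pair))
        object.__setattr__(self, "source", validate_source(self.source))


class KnowledgeBase:
    """Lexicon plus one assertion per (unordered pair, source)."""

    def __init__(self, lexicon: Lexicon, assertions: Iterable[CompatibilityAssertion] = ()):
        self.lexicon = lexicon
        self.assertions: dict[tuple[tuple[str, str], str], CompatibilityAssertion] = {}
        for a in assertions:
            self.add(a)

    def add(self, assertion: CompatibilityAssertion) -> None:
        for drug in assertion.pair:
            if drug not in self.lexicon:
                raise UnknownDrugError(drug)
        key = (assertion.pair, assertion.source)
        existing = self.assertions.get(key)
        if existing is not None and existing.verdict is not assertion.verdict:
            raise DuplicateAssertionError(
                f"conflicting duplicate for pair {assertion.pair} source {assertion.source}: "
                f"{existing.verdict.value} vs {assertion.verdict.value}"
            )
        self.assertions[key] = assertion

    def lookup(self, a: str, b: str, source: str) -> SourceVerdict:
        """Stored verdict for the pair under ``source``, else ``NO_DATA``."""
        key = (pair_key(a, b), validate_source(source))
        stored = self.assertions.get(key)
        return stored.verdict if stored is not None else SourceVerdict.NO_DATA

    def pairs(self) -> set[tuple[str, str]]:
        return {pair for pair, _ in self.assertions}


def lookup(kb: KnowledgeBase, a: str, b: str, source: str) -> SourceVerdict:
    return kb.lookup(a, b, source)


# ---------------------------------------------------------------------------
# Serialization.  CSV dialect: UTF-8, comma separated, header
#   drug_a,drug_b,source,verdict,evidence_note,citation
# Lexicon CSV: canonical_name,synonyms(;-separated),class_tags(;-separated),is_combination
# JSON: one object with "lexicon" and "assertions" arrays.
# ---------------------------------------------------------------------------

KB_CSV_HEADER = ["drug_a", "drug_b", "source", "verdict", "evidence_note", "citation"]
LEXICON_CSV_HEADER = ["canonical_name", "synonyms", "class_tags", "is_combination"]


def _parse_verdict(token: str) -> SourceVerdict:
    try:
        return SourceVerdict(token.strip().upper())
    except ValueError:
        raise KBError(f"unknown verdict token {token!r}") from None


def save_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(LEXICON_CSV_HEADER)
        for c in sorted(lexicon, key=lambda c: c.canonical_name):
            w.writerow(
                [
                    c.canonical_name,
                    ";".join(sorted(c.synonyms)),
                    ";".join(sorted(c.class_tags)),
                    "1" if c.is_combination_product else "0",
                ]
            )


def load_lexicon(path: str | Path) -> Lexicon:
    concepts = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            concepts.append(
                DrugConcept(
                    canonical_name=_normtext(row["canonical_name"]),
                    synonyms=frozenset(s for s in row.get("synonyms", "").split(";") if s),
                    class_tags=frozenset(t for t in row.get("class_tags", "").split(";") if t),
                    is_combination_product=row.get("is_combination", "0").strip() in ("1", "true"),
                )
            )
    return Lexicon(concepts)


def _concept_to_json(c: DrugConcept) -> dict:
    return {
        "canonical_name": c.canonical_name,
        "synonyms": sorted(c.synonyms),
        "class_tags": sorted(c.class_tags),
        "is_combination_product": c.is_combination_product,
    }


def save_kb(kb: KnowledgeBase, path: str | Path, format: str = "csv") -> None:
    """Write the assertion set (``csv``) or the full KB (``json``)."""
    path = Path(path)
    ordered = sorted(kb.assertions.values(), key=lambda a: (a.pair, a.source))
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(KB_CSV_HEADER)
            for a in ordered:
                w.writerow([*a.pair, a.source, a.verdict.value, a.evidence_note, a.citation])
    elif format == "json":
        doc = {
            "lexicon": [_concept_to_json(c) for c in sorted(kb.lexicon, key=lambda c: c.canonical_name)],
            "assertions": [
                {
                    "drug_a": a.pair[0],
                    "drug_b": a.pair[1],
                    "source": a.source,
                    "verdict": a.verdict.value,
                    "evidence_note": a.evidence_note,
                    "citation": a.citation,
                }
                for a in ordered
            ],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    else:
        raise KBError(f"unknown KB format {format!r}")


def _rows_to_kb(rows: Iterable[Mapping[str, str]], lexicon: Lexicon, origin: str) -> KnowledgeBase:
    kb = KnowledgeBase(lexicon)
    seen: dict[tuple[tuple[str, str], str], tuple[int, SourceVerdict]] = {}
    for i, row in enumerate(rows, start=2):  # 1-based, header is row 1
        a = normalize_drug_name(row["drug_a"], lexicon)
        b = normalize_drug_name(row["drug_b"], lexicon)
        source = validate_source(row["source"])
        verdict = _parse_verdict(row["verdict"])
        key = (pair_key(a, b), source)
        if key in seen and seen[key][1] is not verdict:
            raise DuplicateAssertionError(
                f"{origin}: rows {seen[key][0]} and {i} assert different verdicts "
                f"({seen[key][1].value} vs {verdict.value}) for pair {key[0]} source {source}"
            )
        seen[key] = (i, verdict)
        kb.add(
            CompatibilityAssertion(
                pair=(a, b),
                source=source,
                verdict=verdict,
                evidence_note=row.get("evidence_note", "") or "",
                citation=row.get("citation", "") or "",
            )
        )
    return kb


def load_kb(
    path: str | Path,
    format: str = "csv",
    lexicon: Lexicon | None = None,
) -> KnowledgeBase:
    """Load a knowledge base.

    CSV holds assertions only and requires ``lexicon``; JSON embeds the
    lexicon.  Assertions with the pair written in either order collapse to a
    single key; contradictory duplicates are a hard error naming both rows.
    """
    path = Path(path)
    if format == "csv":
        if lexicon is None:
            raise KBError("loading a CSV knowledge base requires a lexicon")
        with open(path, newline="", encoding="utf-8") as fh:
            return _rows_to_kb(csv.DictReader(fh), lexicon, str(path))
    if format == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        lex = Lexicon(
            DrugConcept(
                canonical_name=c["canonical_name"],
                synonyms=frozenset(c.get("synonyms", ())),
                class_tags=frozenset(c.get("class_tags", ())),
                is_combination_product=bool(c.get("is_combination_product", False)),
            )
            for c in doc["lexicon"]
        )
        return _rows_to_kb(doc["assertions"], lex, str(path))
    raise KBError(f"unknown KB format {format!r}")
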