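"""Domain types and file I/O for documents, dictionaries, gold relations,
and ranked relation lists.

The on-disk formats mirror the plain-text downloads of curated
pharmacogenomics / toxicogenomics knowledge bases (PharmGKB- and CTD-style):

* documents: JSON-lines, one abstract record per line with fields
  ``doc_id``, ``title``, ``abstract``, ``mesh``, ``chemicals``;
* term dictionary: TSV ``surface <TAB> entity_id <TAB> type``;
* gold relations: TSV ``doc_id <TAB> id1 <TAB> type1 <TAB> id2 <TAB> type2``;
* ranked output: BioCreative-PPI-style TSV
  ``doc_id <TAB> id1 <TAB> id2 <TAB> rank <TAB> score``.

Entity identity is the pair (id string, type): the same id string under two
types denotes two distinct entities, matching the typed id spaces of the
source databases.  The CTD type "chemical" is represented as ``drug``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)


class RelrankError(Exception):
    """Base class for errors raised by this package."""


class ParseError(RelrankError):
    """A malformed input line; the message names the offending line number."""


class ValidationError(RelrankError):
    """Structurally valid input that violates a domain invariant."""


class ConfigurationError(RelrankError):
    """Inconsistent settings, e.g. ME scoring requested without a model."""


class EntityType(str, Enum):
    """Closed set of entity types handled by the ranker."""

    DISEASE = "disease"
    DRUG = "drug"
    GENE = "gene"

    @classmethod
    def parse(cls, code: str) -> "EntityType":
        # "chemical" (CTD vocabulary) is folded into drug
        if code == "chemical":
            return cls.DRUG
        try:
            return cls(code)
        except ValueError:
            raise ValidationError(
                f"unknown entity type {code!r}; expected one of "
                f"{[t.value for t in cls]} (or 'chemical' as an alias of 'drug')"
            ) from None


@dataclass(frozen=True, order=True)
class EntityId:
    """A typed entity identifier; (id, type) is the unit of identity."""

    id: str
    type: EntityType

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("entity id must be non-empty")

    def __str__(self) -> str:  # used for canonical pair ordering
        return f"{self.id}:{self.type.value}"


@dataclass(frozen=True)
class TermEntry:
    """One dictionary row: a surface form admitting an entity.

    A surface may map to several entities (ambiguity is preserved).
    """

    surface: str
    entity: EntityId

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValidationError("term surface must be non-empty")


class Zone(str, Enum):
    """Document region a term hit was found in; only title hits are boosted."""

    TITLE = "title"
    ABSTRACT = "abstract"
    MESH = "mesh"
    CHEMICALS = "chemicals"


@dataclass
class Document:
    """One abstract record with its metadata zones."""

    doc_id: str
    title: str
    abstract: str
    mesh: list[tuple[str, list[str]]] = field(default_factory=list)
    chemicals: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GoldRelation:
    """An undirected typed entity pair curated for a document."""

    doc_id: str
    e1: EntityId
    e2: EntityId

    def __post_init__(self) -> None:
        if self.e1 == self.e2:
            raise ValidationError("reflexive gold relation")
        # canonical order so that (e1,e2) == (e2,e1)
        if str(self.e2) < str(self.e1):
            first, second = self.e2, self.e1
            object.__setattr__(self, "e1", first)
            object.__setattr__(self, "e2", second)

    @property
    def pair(self) -> tuple[EntityId, EntityId]:
        return (self.e1, self.e2)


class GoldRelationSet:
    """Gold relations indexed by document, with the gold(A, e) predicate.

    ``gold(A, e)`` is true iff entity ``e`` occurs in at least one curated
    relation of document ``A``.
    """

    def __init__(self, relations: Iterable[GoldRelation] = ()) -> None:
        self._by_doc: dict[str, set[GoldRelation]] = {}
        self._entities_by_doc: dict[str, set[EntityId]] = {}
        for rel in relations:
            self.add(rel)

    def add(self, rel: GoldRelation) -> None:
        self._by_doc.setdefault(rel.doc_id, set()).add(rel)
        ents = self._entities_by_doc.setdefault(rel.doc_id, set())
        ents.add(rel.e1)
        ents.add(rel.e2)

    def relations(self, doc_id: str) -> frozenset[GoldRelation]:
        return frozenset(self._by_doc.get(doc_id, ()))

    def pairs(self, doc_id: str) -> frozenset[frozenset[EntityId]]:
        """Unordered gold pairs of a document, for metric computation."""
        return frozenset(
            frozenset((r.e1, r.e2)) for r in self._by_doc.get(doc_id, ())
        )

    def gold(self, doc_id: str, entity: EntityId) -> bool:
        return entity in self._entities_by_doc.get(doc_id, ())

    def contains(self, doc_id: str, e1: EntityId, e2: EntityId) -> bool:
        if e1 == e2:
            return False
        return GoldRelation(doc_id, e1, e2) in self._by_doc.get(doc_id, set())

    def doc_ids(self) -> list[str]:
        return sorted(self._by_doc)

    def n_relations(self, doc_id: str) -> int:
        return len(self._by_doc.get(doc_id, ()))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_doc.values())

    def __iter__(self) -> Iterator[GoldRelation]:
        for doc_id in sorted(self._by_doc):
            yield from sorted(
                self._by_doc[doc_id], key=lambda r: (str(r.e1), str(r.e2))
            )


@dataclass
class Settings:
    """Experimental configuration of the ranking pipeline.

    The short grammar ``zones-e-r-m[-n-c-s]`` (e.g. ``tmc-e1-r1-m1-n3-c6-s1``)
    maps onto these fields; ``norm``/``cap``/``smooth`` only influence the
    maximum-entropy method ``m1`` and are inert under the frequency baseline
    ``m0``.
    """

    zones: str = "t"          # t | tm | tc | tmc
    type_pref: str = "e0"     # e0 (off) | e1 (penalize same-type pairs)
    rel_score: str = "r0"     # r0 (sum) | r1 (harmonic mean)
    method: str = "m0"        # m0 (frequency baseline) | m1 (ME-weighted)
    norm: str = "n0"          # term-form normalization level n0..n3
    cap: str = "c0"           # count cap c0 (none) | c1 | c3 | c6 | c9
    smooth: str = "s0"        # s0 (off) | s1 (lower-count smoothing features)
    title_boost: float = 10.0
    same_type_coeff: float = 0.1
    cutoff: int = 50
    tap_k: int = 10

    _ZONES = ("t", "tm", "tc", "tmc")
    _CAPS = {"c0": None, "c1": 1, "c3": 3, "c6": 6, "c9": 9}

    def __post_init__(self) -> None:
        if self.zones not in self._ZONES:
            raise ValidationError(f"zones must be one of {self._ZONES}")
        if self.type_pref not in ("e0", "e1"):
            raise ValidationError("type_pref must be e0 or e1")
        if self.rel_score not in ("r0", "r1"):
            raise ValidationError("rel_score must be r0 or r1")
        if self.method not in ("m0", "m1"):
            raise ValidationError("method must be m0 or m1")
        if self.norm not in ("n0", "n1", "n2", "n3"):
            raise ValidationError("norm must be one of n0..n3")
        if self.cap not in self._CAPS:
            raise ValidationError("cap must be one of c0,c1,c3,c6,c9")
        if self.smooth not in ("s0", "s1"):
            raise ValidationError("smooth must be s0 or s1")
        if self.title_boost <= 0:
            raise ValidationError("title_boost must be positive")
        if not (0 < self.same_type_coeff <= 1):
            raise ValidationError("same_type_coeff must be in (0, 1]")
        if self.cutoff < 1 or self.tap_k < 1:
            raise ValidationError("cutoff and tap_k must be positive")

    @property
    def cap_value(self) -> int | None:
        return self._CAPS[self.cap]

    @property
    def active_zones(self) -> frozenset[Zone]:
        zones = {Zone.TITLE, Zone.ABSTRACT}
        if "m" in self.zones:
            zones.add(Zone.MESH)
        if "c" in self.zones[1:]:
            zones.add(Zone.CHEMICALS)
        return frozenset(zones)

    def label(self) -> str:
        return "-".join(
            (self.zones, self.type_pref, self.rel_score, self.method,
             self.norm, self.cap, self.smooth)
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_documents(path: str | Path) -> list[Document]:
    """Load a JSON-lines document collection, preserving file order.

    Raises :class:`ParseError` on a malformed line and
    :class:`ValidationError` on duplicate document ids.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                doc = Document(
                    doc_id=str(rec["doc_id"]),
                    title=str(rec.get("title", "")),
                    abstract=str(rec.get("abstract", "")),
                    mesh=[(str(d), [str(q) for q in quals])
                          for d, quals in rec.get("mesh", [])],
                    chemicals=[str(c) for c in rec.get("chemicals", [])],
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: malformed record on line {lineno}: {exc}")
            if doc.doc_id in seen:
                raise ValidationError(
                    f"{path}: duplicate doc_id {doc.doc_id!r} on line {lineno}"
                )
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {
                "doc_id": doc.doc_id,
                "title": doc.title,
                "abstract": doc.abstract,
                "mesh": [[d, q] for d, q in doc.mesh],
                "chemicals": doc.chemicals,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_dictionary(path: str | Path) -> list[TermEntry]:
    """Load a three-column TSV term dictionary (surface, id, type)."""
    entries: list[TermEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(
                    f"{path}: expected 3 tab-separated columns on line {lineno}, "
                    f"got {len(cols)}"
                )
            surface, ent_id, type_code = cols
            if not surface:
                raise ValidationError(f"{path}: empty surface on line {lineno}")
            entries.append(
                TermEntry(surface, EntityId(ent_id, EntityType.parse(type_code)))
            )
    return entries


def write_dictionary(entries: Iterable[TermEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for entry in entries:
            fh.write(
                f"{entry.surface}\t{entry.entity.id}\t{entry.entity.type.value}\n"
            )


def read_gold_relations(path: str | Path) -> GoldRelationSet:
    """Load a five-column TSV of curated relations.

    Reflexive records (both typed ids equal) are dropped — the source
    databases contain a handful of relations between identical concepts —
    and the drop count is logged.  Duplicates of an unordered pair collapse
    silently.
    """
    gold = GoldRelationSet()
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(
                    f"{path}: expected 5 tab-separated columns on line {lineno}, "
                    f"got {len(cols)}"
                )
            doc_id, id1, t1, id2, t2 = cols
            e1 = EntityId(id1, EntityType.parse(t1))
            e2 = EntityId(id2, EntityType.parse(t2))
            if e1 == e2:
                dropped += 1
                continue
            gold.add(GoldRelation(doc_id, e1, e2))
    if dropped:
        logger.info("dropped %d reflexive gold relation(s) from %s", dropped, path)
    gold.reflexive_dropped = dropped  # type: ignore[attr-defined]
    return gold


def write_gold_relations(gold: GoldRelationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rel in gold:
            fh.write(
                f"{rel.doc_id}\t{rel.e1.id}\t{rel.e1.type.value}"
                f"\t{rel.e2.id}\t{rel.e2.type.value}\n"
            )


def write_ranked_relations(
    ranked: Mapping[str, Sequence["ScoredPairLike"]], path: str | Path
) -> None:
    """Write per-document scored pairs as a BioCreative-PPI-style TSV.

    ``ranked`` maps doc_id to a rank-sorted sequence of objects with
    ``pair`` (two EntityIds in canonical order), ``score`` and ``rank``
    attributes.  Pair ids are emitted in lexicographic order; non-finite
    scores are rejected.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id in ranked:
            rows = sorted(ranked[doc_id], key=lambda sr: sr.rank)
            for expected_rank, sr in enumerate(rows, start=1):
                pair = (
                    (sr.pair.e1, sr.pair.e2)
                    if hasattr(sr.pair, "e1")
                    else tuple(sr.pair)
                )
                if not math.isfinite(sr.score):
                    raise ValidationError(
                        f"non-finite score for {doc_id} pair "
                        f"{pair[0]}/{pair[1]}"
                    )
                if sr.rank != expected_rank:
                    raise ValidationError(
                        f"ranks for {doc_id} are not contiguous from 1"
                    )
                a, b = sorted(pair, key=str)
                fh.write(
                    f"{doc_id}\t{a.id}:{a.type.value}\t{b.id}:{b.type.value}"
                    f"\t{sr.rank}\t{sr.score!r}\n"
                )


def read_ranked_relations(
    path: str | Path,
) -> dict[str, list[tuple[EntityId, EntityId, int, float]]]:
    """Inverse of :func:`write_ranked_relations` (used for round-trips)."""
    out: dict[str, list[tuple[EntityId, EntityId, int, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ParseError(
                    f"{path}: expected 5 columns on line {lineno}, got {len(cols)}"
                )
            doc_id, a, b, rank, score = cols
            id1, t1 = a.rsplit(":", 1)
            id2, t2 = b.rsplit(":", 1)
            out.setdefault(doc_id, []).append(
                (
                    EntityId(id1, EntityType.parse(t1)),
                    EntityId(id2, EntityType.parse(t2)),
                    int(rank),
                    float(score),
                )
            )
    return out
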