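"""Per-document entity statistics and candidate relation pairs.

An :class:`EntityProfile` aggregates, for one entity ``e`` in one document,
the raw occurrence count ``f(t:e)`` of each normalized term form ``t`` and
the title-boosted counts ``f_b(t:e)`` (a title hit counts ``boost`` times,
any other hit once).  ``f(E)`` — the document total of boosted entity
counts — normalizes the frequency-baseline relation score; because it is
constant within a document it never changes the within-document ranking.

Candidates are all pairwise undirected combinations of distinct recognized
entities: the maximal-recall strategy, which overgenerates heavily and is
what makes ranking necessary.  An optional same-sentence co-occurrence
filter is provided; it is off by default because a large share of curated
relations never co-occur within one sentence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_model import EntityId, ValidationError, Zone
from .term_recognition import TermHit, normalize_term_form


@dataclass
class EntityProfile:
    """Raw and boosted per-term-form counts of one entity in one document."""

    entity: EntityId
    per_term_counts: dict[str, int] = field(default_factory=dict)
    boosted_per_term: dict[str, float] = field(default_factory=dict)

    @property
    def raw_total(self) -> int:
        """f(e): total raw occurrence count."""
        return sum(self.per_term_counts.values())

    @property
    def boosted_total(self) -> float:
        """f_b(e): total boosted occurrence count."""
        return sum(self.boosted_per_term.values())


@dataclass
class DocumentProfile:
    doc_id: str
    profiles: dict[EntityId, EntityProfile] = field(default_factory=dict)

    @property
    def total_entity_count(self) -> float:
        """f(E): sum of boosted totals over all entities of the document."""
        return sum(p.boosted_total for p in self.profiles.values())


@dataclass(frozen=True)
class CandidatePair:
    """An undirected candidate relation, stored in canonical id order."""

    e1: EntityId
    e2: EntityId
    doc_id: str = ""

    def __post_init__(self) -> None:
        if self.e1 == self.e2:
            raise ValidationError("candidate pair must join distinct entities")
        if str(self.e2) < str(self.e1):
            first, second = self.e2, self.e1
            object.__setattr__(self, "e1", first)
            object.__setattr__(self, "e2", second)

    @property
    def key(self) -> frozenset[EntityId]:
        return frozenset((self.e1, self.e2))


def collect_entity_profiles(
    hits: Sequence[TermHit], boost: float = 10.0, norm: str = "n0"
) -> DocumentProfile:
    """Aggregate hits of one document into per-entity term-form counts.

    Each hit contributes 1 to the raw count of its normalized surface;
    title-zone hits contribute ``boost`` to the boosted count, all other
    zones contribute 1.
    """
    if boost <= 0:
        raise ValidationError("boost must be positive")
    doc_id = hits[0].doc_id if hits else ""
    profile = DocumentProfile(doc_id=doc_id)
    for hit in hits:
        ep = profile.profiles.get(hit.entity)
        if ep is None:
            ep = profile.profiles[hit.entity] = EntityProfile(hit.entity)
        t = normalize_term_form(hit.surface, norm)
        ep.per_term_counts[t] = ep.per_term_counts.get(t, 0) + 1
        weight = boost if hit.zone is Zone.TITLE else 1.0
        ep.boosted_per_term[t] = ep.boosted_per_term.get(t, 0.0) + weight
    return profile


def generate_candidates(profile: DocumentProfile) -> set[CandidatePair]:
    """All unordered pairs of distinct recognized entities of a document."""
    entities = sorted(
        (e for e, p in profile.profiles.items() if p.boosted_total > 0), key=str
    )
    return {
        CandidatePair(entities[i], entities[j], profile.doc_id)
        for i in range(len(entities))
        for j in range(i + 1, len(entities))
    }


def same_sentence_filter(
    pairs: Iterable[CandidatePair], hits: Sequence[TermHit]
) -> set[CandidatePair]:
    """Keep pairs whose entities co-occur in at least one sentence.

    The title counts as a single sentence; metadata zones (MeSH, chemical
    list) have no sentence structure and are excluded.
    """
    by_sentence: dict[tuple[Zone, int], set[EntityId]] = {}
    for hit in hits:
        if hit.zone in (Zone.MESH, Zone.CHEMICALS):
            continue
        sent = 0 if hit.zone is Zone.TITLE else hit.sentence_index
        by_sentence.setdefault((hit.zone, sent), set()).add(hit.entity)
    kept: set[CandidatePair] = set()
    for pair in pairs:
        for entities in by_sentence.values():
            if pair.e1 in entities and pair.e2 in entities:
                kept.add(pair)
                break
    return kept
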