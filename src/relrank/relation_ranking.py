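"""Entity and relation scoring, and per-document candidate ranking.

Two methods are supported.  The frequency baseline (``m0``) scores a pair
by summed boosted entity frequencies normalized by the document's total
entity count:

    relscore(e1, e2) = (f_b(e1) + f_b(e2)) / f(E)

The maximum-entropy weighted method (``m1``) replaces raw frequencies by
probability-weighted sums over the entity's term forms:

    score(e) = sum_t f_b(t:e) * P(gold(A, e) = 1 | e, t, f^c(t:e))

Entity scores combine into a relation score either as a plain sum (``r0``)
or as a harmonic mean (``r1``), which demotes pairs with highly disparate
entity scores; an optional type-preference coefficient (``e1``, default
0.1) penalizes pairs whose entities share a type, reflecting how rarely
same-type relations are curated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .candidate_generation import (
    CandidatePair,
    DocumentProfile,
    EntityProfile,
    collect_entity_profiles,
    generate_candidates,
    same_sentence_filter,
)
from .corpus_model import (
    ConfigurationError,
    Document,
    EntityId,
    EntityType,
    Settings,
    ValidationError,
)
from .gold_probability import GoldProbabilityModel, document_term_probabilities
from .term_recognition import TermHit, TermMatcher, annotate


@dataclass(frozen=True)
class EntityScore:
    entity: EntityId
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("entity score must be non-negative")


@dataclass(frozen=True)
class ScoredRelation:
    pair: CandidatePair
    score: float
    rank: int


def type_preference(
    t1: EntityType, t2: EntityType, setting: str = "e0", coeff: float = 0.1
) -> float:
    """Multiplicative coefficient: ``coeff`` for same-type pairs under e1."""
    if not (0 < coeff <= 1):
        raise ValidationError("type-preference coefficient must be in (0, 1]")
    if setting == "e0":
        return 1.0
    if setting == "e1":
        return coeff if t1 == t2 else 1.0
    raise ValidationError(f"unknown type-preference setting {setting!r}")


def entity_score(
    e: EntityId,
    profile: EntityProfile,
    settings: Settings,
    model: GoldProbabilityModel | None = None,
    term_probabilities: dict[tuple[str, EntityId], float] | None = None,
) -> EntityScore:
    """score(e): boosted total (m0) or probability-weighted sum (m1)."""
    if profile.entity != e:
        raise ValidationError("profile does not belong to the scored entity")
    if settings.method == "m0":
        return EntityScore(e, profile.boosted_total)
    if model is None:
        raise ConfigurationError("method m1 requires a trained gold model")
    if term_probabilities is None:
        raise ConfigurationError(
            "method m1 requires per-document term probabilities"
        )
    value = sum(
        fb * term_probabilities[(t, e)]
        for t, fb in profile.boosted_per_term.items()
    )
    return EntityScore(e, value)


def relation_score(
    s1: EntityScore,
    s2: EntityScore,
    tp: float = 1.0,
    mode: str = "r0",
    method: str = "m1",
    fE: float | None = None,
) -> float:
    """Combine two entity scores into a relation score.

    ``r0`` is the sum (divided by the document entity total f(E) under the
    m0 baseline, where the printed formula carries that normalizer); ``r1``
    is the harmonic mean, 0 when both scores are 0.  The type-preference
    coefficient multiplies either form.
    """
    a, b = s1.value, s2.value
    if a < 0 or b < 0 or tp < 0:
        raise ValidationError("relation_score requires non-negative inputs")
    if mode == "r0":
        value = a + b
        if method == "m0":
            if not fE or fE <= 0:
                raise ValidationError("m0/r0 normalization requires f(E) > 0")
            value /= fE
    elif mode == "r1":
        value = 0.0 if a + b == 0 else 2.0 * a * b / (a + b)
    else:
        raise ValidationError(f"unknown relation-score mode {mode!r}")
    return value * tp


def rank_candidates(
    profile: DocumentProfile,
    candidates: Sequence[CandidatePair] | set[CandidatePair],
    settings: Settings,
    model: GoldProbabilityModel | None = None,
) -> list[ScoredRelation]:
    """Score and rank candidate pairs of one document.

    Sorting is by score descending with ties broken by canonical pair id
    ascending, so rankings are fully deterministic.
    """
    term_probs = None
    if settings.method == "m1":
        if model is None:
            raise ConfigurationError("method m1 requires a trained gold model")
        term_probs = document_term_probabilities(model, profile, settings)
    scores: dict[EntityId, EntityScore] = {}
    for entity, ep in profile.profiles.items():
        scores[entity] = entity_score(entity, ep, settings, model, term_probs)
    fE = profile.total_entity_count
    scored: list[tuple[float, tuple[str, str], CandidatePair]] = []
    for pair in candidates:
        tp = type_preference(
            pair.e1.type, pair.e2.type, settings.type_pref,
            settings.same_type_coeff,
        )
        value = relation_score(
            scores[pair.e1], scores[pair.e2], tp,
            mode=settings.rel_score, method=settings.method, fE=fE,
        )
        scored.append((value, (str(pair.e1), str(pair.e2)), pair))
    scored.sort(key=lambda item: (-item[0], item[1]))
    return [
        ScoredRelation(pair=pair, score=value, rank=i + 1)
        for i, (value, _, pair) in enumerate(scored)
    ]


def rank_document(
    doc: Document,
    dictionary: TermMatcher | Sequence,
    settings: Settings,
    model: GoldProbabilityModel | None = None,
    apply_sentence_filter: bool = False,
) -> list[ScoredRelation]:
    """Full pipeline for one document: annotate, profile, pair up, rank."""
    hits = annotate(doc, dictionary, settings)
    return rank_hits(hits, settings, model, apply_sentence_filter)


def rank_hits(
    hits: Sequence[TermHit],
    settings: Settings,
    model: GoldProbabilityModel | None = None,
    apply_sentence_filter: bool = False,
) -> list[ScoredRelation]:
    """Rank from precomputed term hits (used when hits are cached)."""
    if not hits:
        return []
    profile = collect_entity_profiles(
        hits, boost=settings.title_boost, norm=settings.norm
    )
    candidates = generate_candidates(profile)
    if apply_sentence_filter:
        candidates = same_sentence_filter(candidates, hits)
    return rank_candidates(profile, candidates, settings, model)


def write_explanations(
    doc_id: str,
    ranked: Sequence[ScoredRelation],
    profile: DocumentProfile,
    path: str,
) -> None:
    """Curator-facing TSV: pair, rank, score, and both entity totals."""
    with open(path, "w", encoding="utf-8") as fh:
        for sr in ranked:
            p1 = profile.profiles[sr.pair.e1]
            p2 = profile.profiles[sr.pair.e2]
            fh.write(
                f"{doc_id}\t{sr.pair.e1}\t{sr.pair.e2}\t{sr.rank}"
                f"\t{sr.score!r}\t{p1.boosted_total!r}\t{p2.boosted_total!r}\n"
            )
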