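"""Seeded generator of synthetic dictionaries, abstracts and gold relations.

The generator emulates the statistical structure the ranking method relies
on, without attempting natural-language realism (the method consumes only
term hits and counts):

* every entity owns one or more unique **reliable** term forms, used when
  the entity is mentioned;
* a configurable fraction of **trap** forms is attached to a pool of
  entities that are (almost) never curated, optionally shared across
  several of them — emulating the frequent false-positive matches a noisy
  recognizer produces, which is exactly what the gold-probability model is
  meant to down-weight;
* per document, a relation count is drawn from a categorical distribution
  over 1..20 whose default decays geometrically (a large share of articles
  carry a single relation); typed pairs follow a configurable type mix
  dominated by drug-gene and disease-gene relations;
* gold entities are mentioned in the abstract more often (mean 3) than
  background entities (mean 1), appear in the title with a configurable
  probability, and are copied into the metadata zones (MeSH for diseases,
  chemical substance list for drugs) with configurable probabilities;
* gold entities miss the running text entirely with a small probability,
  so metadata zones add genuine recall, and the two entities of a relation
  co-occur in one sentence with a configurable probability, so the
  same-sentence filter is exercisable.

Everything is drawn from one ``numpy`` generator, so identical
configurations produce byte-identical corpora.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_model import (
    Document,
    EntityId,
    EntityType,
    GoldRelation,
    GoldRelationSet,
    TermEntry,
    ValidationError,
)

_TYPE_PREFIX = {
    EntityType.DISEASE: "Di",
    EntityType.DRUG: "Dr",
    EntityType.GENE: "Ge",
}

#: default relations-per-article distribution over 1..20 — geometric decay,
#: ~40% of articles with a single relation
def _default_relation_distribution(max_relations: int = 20, decay: float = 0.6):
    weights = np.array([decay ** (k - 1) for k in range(1, max_relations + 1)])
    return tuple(weights / weights.sum())


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 1000
    entities_per_type: int = 60
    forms_per_entity: int = 2
    trap_entities_per_type: int = 12
    trap_sharing: int = 2
    trap_gold_rate: float = 0.05
    reliable_gold_rate: float = 0.9
    relations_per_doc: tuple[float, ...] = field(
        default_factory=_default_relation_distribution
    )
    # unordered type-pair weights; same-type mass split evenly over types
    type_mix: tuple[tuple[str, str, float], ...] = (
        ("drug", "gene", 0.42),
        ("disease", "gene", 0.37),
        ("disease", "drug", 0.18),
        ("same", "same", 0.03),
    )
    title_mention_prob: float = 0.5
    text_mention_prob: float = 0.85
    gold_mention_mean: float = 3.0
    background_mention_mean: float = 1.0
    background_rate: float | None = None  # derived from reliable_gold_rate
    mesh_prob: float = 0.8
    chemicals_prob: float = 0.8
    trap_rate: float = 2.0
    trap_mention_mean: float = 2.0
    same_sentence_prob: float = 0.7
    sentence_length: tuple[int, int] = (8, 15)

    def __post_init__(self) -> None:
        if self.entities_per_type < 1:
            raise ValidationError("entities_per_type must be >= 1")
        if self.forms_per_entity < 1:
            raise ValidationError("forms_per_entity must be >= 1")
        probs = [w for _, _, w in self.type_mix]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError("type_mix weights must sum to 1")
        for p in (
            self.trap_gold_rate, self.reliable_gold_rate,
            self.title_mention_prob, self.text_mention_prob,
            self.mesh_prob, self.chemicals_prob, self.same_sentence_prob,
        ):
            if not (0 <= p <= 1):
                raise ValidationError("probabilities must lie in [0, 1]")
        if abs(sum(self.relations_per_doc) - 1.0) > 1e-9:
            raise ValidationError("relations_per_doc must sum to 1")

    @property
    def derived_background_rate(self) -> float:
        if self.background_rate is not None:
            return self.background_rate
        r = self.reliable_gold_rate
        if r >= 1.0:
            return 0.0
        # mean gold entities/doc ~ 2 * mean relations/doc (before dedup);
        # choose the background rate so the share of non-gold instances of
        # reliable forms is (1 - r)
        ks = np.arange(1, len(self.relations_per_doc) + 1)
        mean_gold = 2.0 * float(np.dot(ks, self.relations_per_doc))
        return mean_gold * (1.0 - r) / r


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a corpus for test assertions."""

    form_kind: dict[str, str] = field(default_factory=dict)  # surface -> kind
    planted_rates: dict[str, float] = field(default_factory=dict)
    form_entities: dict[str, list[str]] = field(default_factory=dict)
    placements: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "form_kind": self.form_kind,
                    "planted_rates": self.planted_rates,
                    "form_entities": self.form_entities,
                    "placements": self.placements,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def generate_dictionary(
    config: GeneratorConfig,
) -> tuple[list[TermEntry], SyntheticTruth]:
    """Build the typed term dictionary with reliable and trap surfaces."""
    truth = SyntheticTruth(
        planted_rates={
            "reliable": config.reliable_gold_rate,
            "trap": config.trap_gold_rate,
        }
    )
    entries: list[TermEntry] = []
    for etype in EntityType:
        prefix = _TYPE_PREFIX[etype]
        for i in range(config.entities_per_type):
            entity = EntityId(f"{prefix}{i:04d}", etype)
            for j in range(config.forms_per_entity):
                surface = f"{prefix.lower()}{i:04d}{chr(ord('a') + j)}"
                entries.append(TermEntry(surface, entity))
                truth.form_kind[surface] = "reliable"
                truth.form_entities.setdefault(surface, []).append(str(entity))
        # trap pool: never sampled for planted relations; surfaces may be
        # shared across several trap entities of the type
        trap_ids = [
            EntityId(f"{prefix}T{i:03d}", etype)
            for i in range(config.trap_entities_per_type)
        ]
        for start in range(0, len(trap_ids), config.trap_sharing):
            group = trap_ids[start : start + config.trap_sharing]
            surface = f"trap{prefix.lower()}{start // config.trap_sharing:03d}"
            for entity in group:
                entries.append(TermEntry(surface, entity))
                truth.form_entities.setdefault(surface, []).append(str(entity))
            truth.form_kind[surface] = "trap"
    return entries, truth


class _Filler:
    """Deterministic non-dictionary filler vocabulary."""

    def __init__(self, rng: np.random.Generator, size: int = 80) -> None:
        self._words = [f"flw{i:03d}" for i in range(size)]
        self._rng = rng

    def words(self, n: int) -> list[str]:
        idx = self._rng.integers(0, len(self._words), size=n)
        return [self._words[i] for i in idx]


def generate_corpus(
    config: GeneratorConfig,
    entries: Sequence[TermEntry] | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[list[Document], GoldRelationSet, list[TermEntry], SyntheticTruth]:
    """Generate documents and gold relations over a (generated) dictionary."""
    rng = np.random.default_rng(config.seed)
    if entries is None or truth is None:
        entries, truth = generate_dictionary(config)
    filler = _Filler(rng)

    regular: dict[EntityType, list[EntityId]] = {t: [] for t in EntityType}
    forms_of: dict[EntityId, list[str]] = {}
    for entry in entries:
        if truth.form_kind.get(entry.surface) == "trap":
            forms_of.setdefault(entry.entity, [])
            continue
        if entry.entity not in forms_of:
            regular[entry.entity.type].append(entry.entity)
            forms_of[entry.entity] = []
        forms_of[entry.entity].append(entry.surface)
    trap_surfaces = sorted(
        s for s, kind in truth.form_kind.items() if kind == "trap"
    )
    trap_entities_of = {
        s: [e for e in _entities_of_surface(entries, s)] for s in trap_surfaces
    }

    same_type_weight = sum(w for a, b, w in config.type_mix if a == "same")
    pair_types = [
        (EntityType(a), EntityType(b), w)
        for a, b, w in config.type_mix
        if a != "same"
    ]
    if same_type_weight > 0:
        for t in EntityType:
            if len(regular[t]) < 2:
                raise ValidationError(
                    "same-type relations require >= 2 entities per type"
                )
            pair_types.append((t, t, same_type_weight / len(list(EntityType))))
    type_probs = np.array([w for _, _, w in pair_types])
    type_probs = type_probs / type_probs.sum()

    rel_probs = np.array(config.relations_per_doc)
    documents: list[Document] = []
    gold = GoldRelationSet()

    for d in range(config.n_docs):
        doc_id = f"doc{d:05d}"
        n_rel = int(rng.choice(len(rel_probs), p=rel_probs)) + 1
        relations: set[frozenset[EntityId]] = set()
        attempts = 0
        while len(relations) < n_rel and attempts < 50 * n_rel:
            attempts += 1
            ti = int(rng.choice(len(pair_types), p=type_probs))
            t1, t2, _ = pair_types[ti]
            e1 = regular[t1][int(rng.integers(len(regular[t1])))]
            e2 = regular[t2][int(rng.integers(len(regular[t2])))]
            if e1 == e2:
                continue
            relations.add(frozenset((e1, e2)))
        gold_entities: set[EntityId] = set()
        for pair in relations:
            a, b = sorted(pair, key=str)
            gold.add(GoldRelation(doc_id, a, b))
            gold_entities.update(pair)

        # trap injections; occasionally a trap is genuinely curated
        n_traps = int(rng.poisson(config.trap_rate))
        trap_mentions: list[str] = []
        for _ in range(n_traps):
            surface = trap_surfaces[int(rng.integers(len(trap_surfaces)))]
            n_m = 1 + int(rng.poisson(max(config.trap_mention_mean - 1, 0)))
            trap_mentions.extend([surface] * n_m)
            if rng.random() < config.trap_gold_rate:
                for trap_entity in trap_entities_of[surface]:
                    partners = sorted(
                        (e for e in gold_entities if e.type != trap_entity.type),
                        key=str,
                    )
                    if partners:
                        partner = partners[int(rng.integers(len(partners)))]
                        gold.add(GoldRelation(doc_id, trap_entity, partner))

        # background (non-gold) entity mentions dilute the reliable forms
        n_bg = int(rng.poisson(config.derived_background_rate))
        background: list[EntityId] = []
        pool = [e for t in EntityType for e in regular[t]]
        for _ in range(n_bg):
            e = pool[int(rng.integers(len(pool)))]
            if e not in gold_entities:
                background.append(e)

        placements: dict[str, list[str]] = {}
        title_tokens: list[str] = []
        abstract_mentions: dict[EntityId, list[str]] = {}

        def pick_form(entity: EntityId) -> str:
            forms = forms_of[entity]
            return forms[int(rng.integers(len(forms)))]

        for entity in sorted(gold_entities, key=str):
            zones: list[str] = []
            in_text = rng.random() < config.text_mention_prob
            if in_text:
                n_m = 1 + int(rng.poisson(max(config.gold_mention_mean - 1, 0)))
                if rng.random() < config.title_mention_prob:
                    title_tokens.append(pick_form(entity))
                    zones.append("title")
                    n_m = max(n_m - 1, 1)
                abstract_mentions[entity] = [pick_form(entity) for _ in range(n_m)]
                zones.append("abstract")
            if entity.type is EntityType.DISEASE and rng.random() < config.mesh_prob:
                zones.append("mesh")
            if entity.type is EntityType.DRUG and (
                rng.random() < config.chemicals_prob
            ):
                zones.append("chemicals")
            placements[str(entity)] = zones
        for entity in background:
            n_m = 1 + int(
                rng.poisson(max(config.background_mention_mean - 1, 0))
            )
            abstract_mentions.setdefault(entity, []).extend(
                pick_form(entity) for _ in range(n_m)
            )
            placements.setdefault(str(entity), []).append("abstract")

        # sentence planning: co-place related entities with the configured
        # probability, then scatter the remaining mentions
        sentences: list[list[str]] = []
        for pair in sorted(relations, key=lambda p: sorted(map(str, p))):
            a, b = sorted(pair, key=str)
            if (
                abstract_mentions.get(a)
                and abstract_mentions.get(b)
                and rng.random() < config.same_sentence_prob
            ):
                sentences.append(
                    [abstract_mentions[a].pop(), abstract_mentions[b].pop()]
                )
        loose: list[str] = trap_mentions[:]
        for entity in sorted(abstract_mentions, key=str):
            loose.extend(abstract_mentions[entity])
        rng.shuffle(loose)
        for mention in loose:
            if sentences and rng.random() < 0.5:
                sentences[int(rng.integers(len(sentences)))].append(mention)
            else:
                sentences.append([mention])

        lo, hi = config.sentence_length
        rendered: list[str] = []
        for sent in sentences:
            target = int(rng.integers(lo, hi + 1))
            pad = max(target - len(sent), 1)
            words = filler.words(pad) + sent
            rng.shuffle(words)
            words[0] = words[0].capitalize()
            rendered.append(" ".join(words) + ".")
        abstract = " ".join(rendered)

        title_words = filler.words(3) + title_tokens
        rng.shuffle(title_words)
        title_words[0] = title_words[0].capitalize()
        title = " ".join(title_words)

        mesh: list[tuple[str, list[str]]] = []
        chemicals: list[str] = []
        for entity in sorted(gold_entities, key=str):
            zones = placements.get(str(entity), ())
            if "mesh" in zones:
                mesh.append((pick_form(entity), []))
            if "chemicals" in zones:
                chemicals.append(pick_form(entity))

        documents.append(
            Document(
                doc_id=doc_id,
                title=title,
                abstract=abstract,
                mesh=mesh,
                chemicals=chemicals,
            )
        )
        truth.placements[doc_id] = placements

    return documents, gold, list(entries), truth


def _entities_of_surface(
    entries: Sequence[TermEntry], surface: str
) -> list[EntityId]:
    return sorted(
        {e.entity for e in entries if e.surface == surface}, key=str
    )
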