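"""Maximum-entropy model of an entity's probability of being curated.

For an article ``A``, the predicate ``gold(A, e)`` is 1 iff entity ``e``
takes part in at least one curated relation of ``A``.  The model estimates

    P(gold(A, e) = 1 | e, t, f^c(t:e))

where ``t`` is a normalized term form by which ``e`` was recognized and
``f^c(t:e)`` its capped occurrence count in the article.  Each triple
(e, t, f^c) is a joint indicator feature of a conditional log-linear
(logistic regression) classifier

    p_lambda(y | x) = exp(sum_i lambda_i F_i(x, y)) / Z(x)

trained to maximize conditional log-likelihood.  Two sparsity devices are
layered on top of the raw features:

* **caps** — the count is clipped at 1, 3, 6 or 9 (``c1``..``c9``), or kept
  raw (``c0``); with a cap of 1 the feature reduces to mere presence;
* **smoothing** (``s1``) — a feature (e, t, n) is added for every
  1 <= n < f^c(t:e), so lower count levels receive training signal from
  every instance with a higher capped count.  Under ``c1`` smoothing is a
  no-op by construction.

Prediction backs off for unseen (t, e) pairs: first to the mean predicted
probability of the entity's *seen* term pairs within the same document,
then to a per-entity-type average over the training set.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .corpus_model import (
    Document,
    EntityId,
    EntityType,
    GoldRelationSet,
    Settings,
    ValidationError,
)
from .candidate_generation import DocumentProfile, collect_entity_profiles
from .term_recognition import TermHit

logger = logging.getLogger(__name__)

#: longest smoothing chain emitted for uncapped (c0) counts
MAX_SMOOTHING_CHAIN = 50

_CAP_VALUES = {"c0": None, "c1": 1, "c3": 3, "c6": 6, "c9": 9}


@dataclass(frozen=True, order=True)
class FeatureKey:
    """The joint feature (entity, normalized term form, count level)."""

    entity: EntityId
    term: str
    count_level: int

    def __post_init__(self) -> None:
        if self.count_level < 1:
            raise ValidationError("count_level must be >= 1")


@dataclass(frozen=True)
class TrainingInstance:
    """One (document, term form, entity) observation with its gold label."""

    doc_id: str
    entity: EntityId
    term: str
    capped: int
    features: frozenset[FeatureKey]
    label: int


def capped_count(f: int, cap: str | int | None) -> int:
    """Clip a raw term-entity count at the configured cap.

    ``cap`` may be a setting code (``c0``..``c9``), an integer, or None
    (no cap).  A zero count is rejected: a feature only exists for a term
    that occurred.
    """
    if f < 1:
        raise ValidationError("capped_count requires f >= 1")
    if isinstance(cap, str):
        cap = _CAP_VALUES[cap]
    if cap is None:
        return f
    return min(f, cap)


def build_feature_set(
    e: EntityId, t: str, fc: int, smooth: str | bool = "s0"
) -> frozenset[FeatureKey]:
    """Features for one observation: the joint feature plus smoothing levels.

    With smoothing on, every level ``1 <= n < fc`` is added alongside the
    original feature.  Chains longer than :data:`MAX_SMOOTHING_CHAIN`
    (possible only with uncapped counts) are truncated.
    """
    if fc < 1:
        raise ValidationError("capped count must be >= 1")
    smoothing = smooth in ("s1", True)
    if not smoothing:
        return frozenset({FeatureKey(e, t, fc)})
    top = fc
    if top > MAX_SMOOTHING_CHAIN:
        logger.warning(
            "smoothing chain for %s/%s truncated at %d (count %d)",
            e, t, MAX_SMOOTHING_CHAIN, top,
        )
    levels = set(range(1, min(top, MAX_SMOOTHING_CHAIN) + 1))
    levels.add(top)
    return frozenset(FeatureKey(e, t, n) for n in levels)


def gold_label(doc_id: str, e: EntityId, gold: GoldRelationSet) -> int:
    """1 iff the entity takes part in >= 1 gold relation of the document."""
    return int(gold.gold(doc_id, e))


def build_training_set(
    docs: Sequence[Document],
    hits_per_doc: Mapping[str, Sequence[TermHit]],
    gold: GoldRelationSet,
    settings: Settings,
) -> list[TrainingInstance]:
    """One instance per (document, distinct normalized term form, entity)."""
    instances: list[TrainingInstance] = []
    for doc in docs:
        hits = hits_per_doc.get(doc.doc_id, ())
        if not hits:
            continue
        profile = collect_entity_profiles(
            hits, boost=settings.title_boost, norm=settings.norm
        )
        for entity in sorted(profile.profiles, key=str):
            ep = profile.profiles[entity]
            label = gold_label(doc.doc_id, entity, gold)
            for term in sorted(ep.per_term_counts):
                fc = capped_count(ep.per_term_counts[term], settings.cap)
                instances.append(
                    TrainingInstance(
                        doc_id=doc.doc_id,
                        entity=entity,
                        term=term,
                        capped=fc,
                        features=build_feature_set(
                            entity, term, fc, settings.smooth
                        ),
                        label=label,
                    )
                )
    return instances


@dataclass
class GoldProbabilityModel:
    """Trained feature weights plus back-off tables.

    ``weights`` maps each feature to its lambda; ``bias`` is the intercept.
    ``seen_pairs`` records every (entity, term) observed in training — the
    trigger for direct prediction versus back-off.  ``type_backoff`` holds
    the mean predicted training probability per entity type.
    """

    weights: dict[FeatureKey, float] = field(default_factory=dict)
    bias: float = 0.0
    type_backoff: dict[EntityType, float] = field(default_factory=dict)
    seen_pairs: set[tuple[EntityId, str]] = field(default_factory=set)
    training_meta: tuple[str, str, str] = ("n0", "c0", "s0")
    constant_probability: float | None = None

    def linear_score(self, features: Iterable[FeatureKey]) -> float:
        # summation in sorted feature order keeps float results identical
        # across processes regardless of set iteration order
        return self.bias + sum(
            self.weights.get(f, 0.0) for f in sorted(features)
        )

    def probability_from_features(self, features: Iterable[FeatureKey]) -> float:
        if self.constant_probability is not None:
            return self.constant_probability
        return 1.0 / (1.0 + math.exp(-self.linear_score(features)))

    def default_backoff(self) -> float:
        if self.type_backoff:
            return sum(self.type_backoff.values()) / len(self.type_backoff)
        if self.constant_probability is not None:
            return self.constant_probability
        return 0.5


def train_gold_model(
    instances: Sequence[TrainingInstance],
    l2: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    training_meta: tuple[str, str, str] = ("n0", "c0", "s0"),
) -> GoldProbabilityModel:
    """Fit the logistic model by conditional maximum likelihood.

    With ``l2 = 0`` no penalty is applied, so on disjoint indicator
    features the fitted probabilities equal the empirical label
    frequencies.  If every label is identical the model degenerates to a
    constant probability (with a warning) rather than failing.
    """
    if not instances:
        raise ValidationError("cannot train on an empty instance set")
    meta = training_meta
    labels = np.array([inst.label for inst in instances], dtype=np.int64)
    seen_pairs = {(inst.entity, inst.term) for inst in instances}

    if labels.min() == labels.max():
        logger.warning(
            "all %d training labels are %d; degenerating to a constant model",
            len(labels), labels[0],
        )
        p = float(np.clip(labels.mean(), 1e-6, 1 - 1e-6))
        model = GoldProbabilityModel(
            seen_pairs=seen_pairs, training_meta=meta, constant_probability=p
        )
        model.type_backoff = _type_backoff(model, instances)
        return model

    feature_list = sorted({f for inst in instances for f in inst.features})
    feature_index = {f: i for i, f in enumerate(feature_list)}
    indptr = [0]
    indices: list[int] = []
    for inst in instances:
        indices.extend(sorted(feature_index[f] for f in inst.features))
        indptr.append(len(indices))
    X = csr_matrix(
        (np.ones(len(indices), dtype=np.float64), indices, indptr),
        shape=(len(instances), len(feature_list)),
    )
    clf = LogisticRegression(
        C=np.inf if l2 == 0.0 else 1.0 / l2,
        solver="lbfgs",
        tol=tol,
        max_iter=max_iter,
    )
    with warnings.catch_warnings():
        # separable indicator data stops at the iteration cap by design
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, labels)
    model = GoldProbabilityModel(
        weights={f: float(w) for f, w in zip(feature_list, clf.coef_[0])},
        bias=float(clf.intercept_[0]),
        seen_pairs=seen_pairs,
        training_meta=meta,
    )
    model.type_backoff = _type_backoff(model, instances)
    return model


def _type_backoff(
    model: GoldProbabilityModel, instances: Sequence[TrainingInstance]
) -> dict[EntityType, float]:
    sums: dict[EntityType, float] = {}
    counts: dict[EntityType, int] = {}
    for inst in instances:
        p = model.probability_from_features(inst.features)
        et = inst.entity.type
        sums[et] = sums.get(et, 0.0) + p
        counts[et] = counts.get(et, 0) + 1
    return {et: sums[et] / counts[et] for et in sums}


def predict_gold_probability(
    model: GoldProbabilityModel,
    e: EntityId,
    t: str,
    fc: int,
    smooth: str | bool = "s0",
    seen_pairs_in_doc: Mapping[tuple[str, EntityId], float] | None = None,
) -> float:
    """Predict P(gold | e, t, f^c) with the two-stage back-off.

    A pair seen in training is scored directly from its feature set.  An
    unseen pair falls back to the mean probability of the entity's seen
    pairs within the document (``seen_pairs_in_doc``), and failing that to
    the per-type training average.
    """
    if fc < 1:
        raise ValidationError("capped count must be >= 1")
    if (e, t) in model.seen_pairs or model.constant_probability is not None:
        return model.probability_from_features(build_feature_set(e, t, fc, smooth))
    if seen_pairs_in_doc:
        own = [p for (term, ent), p in seen_pairs_in_doc.items() if ent == e]
        if own:
            return sum(own) / len(own)
    if e.type in model.type_backoff:
        return model.type_backoff[e.type]
    return model.default_backoff()


def document_term_probabilities(
    model: GoldProbabilityModel,
    profile: DocumentProfile,
    settings: Settings,
) -> dict[tuple[str, EntityId], float]:
    """Gold probabilities for every (term form, entity) pair of a document.

    Seen pairs are scored first so that unseen pairs of the same entity can
    back off to their within-document average.
    """
    seen: dict[tuple[str, EntityId], float] = {}
    unseen: list[tuple[str, EntityId, int]] = []
    for entity, ep in profile.profiles.items():
        for term, f in ep.per_term_counts.items():
            fc = capped_count(f, settings.cap)
            if (entity, term) in model.seen_pairs or (
                model.constant_probability is not None
            ):
                seen[(term, entity)] = model.probability_from_features(
                    build_feature_set(entity, term, fc, settings.smooth)
                )
            else:
                unseen.append((term, entity, fc))
    out = dict(seen)
    for term, entity, fc in unseen:
        out[(term, entity)] = predict_gold_probability(
            model, entity, term, fc, settings.smooth, seen
        )
    return out


def evaluate_gold_model(
    model: GoldProbabilityModel,
    instances: Sequence[TrainingInstance],
    metric: str = "accuracy@0.5",
) -> float:
    """Macro-averaged model quality on held-out instances.

    ``accuracy@0.5`` counts a prediction >= 0.5 as class 1;
    ``mean_correct_class_probability`` averages the probability assigned to
    the true class.  Either way the score is computed per document first,
    then averaged over documents.
    """
    if not instances:
        raise ValidationError("cannot evaluate on an empty instance set")
    if metric not in ("accuracy@0.5", "mean_correct_class_probability"):
        raise ValidationError(f"unknown metric {metric!r}")
    by_doc: dict[str, list[TrainingInstance]] = {}
    for inst in instances:
        by_doc.setdefault(inst.doc_id, []).append(inst)
    doc_scores: list[float] = []
    for doc_id, doc_insts in by_doc.items():
        seen: dict[tuple[str, EntityId], float] = {}
        for inst in doc_insts:
            if (inst.entity, inst.term) in model.seen_pairs:
                seen[(inst.term, inst.entity)] = model.probability_from_features(
                    inst.features
                )
        values: list[float] = []
        for inst in doc_insts:
            p = predict_gold_probability(
                model, inst.entity, inst.term, inst.capped,
                seen_pairs_in_doc=seen,
            )
            if (inst.entity, inst.term) in model.seen_pairs:
                p = model.probability_from_features(inst.features)
            if metric == "accuracy@0.5":
                predicted = 1 if p >= 0.5 else 0
                values.append(1.0 if predicted == inst.label else 0.0)
            else:
                values.append(p if inst.label == 1 else 1.0 - p)
        doc_scores.append(sum(values) / len(values))
    return sum(doc_scores) / len(doc_scores)


# ---------------------------------------------------------------------------
# Persistence: flat text format with exact float round-trip
# ---------------------------------------------------------------------------

_SEP = "\x1f"  # reserved separator, cannot occur in normalized term forms


def save_gold_model(model: GoldProbabilityModel, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#meta{_SEP}{_SEP.join(model.training_meta)}\n")
        fh.write(f"#bias{_SEP}{model.bias!r}\n")
        if model.constant_probability is not None:
            fh.write(f"#constant{_SEP}{model.constant_probability!r}\n")
        for et in sorted(model.type_backoff, key=lambda t: t.value):
            fh.write(f"#backoff{_SEP}{et.value}{_SEP}{model.type_backoff[et]!r}\n")
        for e, t in sorted(model.seen_pairs, key=lambda p: (str(p[0]), p[1])):
            fh.write(f"#seen{_SEP}{e.id}{_SEP}{e.type.value}{_SEP}{t}\n")
        for key in sorted(model.weights):
            fh.write(
                f"{key.entity.id}{_SEP}{key.entity.type.value}{_SEP}{key.term}"
                f"{_SEP}{key.count_level}{_SEP}{model.weights[key]!r}\n"
            )


def load_gold_model(path: str) -> GoldProbabilityModel:
    model = GoldProbabilityModel()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(_SEP)
            if parts[0] == "#meta":
                model.training_meta = tuple(parts[1:4])  # type: ignore[assignment]
            elif parts[0] == "#bias":
                model.bias = float(parts[1])
            elif parts[0] == "#constant":
                model.constant_probability = float(parts[1])
            elif parts[0] == "#backoff":
                model.type_backoff[EntityType.parse(parts[1])] = float(parts[2])
            elif parts[0] == "#seen":
                model.seen_pairs.add(
                    (EntityId(parts[1], EntityType.parse(parts[2])), parts[3])
                )
            else:
                ent_id, type_code, term, level, weight = parts
                key = FeatureKey(
                    EntityId(ent_id, EntityType.parse(type_code)), term, int(level)
                )
                model.weights[key] = float(weight)
    return model
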