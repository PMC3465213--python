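"""Ranked-retrieval evaluation: macro-averaged P/R/F, AUC iP/R and TAP-k,
stratified cross-validation, exact paired Wilcoxon comparison, the
perfect-ranking upper bound, and a greedy single-parameter improvement
ladder over experimental settings.

AUC iP/R is the area under the interpolated precision/recall curve of a
ranked candidate list: interpolated precision at recall level r is the
maximum precision at any recall >= r within the evaluated list, and the
area averages it over the recall points of the gold items (items never
retrieved contribute zero).  It rewards correct candidates ranked early —
not to be confused with ROC AUC.

TAP-k models a curator who abandons a ranked list after rejecting ``k``
false positives: precision is summed at the ranks of the gold items at or
above the rank ``T`` of the k-th false positive (or the end of the list if
fewer occur), a terminal precision-at-T term is added, and the total is
divided by (number of gold items + 1).

All document-level metrics are macro-averaged: computed separately per
article, then averaged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .corpus_model import (
    Document,
    GoldRelationSet,
    Settings,
    TermEntry,
    ValidationError,
)
from .gold_probability import build_training_set, train_gold_model
from .relation_ranking import rank_hits
from .term_recognition import TermMatcher, annotate


# ---------------------------------------------------------------------------
# Per-document metrics
# ---------------------------------------------------------------------------

def _dedupe(ranked: Sequence[Hashable]) -> list[Hashable]:
    """Collapse repeated predictions of the same item to their best rank."""
    seen: set[Hashable] = set()
    out = []
    for item in ranked:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


def prf_at_cutoff(
    ranked: Sequence[Hashable], gold: set, cutoff: int
) -> tuple[float, float, float]:
    """Precision, recall and F-measure on the top-``cutoff`` predictions."""
    if not gold:
        raise ValidationError("gold set must be non-empty")
    if cutoff < 1:
        raise ValidationError("cutoff must be positive")
    top = _dedupe(ranked)[:cutoff]
    tp = sum(1 for item in top if item in gold)
    precision = tp / len(top) if top else 0.0
    recall = tp / len(gold)
    f = (
        0.0
        if precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return precision, recall, f


def auc_ipr(ranked: Sequence[Hashable], gold: set, cutoff: int = 50) -> float:
    """Area under the interpolated precision/recall curve, truncated."""
    if not gold:
        raise ValidationError("gold set must be non-empty")
    top = _dedupe(ranked)[:cutoff]
    precisions: list[float] = []  # precision at each gold item's rank
    tp = 0
    for i, item in enumerate(top, start=1):
        if item in gold:
            tp += 1
            precisions.append(tp / i)
    if not precisions:
        return 0.0
    # interpolate: precision at a recall point is the max at this or any
    # deeper recall point inside the evaluated list
    interpolated = list(itertools.accumulate(reversed(precisions), max))
    return sum(interpolated) / len(gold)


def tap_k(ranked: Sequence[Hashable], gold: set, k: int = 10) -> float:
    """Threshold average precision at ``k`` tolerated false positives."""
    if not gold:
        raise ValidationError("gold set must be non-empty")
    if k < 1:
        raise ValidationError("k must be positive")
    items = _dedupe(ranked)
    if not items:
        return 0.0
    threshold_rank = len(items)
    fp = 0
    for i, item in enumerate(items, start=1):
        if item not in gold:
            fp += 1
            if fp == k:
                threshold_rank = i
                break
    total = 0.0
    tp = 0
    precision_at_t = 0.0
    for i, item in enumerate(items[:threshold_rank], start=1):
        if item in gold:
            tp += 1
            total += tp / i
        precision_at_t = tp / i
    return (total + precision_at_t) / (len(gold) + 1)


def perfect_ranking_bound(
    ranked: Sequence[Hashable], gold: set
) -> list[Hashable]:
    """Stable partition pushing all true positives ahead of false positives."""
    tps = [item for item in ranked if item in gold]
    fps = [item for item in ranked if item not in gold]
    return tps + fps


@dataclass
class DocumentEvaluation:
    doc_id: str
    n_gold: int
    precision: float
    recall: float
    f_measure: float
    auc_ipr: float
    tap_k: float


def evaluate_document(
    doc_id: str,
    ranked: Sequence[Hashable],
    gold: set,
    cutoff: int = 50,
    k: int = 10,
) -> DocumentEvaluation:
    p, r, f = prf_at_cutoff(ranked, gold, cutoff)
    return DocumentEvaluation(
        doc_id=doc_id,
        n_gold=len(gold),
        precision=p,
        recall=r,
        f_measure=f,
        auc_ipr=auc_ipr(ranked, gold, cutoff),
        tap_k=tap_k(ranked, gold, k),
    )


def macro_average(
    per_doc: Mapping[str, float | None],
    include_rule: str = "all_gold_docs",
) -> tuple[float, float]:
    """Mean and sample standard deviation over documents.

    A value of None marks a document without predictions: under
    ``all_gold_docs`` it contributes 0, under ``docs_with_predictions`` it
    is excluded (the convention of the original shared-task scorer).
    """
    if include_rule == "all_gold_docs":
        values = [0.0 if v is None else v for v in per_doc.values()]
    elif include_rule == "docs_with_predictions":
        values = [v for v in per_doc.values() if v is not None]
    else:
        raise ValidationError(f"unknown include rule {include_rule!r}")
    if not values:
        raise ValidationError("no documents left after applying include rule")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


# ---------------------------------------------------------------------------
# Stratified cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(
    doc_gold_counts: Mapping[str, int], n_folds: int = 10, seed: int = 0
) -> dict[str, int]:
    """Assign documents to folds, stratified by gold-relation count.

    Within each stratum (documents sharing a relation count) the documents
    are shuffled with the seed and dealt round-robin, so per-stratum fold
    sizes differ by at most one.  The relation-type mix is deliberately not
    balanced.
    """
    if n_folds < 2:
        raise ValidationError("need at least 2 folds")
    for doc_id, count in doc_gold_counts.items():
        if count < 1:
            raise ValidationError(
                f"document {doc_id!r} has no gold relations; exclude it first"
            )
    rng = np.random.default_rng(seed)
    strata: dict[int, list[str]] = {}
    for doc_id in sorted(doc_gold_counts):
        strata.setdefault(doc_gold_counts[doc_id], []).append(doc_id)
    assignment: dict[str, int] = {}
    offset = 0
    for count in sorted(strata):
        docs = strata[count]
        rng.shuffle(docs)
        for i, doc_id in enumerate(docs):
            assignment[doc_id] = (offset + i) % n_folds
        offset += len(docs)
    return assignment


# ---------------------------------------------------------------------------
# Exact paired Wilcoxon signed-rank comparison
# ---------------------------------------------------------------------------

def _signed_rank_distribution(ranks: Sequence[float]) -> dict[Fraction, int]:
    """Exact null distribution of the positive-rank sum by enumeration."""
    dist: dict[Fraction, int] = {Fraction(0): 1}
    for r in ranks:
        fr = Fraction(r).limit_denominator(2)
        new: dict[Fraction, int] = {}
        for value, count in dist.items():
            new[value] = new.get(value, 0) + count
            new[value + fr] = new.get(value + fr, 0) + count
        dist = new
    return dist


def _average_ranks(values: Sequence[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def paired_wilcoxon(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> tuple[float, float]:
    """Exact one-sided signed-rank test of ``b > a`` with a lower CI bound.

    Returns the enumerative (not normal-approximation) one-sided p-value
    and the exact one-sided ``1 - alpha`` lower confidence bound for the
    location shift, computed from the Walsh averages of the differences.
    Zero differences are discarded; if all differences are zero the result
    is (1.0, 0.0).
    """
    if len(a) != len(b):
        raise ValidationError("paired samples must have equal length")
    if len(a) < 5:
        raise ValidationError("need at least 5 pairs for a meaningful test")
    diffs = [bi - ai for ai, bi in zip(a, b)]
    nonzero = [d for d in diffs if d != 0]
    if not nonzero:
        return 1.0, 0.0
    n = len(nonzero)
    ranks = _average_ranks([abs(d) for d in nonzero])
    t_obs = sum(r for d, r in zip(nonzero, ranks) if d > 0)
    dist = _signed_rank_distribution(ranks)
    total = 2 ** n
    t_obs_fr = Fraction(t_obs).limit_denominator(2)
    p = sum(c for v, c in dist.items() if v >= t_obs_fr) / total

    # exact lower confidence bound via Walsh averages
    walsh = sorted(
        (nonzero[i] + nonzero[j]) / 2
        for i in range(n)
        for j in range(i, n)
    )
    # largest q with P(T+ <= q) <= alpha under the untied null
    untied = _signed_rank_distribution(list(range(1, n + 1)))
    cdf = 0.0
    q = -1
    for value in sorted(untied):
        cdf += untied[value] / total
        if cdf <= alpha:
            q = int(value)
        else:
            break
    ci_lower = walsh[max(q, 0)] if q + 1 <= len(walsh) else walsh[-1]
    return float(p), float(ci_lower)


# ---------------------------------------------------------------------------
# Cross-validated comparison of settings
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Macro metric summary of one setting over cross-validation folds."""

    label: str
    metric: str
    fold_means: list[float]
    per_doc: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_means))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_means, ddof=1))


METRIC_FIELDS = {
    "tap": "tap_k",
    "auc": "auc_ipr",
    "precision": "precision",
    "recall": "recall",
    "f": "f_measure",
}


def cross_validate(
    docs: Sequence[Document],
    dictionary: Sequence[TermEntry] | TermMatcher,
    gold: GoldRelationSet,
    settings_list: Sequence[Settings],
    n_folds: int = 10,
    seed: int = 0,
    metric: str = "tap",
    include_rule: str = "all_gold_docs",
) -> dict[str, EvaluationReport]:
    """Stratified k-fold evaluation of every setting on one corpus.

    Documents without gold relations are excluded (macro metrics are
    undefined for them).  For each fold and each ``m1`` setting, the gold
    model is trained on the other folds only.  Returns one report per
    setting label; fold means are macro averages over the fold's documents.
    """
    if metric not in METRIC_FIELDS:
        raise ValidationError(f"unknown metric {metric!r}")
    matcher = (
        dictionary
        if isinstance(dictionary, TermMatcher)
        else TermMatcher(dictionary)
    )
    eligible = [d for d in docs if gold.n_relations(d.doc_id) > 0]
    if not eligible:
        raise ValidationError("no documents with gold relations")
    counts = {d.doc_id: gold.n_relations(d.doc_id) for d in eligible}
    folds = stratified_folds(counts, n_folds=n_folds, seed=seed)

    # annotation depends only on the zone setting; cache per zone string
    hits_cache: dict[str, dict[str, list]] = {}

    def hits_for(zones: str) -> dict[str, list]:
        if zones not in hits_cache:
            zone_settings = Settings(zones=zones)
            hits_cache[zones] = {
                d.doc_id: annotate(d, matcher, zone_settings) for d in eligible
            }
        return hits_cache[zones]

    reports: dict[str, EvaluationReport] = {}
    for settings in settings_list:
        hits_per_doc = hits_for(settings.zones)
        fold_means: list[float] = []
        per_doc_all: dict[str, float] = {}
        for fold in range(n_folds):
            test_docs = [d for d in eligible if folds[d.doc_id] == fold]
            if not test_docs:
                continue
            model = None
            if settings.method == "m1":
                train_docs = [d for d in eligible if folds[d.doc_id] != fold]
                instances = build_training_set(
                    train_docs, hits_per_doc, gold, settings
                )
                model = train_gold_model(
                    instances,
                    training_meta=(settings.norm, settings.cap, settings.smooth),
                )
            per_doc: dict[str, float | None] = {}
            for doc in test_docs:
                gold_pairs = set(gold.pairs(doc.doc_id))
                ranked = rank_hits(hits_per_doc[doc.doc_id], settings, model)
                if not ranked:
                    per_doc[doc.doc_id] = None
                    continue
                ev = evaluate_document(
                    doc.doc_id,
                    [sr.pair.key for sr in ranked],
                    gold_pairs,
                    cutoff=settings.cutoff,
                    k=settings.tap_k,
                )
                per_doc[doc.doc_id] = getattr(ev, METRIC_FIELDS[metric])
            mean, _ = macro_average(per_doc, include_rule)
            fold_means.append(mean)
            per_doc_all.update(
                {k: (0.0 if v is None else v) for k, v in per_doc.items()}
            )
        reports[settings.label()] = EvaluationReport(
            label=settings.label(),
            metric=metric,
            fold_means=fold_means,
            per_doc=per_doc_all,
        )
    return reports


# ---------------------------------------------------------------------------
# Greedy parameter-improvement ladder
# ---------------------------------------------------------------------------

@dataclass
class ImprovementStep:
    from_label: str
    to_label: str
    changed: tuple[str, ...]
    delta_abs: float
    delta_rel: float
    p_value: float
    delta_ci_lower: float
    delta_rel_baseline: float


def _label_fields(label: str) -> tuple[str, ...]:
    parts = label.split("-")
    if len(parts) == 4:  # short form: n0-c0-s0 defaults
        parts = parts + ["n0", "c0", "s0"]
    if len(parts) != 7:
        raise ValidationError(f"cannot parse settings label {label!r}")
    return tuple(parts)


def greedy_parameter_ascent(
    fold_means: Mapping[str, Sequence[float]],
    baseline: str,
    max_changes: int = 3,
) -> list[ImprovementStep]:
    """Greedy ladder: repeatedly apply the best single-parameter change.

    ``fold_means`` maps each setting label in the grid to its per-fold
    macro means.  From the current setting, the single-parameter neighbor
    with the largest mean gain is chosen; only when no single change helps
    are two (then three) simultaneous changes considered.  Each step
    reports the absolute and relative gain, the exact one-sided Wilcoxon
    p-value, the exact lower confidence bound of the gain, and the
    cumulative relative gain over the ladder's first row.
    """
    if baseline not in fold_means:
        raise ValidationError(f"baseline {baseline!r} not in the settings grid")
    fields = {label: _label_fields(label) for label in fold_means}
    baseline_mean = float(np.mean(fold_means[baseline]))
    current = baseline
    steps: list[ImprovementStep] = []
    visited = {current}
    while True:
        current_mean = float(np.mean(fold_means[current]))
        best: tuple[float, str, tuple[str, ...]] | None = None
        for n_changes in range(1, max_changes + 1):
            for label in sorted(fold_means):
                if label in visited:
                    continue
                changed = tuple(
                    name
                    for name, (old, new) in zip(
                        ("zones", "e", "r", "m", "n", "c", "s"),
                        zip(fields[current], fields[label]),
                    )
                    if old != new
                )
                if len(changed) != n_changes:
                    continue
                mean = float(np.mean(fold_means[label]))
                if mean > current_mean and (best is None or mean > best[0]):
                    best = (mean, label, changed)
            if best is not None:
                break
        if best is None:
            return steps
        mean, label, changed = best
        p, ci_lower = paired_wilcoxon(fold_means[current], fold_means[label])
        steps.append(
            ImprovementStep(
                from_label=current,
                to_label=label,
                changed=changed,
                delta_abs=mean - current_mean,
                delta_rel=100.0 * (mean - current_mean) / current_mean
                if current_mean
                else math.inf,
                p_value=p,
                delta_ci_lower=ci_lower,
                delta_rel_baseline=100.0 * (mean - baseline_mean) / baseline_mean
                if baseline_mean
                else math.inf,
            )
        )
        visited.add(label)
        current = label


def write_report(
    steps: Iterable[ImprovementStep],
    fold_means: Mapping[str, Sequence[float]],
    path: str,
) -> None:
    """TSV ladder report: setting, mean, sd, change, gains, p, CI, cumulative."""
    header = (
        "setting\tmean\tsd\tdelta\tdelta_abs\tdelta_rel\tp_value"
        "\tdelta_ci_lower\tdelta_rel_baseline\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        steps = list(steps)
        if steps:
            first = steps[0].from_label
            fm = np.asarray(fold_means[first], dtype=float)
            fh.write(
                f"{first}\t{fm.mean():.4f}\t{fm.std(ddof=1):.4f}\t\t\t\t\t\t\n"
            )
        for step in steps:
            fm = np.asarray(fold_means[step.to_label], dtype=float)
            fh.write(
                f"{step.to_label}\t{fm.mean():.4f}\t{fm.std(ddof=1):.4f}"
                f"\t{'+'.join(step.changed)}\t{step.delta_abs:+.4f}"
                f"\t{step.delta_rel:+.1f}\t{step.p_value:.2e}"
                f"\t{step.delta_ci_lower:+.4f}\t{step.delta_rel_baseline:+.1f}\n"
            )
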