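# relrank

Ranking candidate disease–drug–gene relations in biomedical abstracts for
knowledge-base curation.

## The problem

Curated pharmacogenomics and toxicogenomics knowledge bases (PharmGKB- and
CTD-style resources) record *relations* — undirected pairs of typed
entities (disease, drug, gene) — attached to the article that supports
them. Curators work from ranked lists of candidate relations produced by
text mining; the ranking quality directly determines how many false
candidates a curator must reject before finding the true ones.

`relrank` implements a simple, terminology-agnostic pipeline for this
task:

1. **Term recognition.** Abstracts (title, abstract text, and optionally
   MeSH descriptors/qualifiers and the chemical-substance list — zone
   settings `t`, `tm`, `tc`, `tmc`) are annotated with a typed term
   dictionary by greedy longest match under a lower-cased,
   punctuation-stripped normalization.
2. **Candidate generation.** All pairwise undirected combinations of the
   recognized entities of an article — the maximal-recall strategy, which
   overgenerates and therefore *requires* ranking. (An optional
   same-sentence co-occurrence filter exists but hurts recall: a large
   share of curated relations never co-occur in one sentence.)
3. **Scoring.** The frequency baseline (`m0`) ranks a pair by its
   title-boosted entity frequencies, normalized by the document total:

       relscore(e1, e2) = (f_b(e1) + f_b(e2)) / f(E)

   where a title occurrence counts 10×. The optimized method (`m1`)
   weights each term-form frequency by a **gold probability** — the
   probability, estimated by a conditional maximum-entropy (logistic)
   model, that entity *e* recognized via normalized term form *t* with
   capped count *f^c(t:e)* takes part in a curated relation of the
   article:

       score(e) = Σ_t  f_b(t:e) · P(gold(A,e) = 1 | e, t, f^c(t:e))

   Entity scores combine as a sum (`r0`) or harmonic mean (`r1`), with an
   optional ×0.1 penalty for same-type pairs (`e1`). Count caps
   (`c0,c1,c3,c6,c9`), lower-count smoothing features (`s1`), term-form
   normalization levels (`n0`–`n3`) and a two-stage back-off for unseen
   term-entity pairs control the model's sparsity behaviour.
4. **Evaluation.** Macro-averaged precision/recall/F, AUC iP/R (area under
   the interpolated precision/recall curve) and TAP-k (threshold average
   precision: a curator stops after rejecting k false positives), under
   stratified 10-fold cross-validation with exact paired Wilcoxon
   signed-rank statistics, plus a greedy single-parameter improvement
   ladder and a perfect-ranking upper bound.

A seeded synthetic-corpus generator (`relrank simulate`) emulates the
statistical structure of curated corpora — including ambiguous "trap" term
forms that model recognizer noise — so the whole pipeline is testable
without database snapshots.

## Worked example

```sh
relrank simulate --seed 3 --n-docs 300 --out-dir corpus/
relrank cv \
    --documents corpus/documents.jsonl \
    --dictionary corpus/dictionary.tsv \
    --relations corpus/relations.tsv \
    --settings t-e0-r0-m0 \
    --settings tmc-e1-r1-m1-n3-c6-s1 \
    --metric auc --seed 1 --out-dir reports/
```

prints (one line per setting):

```
t-e0-r0-m0-n0-c0-s0     auc     0.3488  (sd 0.0660)
tmc-e1-r1-m1-n3-c6-s1   auc     0.5550  (sd 0.0553)
```

Each line is the macro-averaged AUC iP/R of that setting, averaged over
the 10 cross-validation folds (models for `m1` are trained on the other
nine folds). The frequency baseline reaches 0.35; weighting frequencies by
learned gold probabilities, adding metadata zones, the same-type penalty
and the harmonic mean lifts it to 0.56 — the trap term forms that inflate
the baseline's rankings are down-weighted by the model. Per-setting JSON
reports with fold means are written to `reports/`.

Settings strings follow the grammar `zones-e-r-m[-n-c-s]`, e.g.
`tmc-e1-r1-m1-n3-c6-s1`; `t-e0-r0-m0` is shorthand for
`t-e0-r0-m0-n0-c0-s0`.

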