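# Methods

## Overview

`relrank` ranks candidate relations between diseases, drugs and genes in
abstract-level biomedical text for curation support. The pipeline is
deliberately shallow — dictionary recognition, exhaustive pair generation,
frequency-and-probability scoring — because its target is not relation
*classification* but a ranking that lets a curator reach the true
relations of an article with few rejections.

## Term recognition

Tokenization splits text into maximal alphanumeric runs; every other
non-space character is its own token. Sentence boundaries are placed after
`.`, `!` or `?` followed by whitespace and an upper-case letter, with a
fixed abbreviation stop-list (`e.g.`, `i.e.`, `Fig.`, `et al.`, ...).
Because the boundary rule requires an upper-case continuation, strings
such as "E. coli" are protected by the case check even though "E." is not
on the stop-list. Sentence structure is consulted only by the optional
same-sentence candidate filter, which is off by default.

Dictionary matching is greedy, longest-first over token sequences, with
both text and dictionary surfaces reduced to a fixed lower-cased,
punctuation-stripped key (the `n1` reduction; punctuation removal is known
not to harm recognition quality). Tokens whose reduction is empty (pure
punctuation) are transparent to matching, so `Fc ( gamma ) - receptor` in
text matches a `fc gamma receptor` dictionary entry. Ambiguity is
preserved: a surface admitting several entities yields one hit per entity
at the same span. Partial matching and acronym generation are deliberately
not implemented; the gold-probability model is the mechanism that absorbs
recognizer noise, and the synthetic generator plants noisy entries to
exercise it.

The configurable normalization *level* (`n0`: lower-cased initial
character per token; `n1`: lower-cased, `' \ ( ) / -` removed; `n2`:
lower-cased alphanumerics per token; `n3`: as `n2` without token
boundaries) does **not** change matching — it controls only the term-form
string used as a model feature. `n0` lower-cases the initial character of
*every* token (the alternative — first token only — is a plausible
reading; per-token was chosen and is flagged here).

MeSH descriptors, MeSH qualifiers and chemical-substance names are matched
as independent strings, carry sentence index −1, count with weight 1 in
frequencies, and can form candidates on their own.

## Candidate generation and frequency scoring

All unordered pairs of distinct recognized entities form the candidate
set. Per entity and normalized term form, raw counts f(t:e) and boosted
counts f_b(t:e) are kept; a title hit counts `title_boost` (default 10,
an empirically sensible boost for abstracts) and every other hit 1. The
baseline relation score is (f_b(e1)+f_b(e2))/f(E); since f(E) is constant
within a document, the normalizer never changes within-document ranking
(asserted as a property test), and it is applied only where the baseline
formula prints it (`m0`/`r0`). Title boosting is treated as a global
setting applied in all methods; setting `title_boost` to 1 disables it.

## Gold-probability model

gold(A, e) is 1 iff entity e takes part in at least one curated relation
of article A. A conditional maximum-entropy (logistic regression) model
estimates P(gold(A,e)=1 | e, t, f^c(t:e)) from joint indicator features
(entity, term form, capped count). Training instances are one per
(document, distinct term form, entity) — prediction must be available per
(t, e) inside the entity score, which rules out coarser granularities.

* **Caps** `c1/c3/c6/c9` clip the count (with `c1` the feature is mere
  presence); `c0` keeps raw counts.
* **Smoothing** `s1` adds a feature at every level 1 ≤ n < f^c, so lower
  levels receive signal from every higher-count instance; under `c1` it
  is vacuous by construction (byte-identical feature sets). With `c0+s1`
  chains are truncated at 50 levels.
* **Fitting** maximizes conditional log-likelihood with no penalty by
  default (L2 available for pathological separability), gradient
  tolerance 1e−6, 200 iterations. Zero penalty preserves the saturated-
  model identity — on disjoint indicator features the fitted probability
  equals the empirical label frequency — which anchors the analytic test
  suite. Separable data is handled by the iteration cap, not by
  regularization. The optimizer is scikit-learn's deterministic lbfgs.
* **Back-off** for a (t, e) pair unseen in training: the mean predicted
  probability of the entity's seen pairs within the same document, else a
  per-type average computed over training-set predictions (a document-
  level averaging population would also be defensible; the training-set
  population was chosen). A bias feature exists, but unseen pairs are
  routed to the explicit back-off rather than the bias-only prediction.
* If every training label is identical the model degenerates to a
  constant probability with a warning.

The entity score under `m1` is Σ_t f_b(t:e) · P(gold | e, t, f^c(t:e));
relation scores are the sum (`r0`) or harmonic mean (`r1`) of the two
entity scores times the type-preference coefficient (`e1`: ×0.1 for
same-type pairs, reflecting how rarely same-type relations are curated).
Ties are broken by canonical pair id for determinism; scores are emitted
raw, rank being the primary output signal.

## Evaluation

All metrics are macro-averaged: computed per article, then averaged.

* **AUC iP/R**: over the top-`cutoff` (default 50) deduplicated list,
  interpolated precision at a recall point is the maximum precision at
  any recall ≥ it within the list; the area averages iP over the gold
  items' recall points, unretrieved gold contributing 0. Not ROC AUC.
* **TAP-k** (default k = 10): precision summed at gold ranks up to the
  rank T of the k-th false positive (or list end if fewer), plus the
  terminal precision at T, divided by |gold|+1; an empty list scores 0.
  Note that TAP-k is *not* monotone in k under this definition: extending
  the threshold past extra false positives without reaching new gold
  items dilutes the terminal term ([TP, FP, FP] scores 0.75 at k=1 and
  ~0.667 at k=2). Both metric definitions are pinned here as normative
  and guarded by exhaustive brute-force oracle tests over all short
  binary lists.
* **Inclusion rules**: ranking metrics default to scoring every document
  with gold relations (prediction-less documents contribute 0); P/R/F
  defaults to ignoring documents without predictions, mirroring the
  original shared-task scorer. Both rules are selectable.
* **Cross-validation** is stratified by relations-per-article (shuffle
  within stratum by seed, deal round-robin); the relation-type mix is
  deliberately not balanced. Fold models are trained on the other nine
  folds.
* **Paired comparison**: exact one-sided Wilcoxon signed-rank p-values by
  enumeration of all 2^n sign assignments (average ranks on tied
  magnitudes, zeros dropped), and the exact one-sided 95% lower
  confidence bound for the shift from Walsh averages. No normal
  approximation is ever used; the smallest attainable p at n=10 is
  1/1024 ≈ 9.8e−4.
* **Greedy ladder**: from a baseline setting, repeatedly apply the
  single-parameter change with the largest macro-mean gain (two or more
  simultaneous changes only when no single change improves), reporting
  absolute/relative gains, exact p, the CI lower bound, and the
  cumulative gain over the baseline.
* **Perfect-ranking bound**: stable partition pushing all true positives
  ahead of all false positives — the ranking ceiling given recognizer
  output.

## Synthetic corpus generator

The generator emulates what the method is sensitive to, not language.
Documents are filler-token sentences (8–15 tokens) with term mentions
spliced in. Defaults define the study conditions:

* 1000 documents, 60 entities per type, 2 unique reliable term forms per
  entity; 12 never-curated trap entities per type whose surfaces are
  shared pairwise (ambiguity), injected ~2 per document with mean 2
  mentions — frequent-but-irrelevant recognizer noise.
* Relations per article follow a geometric-like categorical distribution
  over 1..20 (~40% of articles carry a single relation); the type mix is
  42% drug–gene, 37% disease–gene, 18% disease–drug, 3% same-type.
* Reliable term forms have a planted gold-rate of 0.9 (background,
  non-curated mentions of regular entities supply the other 10%); trap
  forms have 0.05 (a trap injection is occasionally accompanied by a real
  relation involving the trap entity).
* Gold entities: mean 3 abstract mentions vs 1 for background entities;
  title mention with probability 0.5; copied into MeSH (diseases) and the
  chemical list (drugs) with probability 0.8; absent from title/abstract
  entirely with probability 0.15, so metadata zones add genuine recall.
  Related entities co-occur in one sentence with probability 0.7,
  matching the observed ~70% same-sentence share of curated relations.

What passing tests on this corpus show: the maximum-entropy weighting
reliably separates planted reliable from trap forms and beats the
frequency baseline by a large margin under cross-validation, and metadata
zones raise candidate recall and TAP-10. What they do not show: absolute
metric levels on real curated corpora, which depend on recognizer
coverage, real term ambiguity, and database-specific relation
distributions the generator does not model.

## Numerical and interface choices

* Character spans are 0-based half-open; sentence indices are per-zone;
  the title counts as one sentence for the co-occurrence filter.
* Entity identity is (id string, type); the CTD-style type "chemical" is
  read as drug.
* Reflexive gold relations are dropped on load (count logged); duplicate
  unordered pairs collapse silently.
* Duplicate predictions of a pair are collapsed to their best rank before
  evaluation.
* Model persistence is a flat text format with `repr` floats (exact
  round-trip); ranked lists are five-column TSV (doc, id1, id2, rank,
  score) with ids in lexicographic order.
* All randomness flows through seeded numpy generators; identical
  configurations produce byte-identical corpora and reports.

## Known limitations

No partial/acronym matching, coreference or syntactic filtering; no
relation-type labels or directionality; abstracts only; the ranking
favors entities and term forms already seen in training (conservative
bias) — contextual and linguistic features would be the natural next
step.
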