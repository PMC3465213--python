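"""Tokenization, sentence splitting, term-form normalization and
dictionary-based annotation of document zones.

Matching is exact, greedy and longest-first over token sequences, with both
the text and the dictionary surfaces reduced to a fixed lower-cased,
punctuation-stripped key (the ``n1`` reduction below).  The normalization
*level* configured in :class:`~relrank.corpus_model.Settings` does not alter
matching; it only controls the term-form string that is later used as a
feature of the gold-probability model.

Normalization levels of a matched surface (symbol ``t``):

* ``n0`` — each whitespace token keeps its shape except that its initial
  character is lower-cased; tokens joined by single spaces;
* ``n1`` — fully lower-cased, the characters ``' \\ ( ) / -`` removed,
  whitespace squeezed;
* ``n2`` — fully lower-cased, only alphanumeric characters retained within
  tokens, empty tokens dropped;
* ``n3`` — as ``n2`` with token boundaries removed.

So ``"Fc ( gamma ) - receptor"`` becomes ``"fc gamma receptor"`` under
``n1``/``n2`` and ``"fcgammareceptor"`` under ``n3``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_model import Document, EntityId, Settings, TermEntry, Zone

#: characters removed by the n1 normalization
_N1_STRIP = set("'\\()/-")

#: sentence-final token strings that do not end a sentence
SENTENCE_ABBREVIATIONS = frozenset(
    {"e.g.", "i.e.", "Fig.", "Figs.", "al.", "cf.", "vs.", "etc.",
     "approx.", "No.", "St.", "Dr."}
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^A-Za-z0-9\s]")


@dataclass(frozen=True)
class Token:
    """A token with its half-open character span in the source zone."""

    text: str
    start: int
    end: int
    sentence_index: int = -1


@dataclass(frozen=True)
class TermHit:
    """One recognized (surface -> entity) occurrence in a document zone.

    Ambiguous surfaces yield one hit per admissible entity at the same span.
    ``sentence_index`` is -1 in metadata zones, which never take part in the
    same-sentence co-occurrence filter.
    """

    doc_id: str
    zone: Zone
    sentence_index: int
    start: int
    end: int
    surface: str
    entity: EntityId


def tokenize(text: str) -> list[Token]:
    """Split text into maximal alphanumeric runs plus single symbol tokens."""
    return [
        Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)
    ]


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Partition ``text`` into sentence intervals (half-open char spans).

    A boundary is placed after ``.``, ``!`` or ``?`` when followed by
    whitespace and an upper-case letter, unless the terminator closes a
    token on the abbreviation stop-list (``e.g.``, ``et al.``, ``Fig.`` ...).
    """
    if not text:
        return []
    boundaries: list[int] = []
    for m in re.finditer(r"[.!?]", text):
        end = m.end()
        rest = text[end:]
        stripped = rest.lstrip()
        if not stripped or stripped == rest or not stripped[0].isupper():
            continue
        # token ending at the terminator, including the terminator itself
        prev = re.search(r"(\S+)$", text[:end])
        if prev and prev.group(1) in SENTENCE_ABBREVIATIONS:
            continue
        boundaries.append(end)
    spans: list[tuple[int, int]] = []
    start = 0
    for b in boundaries:
        spans.append((start, b))
        start = b
    spans.append((start, len(text)))
    return spans


def normalize_term_form(surface: str, level: str) -> str:
    """Normalize a surface string at level ``n0``..``n3`` (idempotent)."""
    if level == "n0":
        tokens = surface.split()
        return " ".join(t[0].lower() + t[1:] if t else t for t in tokens)
    if level == "n1":
        lowered = surface.lower()
        kept = "".join(c for c in lowered if c not in _N1_STRIP)
        return " ".join(kept.split())
    if level in ("n2", "n3"):
        tokens = [
            "".join(c for c in tok.lower() if c.isalnum())
            for tok in surface.split()
        ]
        tokens = [t for t in tokens if t]
        return ("" if level == "n3" else " ").join(tokens)
    raise ValueError(f"unknown normalization level {level!r}")


def _match_key_tokens(surface: str) -> tuple[str, ...]:
    """Matcher key: per-token n1 reduction with empty tokens dropped."""
    out = []
    for tok in tokenize(surface):
        reduced = "".join(c for c in tok.text.lower() if c not in _N1_STRIP)
        if reduced:
            out.append(reduced)
    return tuple(out)


class TermMatcher:
    """Dictionary index supporting greedy longest-match annotation.

    Surfaces are indexed as tuples of n1-reduced tokens; matching skips
    text tokens whose reduction is empty (pure punctuation), so
    ``Fc ( gamma ) - receptor`` in text matches a ``fc gamma receptor``
    dictionary entry across six raw tokens.
    """

    def __init__(self, entries: Iterable[TermEntry]) -> None:
        self._index: dict[tuple[str, ...], set[EntityId]] = {}
        self.max_len = 0
        for entry in entries:
            key = _match_key_tokens(entry.surface)
            if not key:
                continue
            self._index.setdefault(key, set()).add(entry.entity)
            self.max_len = max(self.max_len, len(key))

    def __len__(self) -> int:
        return len(self._index)

    def match_zone(
        self,
        doc_id: str,
        zone: Zone,
        text: str,
        sentence_spans: Sequence[tuple[int, int]] | None = None,
    ) -> list[TermHit]:
        tokens = tokenize(text)
        reduced = [
            "".join(c for c in t.text.lower() if c not in _N1_STRIP)
            for t in tokens
        ]
        content = [i for i, r in enumerate(reduced) if r]

        def sent_index(pos: int) -> int:
            if sentence_spans is None:
                return -1
            for idx, (s, e) in enumerate(sentence_spans):
                if s <= pos < e:
                    return idx
            return len(sentence_spans) - 1 if sentence_spans else -1

        hits: list[TermHit] = []
        ci = 0
        while ci < len(content):
            best_len = 0
            best_entities: set[EntityId] | None = None
            # longest-first over content (non-empty) tokens
            limit = min(self.max_len, len(content) - ci)
            key: list[str] = []
            candidates: list[tuple[int, set[EntityId]]] = []
            for l in range(1, limit + 1):
                key.append(reduced[content[ci + l - 1]])
                ents = self._index.get(tuple(key))
                if ents:
                    candidates.append((l, ents))
            if candidates:
                best_len, best_entities = candidates[-1]
                first_tok = tokens[content[ci]]
                last_tok = tokens[content[ci + best_len - 1]]
                surface = text[first_tok.start : last_tok.end]
                si = sent_index(first_tok.start)
                for entity in sorted(best_entities):
                    hits.append(
                        TermHit(
                            doc_id=doc_id,
                            zone=zone,
                            sentence_index=si,
                            start=first_tok.start,
                            end=last_tok.end,
                            surface=surface,
                            entity=entity,
                        )
                    )
                ci += best_len
            else:
                ci += 1
        return hits


def annotate(
    doc: Document,
    dictionary: Iterable[TermEntry] | TermMatcher,
    zones: str | Settings = "t",
) -> list[TermHit]:
    """Annotate a document's active zones with dictionary term hits.

    ``zones`` is a zone setting (``t``/``tm``/``tc``/``tmc``) or a full
    :class:`Settings`.  The title counts as a single sentence (index 0);
    abstract sentences are indexed by the splitter; MeSH descriptors,
    qualifiers and chemical names are matched as independent strings with
    sentence index -1.
    """
    settings = zones if isinstance(zones, Settings) else Settings(zones=zones)
    matcher = (
        dictionary if isinstance(dictionary, TermMatcher) else TermMatcher(dictionary)
    )
    active = settings.active_zones
    hits: list[TermHit] = []
    hits.extend(
        matcher.match_zone(doc.doc_id, Zone.TITLE, doc.title, [(0, len(doc.title))])
    )
    hits.extend(
        matcher.match_zone(
            doc.doc_id, Zone.ABSTRACT, doc.abstract, split_sentences(doc.abstract)
        )
    )
    if Zone.MESH in active:
        for descriptor, qualifiers in doc.mesh:
            hits.extend(matcher.match_zone(doc.doc_id, Zone.MESH, descriptor))
            for qualifier in qualifiers:
                hits.extend(matcher.match_zone(doc.doc_id, Zone.MESH, qualifier))
    if Zone.CHEMICALS in active:
        for name in doc.chemicals:
            hits.extend(matcher.match_zone(doc.doc_id, Zone.CHEMICALS, name))
    return hits


def write_annotation_dump(hits: Iterable[TermHit], path: str) -> None:
    """Debugging TSV: doc, zone, sentence, span, surface, entity id, type."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                f"{h.doc_id}\t{h.zone.value}\t{h.sentence_index}\t{h.start}"
                f"\t{h.end}\t{h.surface}\t{h.entity.id}\t{h.entity.type.value}\n"
            )
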