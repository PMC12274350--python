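"""Mention detection and positive/non-positive classification.

Candidate mentions are found by regular-expression stem matching (or, for
visual hallucinations, a same-sentence proximity rule over two stems).
Each candidate is then classified by NegEx-style context rules: a
negation, uncertainty or wrong-experiencer cue scoping over the span in
the same sentence makes the mention non-positive; otherwise it is
positive. The rule path is the shipped default; a trained classifier
(see :mod:`dlbtext.classifier`) can be substituted.
"""
from __future__ import annotations

import re
from functools import lru_cache
from typing import Iterable, Protocol

import pandas as pd

from .lexicon import (ConceptLexicon, CueLexicon, default_cues,
                      default_lexicons)
from .types import (ClinicalDocument, Concept, MentionCandidate, MentionLabel,
                    POSITIVE, non_positive)

_SENT_BOUNDARY = re.compile(r"[.!?\n](?=\s|$)")
_WORD = re.compile(r"[a-z0-9]+", re.IGNORECASE)

#: Token-gap scope of a cue relative to the candidate span, within one
#: sentence: at most this many tokens between cue and candidate.
CUE_SCOPE_BEFORE = 6
CUE_SCOPE_AFTER = 6

_CUE_PRIORITY = {"negated": 0, "unknown": 1, "irrelevant": 2}


def sentence_spans(text: str) -> list[tuple[int, int]]:
    """Half-open character spans of sentences.

    Sentences end at ``.``, ``!``, ``?`` or a newline followed by
    whitespace or end of text; the terminator belongs to the sentence.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        spans.append((start, m.end()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return [(s, e) for s, e in spans if text[s:e].strip()]


def _tokens(text: str) -> list[tuple[str, int, int]]:
    """Lowercased word tokens with character offsets."""
    return [(m.group(0).lower(), m.start(), m.end())
            for m in _WORD.finditer(text)]


@lru_cache(maxsize=None)
def _compiled_patterns(lexicon: ConceptLexicon):
    return lexicon.compiled()


@lru_cache(maxsize=None)
def _compiled_proximity(lexicon: ConceptLexicon):
    assert lexicon.proximity_rule is not None
    return lexicon.proximity_rule.regexes()


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(spans):
        if merged and lo < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def find_candidates(text: str, lexicon: ConceptLexicon,
                    doc_id: str = "") -> list[MentionCandidate]:
    """All maximal matches of a concept in ``text``, ordered by offset.

    Overlapping matches of the same concept are merged into a single
    candidate; the context attached to each candidate is the sentence
    containing the span.
    """
    if not text:
        return []
    sentences = sentence_spans(text)
    spans: list[tuple[int, int]] = []

    if lexicon.proximity_rule is not None:
        re_a, re_b = _compiled_proximity(lexicon)
        max_gap = lexicon.proximity_rule.max_gap
        for s_lo, s_hi in sentences:
            toks = _tokens(text[s_lo:s_hi])
            idx_a = [i for i, (t, _, _) in enumerate(toks) if re_a.match(t)]
            idx_b = [i for i, (t, _, _) in enumerate(toks) if re_b.match(t)]
            for i in idx_a:
                for j in idx_b:
                    if i != j and abs(i - j) - 1 <= max_gap:
                        lo = min(toks[i][1], toks[j][1]) + s_lo
                        hi = max(toks[i][2], toks[j][2]) + s_lo
                        spans.append((lo, hi))
    else:
        for pattern in _compiled_patterns(lexicon):
            spans.extend(m.span() for m in pattern.finditer(text))

    candidates = []
    for lo, hi in _merge_spans(spans):
        s_lo, s_hi = next(((a, b) for a, b in sentences if a <= lo < b),
                          (0, len(text)))
        candidates.append(MentionCandidate(
            doc_id=doc_id, concept=lexicon.concept, start=lo, end=hi,
            context=text[s_lo:s_hi], context_start=s_lo))
    return candidates


def classify_mention(cand: MentionCandidate,
                     cues: CueLexicon | None = None) -> MentionLabel:
    """Rule-based positive vs non-positive call for one candidate.

    A cue within :data:`CUE_SCOPE_BEFORE` tokens upstream or
    :data:`CUE_SCOPE_AFTER` tokens downstream of the span (same
    sentence) makes the mention non-positive; the nearest cue decides
    the sublabel, ties resolved conservatively towards negation. A ``?``
    immediately prefixed to the span is an uncertainty cue.
    """
    cues = cues or default_cues()
    rel_lo = cand.start - cand.context_start
    rel_hi = cand.end - cand.context_start
    toks = _tokens(cand.context)
    cand_idx = [i for i, (_, lo, hi) in enumerate(toks)
                if lo < rel_hi and rel_lo < hi]
    if not cand_idx:  # span matched no word token (should not happen)
        return POSITIVE
    first, last = cand_idx[0], cand_idx[-1]

    hits: list[tuple[int, int, str]] = []  # (gap, priority, sublabel)
    if cand.context[:rel_lo].rstrip().endswith("?"):
        hits.append((0, _CUE_PRIORITY["unknown"], "unknown"))

    token_strings = [t for t, _, _ in toks]
    for cue, sublabel in _token_cues(cues):
        n = len(cue)
        for i in range(len(toks) - n + 1):
            if tuple(token_strings[i:i + n]) != cue:
                continue
            cue_first, cue_last = i, i + n - 1
            if cue_last < first:
                gap = first - cue_last - 1
                if gap <= CUE_SCOPE_BEFORE:
                    hits.append((gap, _CUE_PRIORITY[sublabel], sublabel))
            elif cue_first > last:
                gap = cue_first - last - 1
                if gap <= CUE_SCOPE_AFTER:
                    hits.append((gap, _CUE_PRIORITY[sublabel], sublabel))

    if not hits:
        return POSITIVE
    hits.sort()
    return non_positive(hits[0][2])


@lru_cache(maxsize=None)
def _token_cues(cues: CueLexicon):
    return tuple(cues.token_cues())


class MentionClassifierProtocol(Protocol):
    def predict(self, candidates: list[MentionCandidate]) -> list[MentionLabel]:
        ...


def extract_document(doc: ClinicalDocument,
                     lexicons: dict[Concept, ConceptLexicon] | None = None,
                     classifier: MentionClassifierProtocol | CueLexicon | None = None,
                     ) -> list[tuple[MentionCandidate, MentionLabel]]:
    """Find and classify all concept mentions in one document."""
    lexicons = lexicons or default_lexicons()
    candidates: list[MentionCandidate] = []
    for lexicon in lexicons.values():
        candidates.extend(find_candidates(doc.text, lexicon, doc_id=doc.doc_id))
    candidates.sort(key=lambda c: (c.start, c.concept.value))
    if classifier is None or isinstance(classifier, CueLexicon):
        labels = [classify_mention(c, classifier) for c in candidates]
    else:
        labels = classifier.predict(candidates)
    return list(zip(candidates, labels))


MENTION_COLUMNS = ["doc_id", "concept", "start", "end", "label", "sublabel"]


def extract_corpus(documents: Iterable[ClinicalDocument],
                   lexicons: dict[Concept, ConceptLexicon] | None = None,
                   classifier: MentionClassifierProtocol | CueLexicon | None = None,
                   ) -> pd.DataFrame:
    """Run extraction over a corpus; one row per labelled mention."""
    rows = []
    for doc in documents:
        for cand, label in extract_document(doc, lexicons, classifier):
            rows.append((cand.doc_id, cand.concept.value, cand.start,
                         cand.end, label.label, label.sublabel))
    return pd.DataFrame(rows, columns=MENTION_COLUMNS)
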