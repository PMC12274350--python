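"""Candidate detection and mention classification."""
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlbtext.extract import (classify_mention, extract_document,
                             find_candidates, sentence_spans)
from dlbtext.lexicon import default_cues, default_lexicons
from dlbtext.types import ClinicalDocument, Concept

LEX = default_lexicons()

# Clinical example snippets and the side of the positive/non-positive
# divide each belongs to.
POSITIVE_SNIPPETS = [
    ("responding to visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("experiencing visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("history of visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("distressed by visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("mood has been fluctuating a lot", Concept.FLUCTUATIONS),
    ("suicidal thoughts appear to fluctuate", Concept.FLUCTUATIONS),
    ("fluctuating attention", Concept.FLUCTUATIONS),
    ("fluctuating cognitive impairment", Concept.FLUCTUATIONS),
    ("there was evidence of a tremor when writing", Concept.TREMOR),
    ("with a degree of resting tremor", Concept.TREMOR),
    ("presence of bradykinesia", Concept.BRADYKINESIA),
    ("motor symptoms - moderate bradykinesia L > R", Concept.BRADYKINESIA),
    ("had a bad dream last night", Concept.BAD_DREAMS),
    ("frequently has bad dreams", Concept.BAD_DREAMS),
    ("unsettled sleep with vivid nightmares", Concept.NIGHTMARES),
]
NON_POSITIVE_SNIPPETS = [
    ("denied any visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("not experiencing visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("not responding to visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("no current visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("no visual hallucinations", Concept.VISUAL_HALLUCINATIONS),
    ("no evidence of mood fluctuation", Concept.FLUCTUATIONS),
    ("does not appear to have significant fluctuations in mental state",
     Concept.FLUCTUATIONS),
    ("monitoring to see if fluctuations deteriorate", Concept.FLUCTUATIONS),
    ("his mother's responsibility fluctuated", Concept.FLUCTUATIONS),
    ("the person's risk is likely to fluctuate", Concept.FLUCTUATIONS),
]


def one_candidate(text: str, concept: Concept):
    cands = find_candidates(text, LEX[concept])
    assert len(cands) == 1, (text, cands)
    return cands[0]


@pytest.mark.parametrize("text,concept", POSITIVE_SNIPPETS)
def test_reference_snippets_positive(text, concept):
    label = classify_mention(one_candidate(text, concept), default_cues())
    assert label.is_positive, text


@pytest.mark.parametrize("text,concept", NON_POSITIVE_SNIPPETS)
def test_reference_snippets_non_positive(text, concept):
    label = classify_mention(one_candidate(text, concept), default_cues())
    assert not label.is_positive, text


def test_sublabels_follow_cue_class():
    neg = classify_mention(one_candidate(
        "no evidence of mood fluctuation", Concept.FLUCTUATIONS))
    unk = classify_mention(one_candidate(
        "monitoring to see if fluctuations deteriorate", Concept.FLUCTUATIONS))
    irr = classify_mention(one_candidate(
        "his mother's responsibility fluctuated", Concept.FLUCTUATIONS))
    q = classify_mention(one_candidate(
        "?visual hallucinations", Concept.VISUAL_HALLUCINATIONS))
    assert neg.sublabel == "negated"
    assert unk.sublabel == "unknown"
    assert irr.sublabel == "irrelevant"
    assert q.sublabel == "unknown"


def test_empty_text_yields_no_candidates():
    for lexicon in LEX.values():
        assert find_candidates("", lexicon) == []


def test_candidate_offsets_and_order():
    text = "A fine tremor was noted. Later a resting tremor was seen."
    cands = find_candidates(text, LEX[Concept.TREMOR])
    assert [text[c.start:c.end] for c in cands] == ["tremor", "tremor"]
    assert cands[0].start < cands[1].start
    assert all(c.context == text[c.context_start:c.context_start
                                 + len(c.context)] for c in cands)


def test_negation_does_not_cross_sentence_boundary():
    text = "Symptoms were denied last week. Tremor evident on examination."
    cand = one_candidate(text, Concept.TREMOR)
    assert classify_mention(cand).is_positive


def test_negation_scope_limited_to_six_tokens():
    far = ("not one of the many colleagues present at the long review "
           "mentioned tremor")
    cand = one_candidate(far, Concept.TREMOR)
    assert classify_mention(cand).is_positive


def test_no_overlapping_candidates_per_concept():
    text = "visual hallucinations and visual hallucinations of hallucinations"
    cands = find_candidates(text, LEX[Concept.VISUAL_HALLUCINATIONS])
    for a, b in zip(cands, cands[1:]):
        assert a.end <= b.start


def _brute_force_vh(text: str, window: int) -> bool:
    """Exhaustive token-pair scan for visual + hallucinat* within a gap."""
    found = False
    for s_lo, s_hi in sentence_spans(text):
        toks = [m.group(0).lower()
                for m in re.finditer(r"[a-z0-9]+", text[s_lo:s_hi],
                                     re.IGNORECASE)]
        for i, a in enumerate(toks):
            for j, b in enumerate(toks):
                if (i != j and a == "visual" and b.startswith("hallucinat")
                        and abs(i - j) - 1 <= window):
                    found = True
    return found


@pytest.mark.parametrize("text", [
    "visually striking hallucinatory experience",
    "visual hallucinations reported",
    "visual disturbance with occasional hallucinations",
    "hallucinations that are clearly visual in nature",
    "visual field intact but one two three four five hallucinations later",
    "Visual acuity normal. Hallucinations denied.",
    "no relevant text here",
])
@pytest.mark.parametrize("window", [0, 2, 5, 8])
def test_proximity_rule_matches_exhaustive_pair_scan(text, window):
    from dlbtext.lexicon import ConceptLexicon, ProximityRule
    lexicon = ConceptLexicon(
        concept=Concept.VISUAL_HALLUCINATIONS,
        proximity_rule=ProximityRule("visual", "hallucinat*", window))
    got = bool(find_candidates(text, lexicon))
    assert got == _brute_force_vh(text, window), (text, window)


@pytest.mark.parametrize("concept", list(Concept))
def test_case_insensitivity(concept, small_corpus):
    docs = [d for d in small_corpus.documents][:40]
    for doc in docs:
        lower = find_candidates(doc.text, LEX[concept])
        upper = find_candidates(doc.text.upper(), LEX[concept])
        assert ([(c.start, c.end) for c in lower]
                == [(c.start, c.end) for c in upper])


def test_adding_a_sentence_preserves_existing_candidates(small_corpus):
    extra = " Reviewed by the community team without concerns."
    for doc in small_corpus.documents[:40]:
        for concept in Concept:
            before = {(c.start, c.end)
                      for c in find_candidates(doc.text, LEX[concept])}
            after = {(c.start, c.end)
                     for c in find_candidates(doc.text + extra, LEX[concept])}
            assert before <= after


def test_extract_document_composes_all_concepts():
    doc = ClinicalDocument(
        "d1", "p1",
        "Presence of bradykinesia. Unsettled sleep with vivid nightmares. "
        "Denied any visual hallucinations.")
    results = extract_document(doc)
    by_concept = {c.concept: lab for c, lab in results}
    assert by_concept[Concept.BRADYKINESIA].is_positive
    assert by_concept[Concept.NIGHTMARES].is_positive
    assert not by_concept[Concept.VISUAL_HALLUCINATIONS].is_positive
    assert len(results) == 3


def test_distractor_only_document_is_empty():
    doc = ClinicalDocument("d1", "p1",
                           "Attended clinic. Medication reviewed. "
                           "Appetite remains good.")
    assert extract_document(doc) == []


WORDS = ["tremor", "no", "not", "denied", "visual", "hallucinations",
         "fluctuating", "bad", "dream", "nightmares", "the", "patient",
         "review", "mood", "sleep", "bradykinesia", "daughter", "?"]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(WORDS), min_size=0, max_size=25))
def test_extraction_invariants_on_random_word_soup(words):
    text = " ".join(words)
    doc_ok = bool(text.strip())
    for concept in Concept:
        cands = find_candidates(text, LEX[concept], doc_id="d")
        starts = [c.start for c in cands]
        assert starts == sorted(starts)
        for a, b in zip(cands, cands[1:]):
            assert a.end <= b.start
        for cand in cands:
            assert cand.concept == concept
            assert 0 <= cand.start < cand.end <= len(text)
            assert cand.span_text == text[cand.start:cand.end]
            label = classify_mention(cand)
            assert label.is_positive == (label.sublabel == "none")
    if doc_ok:
        extract_document(ClinicalDocument("d", "p", text))
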