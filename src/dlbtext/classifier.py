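"""Optional trainable mention classifier.

A supervised stand-in for the machine-learning annotators used in
register-scale symptom extraction: bag-of-words features over the
candidate's sentence, logistic regression, binarized to
positive/non-positive. It is OFF by default — the deterministic rule
path in :mod:`dlbtext.extract` is the shipped behaviour — and is
trained only on (synthetic) gold annotations supplied by the caller.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from .extract import classify_mention
from .lexicon import CueLexicon
from .types import (ClinicalDocument, GoldAnnotation, GoldLabel,
                    MentionCandidate, MentionLabel, POSITIVE, non_positive)


@dataclass
class MentionClassifier:
    """Bag-of-words positive/non-positive classifier with rule fallback.

    When ``fallback`` is set (degenerate single-class training corpus)
    prediction delegates entirely to the rule path. When the model
    predicts non-positive, the sublabel is taken from the rule path if
    it also rejects the mention, else coded ``unknown``.
    """

    pipeline: Pipeline | None
    fallback: bool = False
    cues: CueLexicon | None = None

    def predict(self, candidates: list[MentionCandidate]) -> list[MentionLabel]:
        if not candidates:
            return []
        rule_labels = [classify_mention(c, self.cues) for c in candidates]
        if self.fallback or self.pipeline is None:
            return rule_labels
        preds = self.pipeline.predict([c.context.lower() for c in candidates])
        out: list[MentionLabel] = []
        for pred, rule in zip(preds, rule_labels):
            if pred == "positive":
                out.append(POSITIVE)
            elif not rule.is_positive:
                out.append(rule)
            else:
                out.append(non_positive("unknown"))
        return out


def training_examples_from_gold(
        documents: list[ClinicalDocument],
        gold: list[GoldAnnotation]) -> list[tuple[str, str]]:
    """(sentence, binary label) pairs from gold annotations.

    The sentence containing each gold span is the feature context;
    negative and unknown gold labels collapse to ``non_positive``.
    """
    from .extract import sentence_spans

    by_doc = {d.doc_id: d.text for d in documents}
    examples = []
    for ann in gold:
        text = by_doc[ann.doc_id]
        s_lo, s_hi = next(((a, b) for a, b in sentence_spans(text)
                           if a <= ann.start < b), (0, len(text)))
        label = ("positive" if ann.label == GoldLabel.POSITIVE
                 else "non_positive")
        examples.append((text[s_lo:s_hi].lower(), label))
    return examples


def train_mention_classifier(examples: list[tuple[str, str]],
                             cues: CueLexicon | None = None,
                             seed: int = 0) -> MentionClassifier:
    """Fit the classifier on (context, label) pairs.

    Deterministic given the examples and seed. A single-class corpus
    cannot support a discriminative model: the classifier is returned
    with ``fallback=True`` and a warning.
    """
    labels = {lab for _, lab in examples}
    if len(labels) < 2:
        warnings.warn("training corpus has a single class; "
                      "falling back to rule-based classification",
                      stacklevel=2)
        return MentionClassifier(pipeline=None, fallback=True, cues=cues)
    pipeline = Pipeline([
        ("vectorize", CountVectorizer(ngram_range=(1, 2), lowercase=True)),
        ("model", LogisticRegression(max_iter=1000, random_state=seed)),
    ])
    pipeline.fit([ctx for ctx, _ in examples], [lab for _, lab in examples])
    return MentionClassifier(pipeline=pipeline, fallback=False, cues=cues)
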