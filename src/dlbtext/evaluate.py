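"""Precision/recall scoring of extraction output against gold annotations.

Only positive calls count as retrieved entities and only gold positives
count as relevant entities; negated and uncertain gold mentions are
non-entities, mirroring how register NLP applications fold negations
into the unwanted class. A predicted positive matches a gold positive
of the same concept in the same document when their spans overlap
(default) or coincide exactly (``match_rule="exact"``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Concept


@dataclass(frozen=True)
class EvalMetrics:
    """Per-concept true/false positive and false negative counts.

    ``precision`` / ``recall`` are ``None`` (not silently zero) when
    their denominator is empty.
    """

    concept: Concept
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None


def _as_spans(df: pd.DataFrame) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Group span lists by (doc_id, concept), sorted by start offset."""
    out: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for doc_id, concept, start, end in zip(df["doc_id"], df["concept"],
                                           df["start"], df["end"]):
        out.setdefault((doc_id, concept), []).append((int(start), int(end)))
    for spans in out.values():
        spans.sort()
    return out


def _match_count(pred: list[tuple[int, int]], gold: list[tuple[int, int]],
                 exact: bool) -> int:
    """Greedy one-to-one matching of predicted and gold spans."""
    used = [False] * len(gold)
    tp = 0
    for p_lo, p_hi in pred:
        for k, (g_lo, g_hi) in enumerate(gold):
            if used[k]:
                continue
            hit = ((p_lo, p_hi) == (g_lo, g_hi) if exact
                   else p_lo < g_hi and g_lo < p_hi)
            if hit:
                used[k] = True
                tp += 1
                break
    return tp


def score_extraction(predicted: pd.DataFrame, gold: pd.DataFrame,
                     match_rule: str = "overlap") -> list[EvalMetrics]:
    """Score predicted positive mentions against gold annotations.

    ``predicted`` needs doc_id/concept/start/end and (optionally) a
    ``label`` column, from which only ``positive`` rows are kept;
    ``gold`` needs the same plus a gold ``label`` column from which only
    ``positive`` rows count as relevant entities.
    """
    if match_rule not in ("overlap", "exact"):
        raise ValueError(f"unknown match_rule: {match_rule!r}")
    for df in (predicted, gold):
        bad = set(df["concept"]) - {c.value for c in Concept}
        if bad:
            raise ValueError(f"unknown concept names: {sorted(bad)}")
    if "label" in predicted.columns:
        predicted = predicted[predicted["label"] == "positive"]
    gold = gold[gold["label"] == "positive"]

    pred_spans = _as_spans(predicted)
    gold_spans = _as_spans(gold)
    exact = match_rule == "exact"

    metrics = []
    for concept in Concept:
        tp = fp = fn = 0
        keys = ({k for k in pred_spans if k[1] == concept.value}
                | {k for k in gold_spans if k[1] == concept.value})
        for key in keys:
            pred = pred_spans.get(key, [])
            g = gold_spans.get(key, [])
            hits = _match_count(pred, g, exact)
            tp += hits
            fp += len(pred) - hits
            fn += len(g) - hits
        metrics.append(EvalMetrics(concept, tp, fp, fn))
    return metrics


def document_level_metrics(predicted: pd.DataFrame,
                           gold: pd.DataFrame) -> list[EvalMetrics]:
    """Presence/absence scoring per document instead of per mention."""
    if "label" in predicted.columns:
        predicted = predicted[predicted["label"] == "positive"]
    gold = gold[gold["label"] == "positive"]
    metrics = []
    for concept in Concept:
        pred_docs = set(predicted.loc[predicted["concept"] == concept.value,
                                      "doc_id"])
        gold_docs = set(gold.loc[gold["concept"] == concept.value, "doc_id"])
        tp = len(pred_docs & gold_docs)
        metrics.append(EvalMetrics(concept, tp, len(pred_docs) - tp,
                                   len(gold_docs) - tp))
    return metrics


def metrics_frame(metrics: list[EvalMetrics]) -> pd.DataFrame:
    """Tabular form with header concept,tp,fp,fn,precision,recall."""
    rows = [(m.concept.value, m.tp, m.fp, m.fn,
             m.precision if m.precision is not None else float("nan"),
             m.recall if m.recall is not None else float("nan"))
            for m in metrics]
    return pd.DataFrame(rows, columns=["concept", "tp", "fp", "fn",
                                       "precision", "recall"])


def sample_test_corpus(documents: list, n_docs: int, seed: int) -> list:
    """Uniform without-replacement sample of documents, seeded.

    Returned documents keep their original corpus order, emulating the
    fixed-size held-out document sets used to benchmark extraction.
    """
    if n_docs > len(documents):
        raise ValueError(f"requested {n_docs} documents from a corpus "
                         f"of {len(documents)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(documents), size=n_docs, replace=False)
    return [documents[i] for i in sorted(idx)]
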