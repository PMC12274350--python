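"""Sentence templates for the synthetic note generator.

Each template is a clinical-style sentence carrying exactly one concept
mention, split into prefix / keyword / suffix so the generator knows the
exact character span of the keyword region and can emit a gold
annotation without re-parsing its own output. The bank is table-driven
on purpose: no free paraphrasing, so gold labels and spans stay exact.

Positive, negated and uncertain phrasings follow the conventions of
memory-clinic correspondence (symptom asserted, symptom denied or absent
on examination, symptom queried or hypothetical / about a relative).
Distractors are neutral sentences containing none of the concept
keywords.
"""
from __future__ import annotations

from dataclasses import dataclass

from .types import Concept, GoldLabel


@dataclass(frozen=True)
class Template:
    concept: Concept
    label: GoldLabel
    prefix: str
    keyword: str
    suffix: str

    @property
    def sentence(self) -> str:
        return self.prefix + self.keyword + self.suffix

    @property
    def keyword_span(self) -> tuple[int, int]:
        return len(self.prefix), len(self.prefix) + len(self.keyword)


def _t(concept: Concept, label: GoldLabel,
       prefix: str, keyword: str, suffix: str = "") -> Template:
    return Template(concept, label, prefix, keyword, suffix)


_P, _N, _U = GoldLabel.POSITIVE, GoldLabel.NEGATIVE, GoldLabel.UNKNOWN
_VH = Concept.VISUAL_HALLUCINATIONS
_FL = Concept.FLUCTUATIONS
_TR = Concept.TREMOR
_BK = Concept.BRADYKINESIA
_BD = Concept.BAD_DREAMS
_NM = Concept.NIGHTMARES

TEMPLATES: dict[tuple[Concept, GoldLabel], tuple[Template, ...]] = {
    (_VH, _P): (
        _t(_VH, _P, "appears to be responding to ", "visual hallucinations"),
        _t(_VH, _P, "currently experiencing ", "visual hallucinations",
           " of small animals"),
        _t(_VH, _P, "there is a history of ", "visual hallucinations"),
        _t(_VH, _P, "remains distressed by ", "visual hallucinations",
           " most evenings"),
        _t(_VH, _P, "describes vivid ", "visual hallucinations",
           " of people in the room"),
    ),
    (_VH, _N): (
        _t(_VH, _N, "denied any ", "visual hallucinations"),
        _t(_VH, _N, "not responding to ", "visual hallucinations"),
        _t(_VH, _N, "no current ", "visual hallucinations"),
        _t(_VH, _N, "no ", "visual hallucinations", " reported at review"),
    ),
    (_VH, _U): (
        _t(_VH, _U, "?", "visual hallucinations", " to be reviewed"),
        _t(_VH, _U, "query ", "visual hallucinations", " at night"),
    ),
    (_FL, _P): (
        _t(_FL, _P, "mood has been ", "fluctuating", " a lot recently"),
        _t(_FL, _P, "suicidal thoughts appear to ", "fluctuate"),
        _t(_FL, _P, "", "fluctuating", " attention noted during assessment"),
        _t(_FL, _P, "", "fluctuating", " cognitive impairment over the week"),
        _t(_FL, _P, "presentation ", "fluctuates", " markedly from day to day"),
    ),
    (_FL, _N): (
        _t(_FL, _N, "no evidence of mood ", "fluctuation"),
        _t(_FL, _N, "does not appear to have significant ", "fluctuations",
           " in mental state"),
        _t(_FL, _N, "no diurnal ", "fluctuation", " observed on the ward"),
    ),
    (_FL, _U): (
        _t(_FL, _U, "monitoring to see if ", "fluctuations", " deteriorate"),
        _t(_FL, _U, "their mother's responsibility ", "fluctuated",
           " over the years"),
        _t(_FL, _U, "the risk is likely to ", "fluctuate"),
    ),
    (_TR, _P): (
        _t(_TR, _P, "there was evidence of a ", "tremor", " when writing"),
        _t(_TR, _P, "presents with a degree of resting ", "tremor"),
        _t(_TR, _P, "a fine ", "tremor", " was noted in both hands"),
    ),
    (_TR, _N): (
        _t(_TR, _N, "no resting ", "tremor", " observed on examination"),
        _t(_TR, _N, "denies any ", "tremor", " or shakiness"),
    ),
    (_TR, _U): (
        _t(_TR, _U, "monitoring to see if the ", "tremor", " worsens"),
    ),
    (_BK, _P): (
        _t(_BK, _P, "examination confirmed the presence of ", "bradykinesia"),
        _t(_BK, _P, "motor symptoms - moderate ", "bradykinesia", " L > R"),
        _t(_BK, _P, "gait assessment revealed ", "bradykinesia",
           " and reduced arm swing"),
    ),
    (_BK, _N): (
        _t(_BK, _N, "no ", "bradykinesia", " on examination today"),
        _t(_BK, _N, "without obvious ", "bradykinesia", " or rigidity"),
    ),
    (_BD, _P): (
        _t(_BD, _P, "had a ", "bad dream", " last night and woke shouting"),
        _t(_BD, _P, "frequently has ", "bad dreams"),
        _t(_BD, _P, "carer reports recurrent ", "bad dreams",
           " disturbing sleep"),
    ),
    (_BD, _N): (
        _t(_BD, _N, "denies any ", "bad dreams"),
        _t(_BD, _N, "no ", "bad dreams", " in recent weeks"),
    ),
    (_NM, _P): (
        _t(_NM, _P, "unsettled sleep with vivid ", "nightmares"),
        _t(_NM, _P, "troubled by frequent ", "nightmares",
           " and calling out in sleep"),
    ),
    (_NM, _N): (
        _t(_NM, _N, "no ", "nightmares", " reported by family"),
        _t(_NM, _N, "denied ", "nightmares", " or disturbed sleep"),
    ),
}

#: Neutral filler sentences; none contains a concept keyword.
DISTRACTORS: tuple[str, ...] = (
    "attended the memory clinic accompanied by a neighbour",
    "medication reviewed and repeat prescription issued",
    "appetite remains good and weight is stable",
    "community mental health team to follow up in six weeks",
    "lives alone with a package of care twice daily",
    "blood pressure 128/76 and pulse regular",
    "scored 22 out of 30 on cognitive testing today",
    "no concerns raised regarding physical health",
    "slept reasonably well over the past week",
    "discussed future care planning with the family",
    "enjoys attending the day centre twice a week",
    "bloods taken for routine monitoring",
)


def templates_for(concept: Concept, label: GoldLabel) -> tuple[Template, ...]:
    """Templates for a concept/label pair; empty tuple if none exist."""
    return TEMPLATES.get((concept, label), ())
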