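"""Core record types shared across the pipeline.

The pipeline moves through four representations: patients and their
planted ground-truth symptom profiles (synthetic cohort), free-text
clinical documents with gold span annotations, mention candidates with
positive/non-positive calls (extraction), and patient-level symptom
profiles (aggregation).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Diagnosis(str, Enum):
    """Clinical dementia diagnosis recorded for a patient."""

    AD = "AD"
    DLB = "DLB"


class Concept(str, Enum):
    """The six elementary concepts mined from text.

    Tremor and bradykinesia roll up to parkinsonism; bad dreams and
    nightmares roll up to possible REM sleep behaviour disorder. Visual
    hallucinations and fluctuations map one-to-one onto core features.
    """

    VISUAL_HALLUCINATIONS = "visual_hallucinations"
    FLUCTUATIONS = "fluctuations"
    TREMOR = "tremor"
    BRADYKINESIA = "bradykinesia"
    BAD_DREAMS = "bad_dreams"
    NIGHTMARES = "nightmares"


#: All six elementary concepts, in canonical order.
CONCEPTS: tuple[Concept, ...] = tuple(Concept)

#: Concept -> attribute name on :class:`TrueProfile`.
PROFILE_FIELD = {
    Concept.VISUAL_HALLUCINATIONS: "vh",
    Concept.FLUCTUATIONS: "fluct",
    Concept.TREMOR: "tremor",
    Concept.BRADYKINESIA: "bradykinesia",
    Concept.BAD_DREAMS: "bad_dreams",
    Concept.NIGHTMARES: "nightmares",
}


class GoldLabel(str, Enum):
    """Three-way annotation scheme for gold mentions.

    ``UNKNOWN`` (uncertain, hypothetical, or not about the patient) is
    coded as non-positive everywhere downstream, exactly like ``NEGATIVE``.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PatientRecord:
    """Demographics and diagnosis for one patient."""

    patient_id: str
    diagnosis: Diagnosis
    age_referral: float
    age_diagnosis: float
    gender: str  # "female" | "male"
    ethnicity: str  # "white" | "non_white"
    marital: str  # "married_cohabiting" | "other"

    def __post_init__(self) -> None:
        if self.age_diagnosis < self.age_referral:
            raise ValueError(
                f"{self.patient_id}: age at diagnosis ({self.age_diagnosis}) "
                f"precedes age at referral ({self.age_referral})"
            )
        if self.gender not in ("female", "male"):
            raise ValueError(f"invalid gender: {self.gender!r}")
        if self.ethnicity not in ("white", "non_white"):
            raise ValueError(f"invalid ethnicity: {self.ethnicity!r}")
        if self.marital not in ("married_cohabiting", "other"):
            raise ValueError(f"invalid marital status: {self.marital!r}")


@dataclass(frozen=True)
class TrueProfile:
    """Planted ground-truth elementary symptom flags for one patient.

    Independent of any extraction output; persisted alongside the corpus
    so recovery tests can compare extracted profiles against the truth.
    """

    vh: bool
    fluct: bool
    tremor: bool
    bradykinesia: bool
    bad_dreams: bool
    nightmares: bool

    @property
    def parkinsonism(self) -> bool:
        return self.tremor or self.bradykinesia

    @property
    def rbd(self) -> bool:
        return self.bad_dreams or self.nightmares

    @property
    def core_count(self) -> int:
        return sum((self.vh, self.fluct, self.parkinsonism, self.rbd))

    def has(self, concept: Concept) -> bool:
        return bool(getattr(self, PROFILE_FIELD[concept]))


@dataclass(frozen=True)
class ClinicalDocument:
    """One free-text note tied to a patient."""

    doc_id: str
    patient_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"{self.doc_id}: document text must be non-empty")


@dataclass(frozen=True)
class GoldAnnotation:
    """Gold label for a concept span, 0-based half-open character offsets."""

    doc_id: str
    concept: Concept
    start: int
    end: int
    label: GoldLabel

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class MentionCandidate:
    """A matched concept span and the sentence that contains it."""

    doc_id: str
    concept: Concept
    start: int
    end: int
    context: str
    context_start: int

    def __post_init__(self) -> None:
        if not (self.context_start <= self.start < self.end
                <= self.context_start + len(self.context)):
            raise ValueError(
                f"span [{self.start}, {self.end}) outside context window "
                f"starting at {self.context_start}"
            )

    @property
    def span_text(self) -> str:
        lo = self.start - self.context_start
        return self.context[lo:lo + (self.end - self.start)]


#: Sub-labels for non-positive mentions.
SUBLABELS = ("negated", "unknown", "irrelevant", "none")


@dataclass(frozen=True)
class MentionLabel:
    """Binary positive/non-positive call with the reason for rejection.

    Negated, uncertain/hypothetical and irrelevant mentions are all
    collapsed into the single non-positive class; ``sublabel`` records
    which cue fired and is ``"none"`` exactly when the call is positive.
    """

    label: str  # "positive" | "non_positive"
    sublabel: str = "none"

    def __post_init__(self) -> None:
        if self.label not in ("positive", "non_positive"):
            raise ValueError(f"invalid label: {self.label!r}")
        if self.sublabel not in SUBLABELS:
            raise ValueError(f"invalid sublabel: {self.sublabel!r}")
        if (self.label == "non_positive") != (self.sublabel != "none"):
            raise ValueError(
                f"label {self.label!r} inconsistent with sublabel {self.sublabel!r}"
            )

    @property
    def is_positive(self) -> bool:
        return self.label == "positive"


POSITIVE = MentionLabel("positive")


def non_positive(sublabel: str) -> MentionLabel:
    return MentionLabel("non_positive", sublabel)
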