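"""Patient-level roll-up of labelled mentions.

Ascertainment is whole-record with no time window: a single positive
mention anywhere in a patient's documents sets the lifetime flag for
that elementary symptom. Non-positive mentions never veto a positive
mention elsewhere. Compound core features follow the diagnostic
convention: parkinsonism = tremor OR bradykinesia, RBD = bad dreams OR
nightmares; the core-feature count (0-4) drives the possible/probable
criteria category (one feature => possible, two or more => probable
profile).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .types import CONCEPTS, Concept, Diagnosis

ELEMENTARY = [c.value for c in CONCEPTS]


@dataclass(frozen=True)
class SymptomProfile:
    """Patient-level flags for elementary and core features."""

    vh: bool = False
    fluct: bool = False
    tremor: bool = False
    bradykinesia: bool = False
    bad_dreams: bool = False
    nightmares: bool = False

    @property
    def parkinsonism(self) -> bool:
        return self.tremor or self.bradykinesia

    @property
    def rbd(self) -> bool:
        return self.bad_dreams or self.nightmares

    @property
    def core_count(self) -> int:
        return sum((self.vh, self.fluct, self.parkinsonism, self.rbd))


class CriteriaLevel(str, Enum):
    NONE = "none"
    ONE_FEATURE = "one_feature"
    TWO_PLUS = "two_plus"


@dataclass(frozen=True)
class CriteriaCategory:
    category: CriteriaLevel
    ad2cs_flag: bool

    def __post_init__(self) -> None:
        if self.ad2cs_flag and self.category != CriteriaLevel.TWO_PLUS:
            raise ValueError("ad2cs_flag requires the two_plus category")


_FLAG_FOR = {
    Concept.VISUAL_HALLUCINATIONS: "vh",
    Concept.FLUCTUATIONS: "fluct",
    Concept.TREMOR: "tremor",
    Concept.BRADYKINESIA: "bradykinesia",
    Concept.BAD_DREAMS: "bad_dreams",
    Concept.NIGHTMARES: "nightmares",
}


def aggregate_patient(mentions: pd.DataFrame | Iterable[tuple]) -> SymptomProfile:
    """Roll all of one patient's labelled mentions up to a profile.

    ``mentions`` is a DataFrame with at least ``concept`` and ``label``
    columns (and optionally ``patient_id``, which must be single-valued)
    or an iterable of ``(concept, label)`` pairs. An elementary flag is
    true iff at least one positive mention of the concept exists.
    """
    if not isinstance(mentions, pd.DataFrame):
        mentions = pd.DataFrame(list(mentions), columns=["concept", "label"])
    if "patient_id" in mentions.columns and mentions["patient_id"].nunique() > 1:
        raise ValueError("mentions span multiple patients: "
                         + ", ".join(sorted(mentions["patient_id"].unique())))
    flags = dict.fromkeys(ELEMENTARY, False)
    if len(mentions):
        positives = mentions.loc[mentions["label"] == "positive", "concept"]
        for concept in positives:
            flags[Concept(concept).value] = True
    return SymptomProfile(**{_FLAG_FOR[Concept(k)]: v for k, v in flags.items()})


def classify_criteria(diagnosis: Diagnosis | str,
                      profile: SymptomProfile) -> CriteriaCategory:
    """Map a profile to the none / one-feature / two-plus category."""
    diagnosis = Diagnosis(diagnosis)
    count = profile.core_count
    if count == 0:
        level = CriteriaLevel.NONE
    elif count == 1:
        level = CriteriaLevel.ONE_FEATURE
    else:
        level = CriteriaLevel.TWO_PLUS
    return CriteriaCategory(
        category=level,
        ad2cs_flag=(diagnosis == Diagnosis.AD and level == CriteriaLevel.TWO_PLUS))


PROFILE_COLUMNS = ["patient_id", "diagnosis", "vh", "fluct", "parkinsonism",
                   "rbd", "core_count", "category", "ad2cs_flag"]


def doc_patient_from_id(doc_id: str) -> str:
    """Default document-to-patient mapping: ``<patient_id>-D<n>``."""
    patient_id, sep, _ = doc_id.rpartition("-D")
    if not sep:
        raise ValueError(f"cannot derive patient from doc_id {doc_id!r}")
    return patient_id


def build_profiles(mentions: pd.DataFrame, patients: pd.DataFrame,
                   doc_patient: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Patient-level profile table for a whole cohort.

    ``patients`` needs ``patient_id`` and ``diagnosis`` columns; every
    patient appears in the output even with no mentions. ``doc_patient``
    maps document ids to patient ids; if omitted the ``<patient>-D<n>``
    naming convention of the synthetic corpus is assumed.
    """
    mentions = mentions.copy()
    if doc_patient is not None:
        mentions["patient_id"] = mentions["doc_id"].map(doc_patient)
        if mentions["patient_id"].isna().any():
            missing = mentions.loc[mentions["patient_id"].isna(), "doc_id"]
            raise ValueError(f"documents with no patient mapping: "
                             f"{sorted(set(missing))[:5]}")
    else:
        mentions["patient_id"] = mentions["doc_id"].map(doc_patient_from_id)

    positive = mentions[mentions["label"] == "positive"]
    seen = positive.groupby("patient_id")["concept"].agg(set).to_dict()

    rows = []
    for patient_id, diagnosis in zip(patients["patient_id"],
                                     patients["diagnosis"]):
        concepts = seen.get(patient_id, set())
        profile = SymptomProfile(
            **{_FLAG_FOR[c]: (c.value in concepts) for c in CONCEPTS})
        cat = classify_criteria(diagnosis, profile)
        rows.append((patient_id, Diagnosis(diagnosis).value,
                     int(profile.vh), int(profile.fluct),
                     int(profile.parkinsonism), int(profile.rbd),
                     profile.core_count, cat.category.value,
                     int(cat.ad2cs_flag)))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def profiles_from_truth(cohort) -> pd.DataFrame:
    """Profile table computed directly from planted ground truth."""
    rows = []
    for record, truth in cohort:
        profile = SymptomProfile(vh=truth.vh, fluct=truth.fluct,
                                 tremor=truth.tremor,
                                 bradykinesia=truth.bradykinesia,
                                 bad_dreams=truth.bad_dreams,
                                 nightmares=truth.nightmares)
        cat = classify_criteria(record.diagnosis, profile)
        rows.append((record.patient_id, record.diagnosis.value,
                     int(profile.vh), int(profile.fluct),
                     int(profile.parkinsonism), int(profile.rbd),
                     profile.core_count, cat.category.value,
                     int(cat.ad2cs_flag)))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
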