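"""Configuration models for the synthetic cohort and corpus generator.

Defaults encode the study population the generator emulates: a memory
services cohort of 13,712 Alzheimer's disease (AD) and 617 dementia with
Lewy bodies (DLB) patients, with per-group demographics and per-group
prevalences of the four DLB core features (visual hallucinations,
cognitive fluctuations, parkinsonism, REM sleep behaviour disorder).

Parkinsonism and RBD are compound features (tremor OR bradykinesia,
bad dreams OR nightmares). The generator samples the six elementary
symptoms independently, so a compound target prevalence ``q`` is split
symmetrically into two elementary Bernoulli rates ``p = 1 - sqrt(1-q)``,
which recombine to exactly ``q`` under independence.
"""
from __future__ import annotations

import math
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .types import Diagnosis


class GroupPrevalence(BaseModel):
    """Per-group Bernoulli probabilities for the six elementary symptoms."""

    vh: float = Field(ge=0.0, le=1.0)
    fluct: float = Field(ge=0.0, le=1.0)
    tremor: float = Field(ge=0.0, le=1.0)
    bradykinesia: float = Field(ge=0.0, le=1.0)
    bad_dreams: float = Field(ge=0.0, le=1.0)
    nightmares: float = Field(ge=0.0, le=1.0)

    @classmethod
    def from_core(cls, vh: float, fluct: float,
                  parkinsonism: float, rbd: float) -> "GroupPrevalence":
        """Build elementary rates from the four core-feature prevalences."""
        p_motor = 1.0 - math.sqrt(1.0 - parkinsonism)
        p_dream = 1.0 - math.sqrt(1.0 - rbd)
        return cls(vh=vh, fluct=fluct, tremor=p_motor, bradykinesia=p_motor,
                   bad_dreams=p_dream, nightmares=p_dream)

    @property
    def parkinsonism(self) -> float:
        return 1.0 - (1.0 - self.tremor) * (1.0 - self.bradykinesia)

    @property
    def rbd(self) -> float:
        return 1.0 - (1.0 - self.bad_dreams) * (1.0 - self.nightmares)

    def core(self) -> dict[str, float]:
        """Implied prevalence of each of the four core features."""
        return {"vh": self.vh, "fluct": self.fluct,
                "parkinsonism": self.parkinsonism, "rbd": self.rbd}


class GroupDemographics(BaseModel):
    """Gaussian age model and binary demographic rates for one group.

    ``diagnosis_delay_years`` is the mean of an exponential waiting time
    between first referral and first dementia diagnosis;
    ``diagnosis_delay_two_plus_years`` replaces it for patients whose
    planted profile carries two or more core features (the strata with a
    longer route to diagnosis).
    """

    age_referral_mean: float = Field(gt=0)
    age_referral_sd: float = Field(gt=0)
    female: float = Field(ge=0.0, le=1.0)
    non_white: float = Field(ge=0.0, le=1.0)
    married: float = Field(ge=0.0, le=1.0)
    diagnosis_delay_years: float = Field(ge=0.0)
    diagnosis_delay_two_plus_years: float = Field(ge=0.0)


class PrevalenceConfig(BaseModel):
    """Symptom and demographic parameters for both diagnosis groups."""

    prevalence: dict[Diagnosis, GroupPrevalence]
    demographics: dict[Diagnosis, GroupDemographics]

    @model_validator(mode="after")
    def _both_groups(self) -> "PrevalenceConfig":
        for mapping in (self.prevalence, self.demographics):
            missing = {Diagnosis.AD, Diagnosis.DLB} - set(mapping)
            if missing:
                raise ValueError(f"missing group parameters for {sorted(missing)}")
        return self

    @classmethod
    def default(cls) -> "PrevalenceConfig":
        return cls(
            prevalence={
                Diagnosis.DLB: GroupPrevalence.from_core(
                    vh=0.831, fluct=0.747, parkinsonism=0.621, rbd=0.266),
                Diagnosis.AD: GroupPrevalence.from_core(
                    vh=0.167, fluct=0.303, parkinsonism=0.197, rbd=0.093),
            },
            demographics={
                Diagnosis.DLB: GroupDemographics(
                    age_referral_mean=76.9, age_referral_sd=10.2,
                    female=0.490, non_white=0.264, married=0.426,
                    diagnosis_delay_years=2.0,
                    diagnosis_delay_two_plus_years=2.0),
                Diagnosis.AD: GroupDemographics(
                    age_referral_mean=80.6, age_referral_sd=8.5,
                    female=0.640, non_white=0.279, married=0.348,
                    diagnosis_delay_years=1.0,
                    diagnosis_delay_two_plus_years=2.0),
            },
        )


class NoiseConfig(BaseModel):
    """Controls document counts, planted non-positive mentions and filler.

    ``negated_mention_rate`` / ``unknown_mention_rate`` are per-patient,
    per-concept probabilities of planting a negated or uncertain mention
    regardless of the patient's true profile, so the mention classifier
    is exercised on both sides. Distractor sentences are neutral clinical
    text containing none of the concept keywords.
    """

    docs_per_patient_min: int = Field(default=1, ge=1)
    docs_per_patient_max: int = Field(default=5, ge=1)
    negated_mention_rate: float = Field(default=0.30, ge=0.0, le=1.0)
    unknown_mention_rate: float = Field(default=0.15, ge=0.0, le=1.0)
    distractors_per_doc_min: int = Field(default=1, ge=0)
    distractors_per_doc_max: int = Field(default=3, ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "NoiseConfig":
        if self.docs_per_patient_max < self.docs_per_patient_min:
            raise ValueError("docs_per_patient_max < docs_per_patient_min")
        if self.distractors_per_doc_max < self.distractors_per_doc_min:
            raise ValueError("distractors_per_doc_max < distractors_per_doc_min")
        return self

    @classmethod
    def noise_free(cls) -> "NoiseConfig":
        """No planted negated/uncertain mentions; distractors remain."""
        return cls(negated_mention_rate=0.0, unknown_mention_rate=0.0)


class CorpusConfig(BaseModel):
    """Top-level generator configuration: group sizes + parameters."""

    n_ad: int = Field(default=13712, ge=0)
    n_dlb: int = Field(default=617, ge=0)
    params: PrevalenceConfig = Field(default_factory=PrevalenceConfig.default)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)

    @classmethod
    def default(cls) -> "CorpusConfig":
        return cls()


def load_config(path: str | Path) -> CorpusConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return CorpusConfig.model_validate(raw or {})


def dump_config(config: CorpusConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
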