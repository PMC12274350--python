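"""Seeded synthetic cohort, notes and gold-annotation generator.

Stands in for a restricted mental-health case register: it produces a
two-group dementia cohort (AD / DLB) with group-specific demographics,
plants six elementary symptoms per patient as independent Bernoulli
draws, renders each patient's record as a handful of short clinical
notes built from a fixed template bank, and emits gold span annotations
for every planted mention.

Seeding uses one master seed split deterministically per patient
(``SeedSequence(seed, spawn_key=(group, index, stream))``), so a given
patient's record is reproducible independently of cohort size.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .config import CorpusConfig, NoiseConfig, PrevalenceConfig
from .templates import DISTRACTORS, Template, templates_for
from .types import (CONCEPTS, ClinicalDocument, Concept, Diagnosis,
                    GoldAnnotation, GoldLabel, PatientRecord, TrueProfile)

_GROUP_KEY = {Diagnosis.AD: 0, Diagnosis.DLB: 1}
_COHORT_STREAM, _RENDER_STREAM = 0, 1


class Corpus(NamedTuple):
    cohort: list[tuple[PatientRecord, TrueProfile]]
    documents: list[ClinicalDocument]
    gold: list[GoldAnnotation]


def _patient_rng(seed: int, diagnosis: Diagnosis, index: int,
                 stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(_GROUP_KEY[diagnosis], index, stream))
    return np.random.default_rng(ss)


def _sample_patient(diagnosis: Diagnosis, index: int,
                    params: PrevalenceConfig, seed: int
                    ) -> tuple[PatientRecord, TrueProfile]:
    rng = _patient_rng(seed, diagnosis, index, _COHORT_STREAM)
    prev = params.prevalence[diagnosis]
    demo = params.demographics[diagnosis]

    draws = rng.random(6)
    profile = TrueProfile(
        vh=bool(draws[0] < prev.vh),
        fluct=bool(draws[1] < prev.fluct),
        tremor=bool(draws[2] < prev.tremor),
        bradykinesia=bool(draws[3] < prev.bradykinesia),
        bad_dreams=bool(draws[4] < prev.bad_dreams),
        nightmares=bool(draws[5] < prev.nightmares),
    )

    age_referral = rng.normal(demo.age_referral_mean, demo.age_referral_sd)
    delay_mean = (demo.diagnosis_delay_two_plus_years
                  if profile.core_count >= 2 else demo.diagnosis_delay_years)
    delay = rng.exponential(delay_mean) if delay_mean > 0 else 0.0
    demo_draws = rng.random(3)
    record = PatientRecord(
        patient_id=f"{diagnosis.value}-{index + 1:06d}",
        diagnosis=diagnosis,
        age_referral=round(age_referral, 2),
        age_diagnosis=round(age_referral + delay, 2),
        gender="female" if demo_draws[0] < demo.female else "male",
        ethnicity="non_white" if demo_draws[1] < demo.non_white else "white",
        marital=("married_cohabiting" if demo_draws[2] < demo.married
                 else "other"),
    )
    return record, profile


def generate_cohort(n_ad: int, n_dlb: int, params: PrevalenceConfig,
                    seed: int) -> list[tuple[PatientRecord, TrueProfile]]:
    """Sample a cohort of AD and DLB patients with planted symptom flags.

    Identical ``(n_ad, n_dlb, params, seed)`` give identical output, and
    the first ``k`` patients of a group are unchanged when the group is
    enlarged.
    """
    if n_ad < 0 or n_dlb < 0:
        raise ValueError("group sizes must be non-negative")
    cohort = [_sample_patient(Diagnosis.AD, i, params, seed)
              for i in range(n_ad)]
    cohort += [_sample_patient(Diagnosis.DLB, i, params, seed)
               for i in range(n_dlb)]
    return cohort


def _plant_plan(profile: TrueProfile, noise: NoiseConfig,
                rng: np.random.Generator) -> tuple[int, list[tuple[int, Template]]]:
    """Decide document count and which templates go into which document."""
    n_docs = int(rng.integers(noise.docs_per_patient_min,
                              noise.docs_per_patient_max + 1))
    planted: list[tuple[int, Template]] = []

    def plant(options: Sequence[Template]) -> None:
        tpl = options[int(rng.integers(len(options)))]
        planted.append((int(rng.integers(n_docs)), tpl))

    for concept in CONCEPTS:
        if profile.has(concept):
            plant(templates_for(concept, GoldLabel.POSITIVE))
    for concept in CONCEPTS:
        if (noise.negated_mention_rate
                and rng.random() < noise.negated_mention_rate):
            plant(templates_for(concept, GoldLabel.NEGATIVE))
        unknowns = templates_for(concept, GoldLabel.UNKNOWN)
        if (unknowns and noise.unknown_mention_rate
                and rng.random() < noise.unknown_mention_rate):
            plant(unknowns)
    return n_docs, planted


def render_documents(patient: PatientRecord, profile: TrueProfile,
                     noise: NoiseConfig, seed: int | np.random.SeedSequence
                     ) -> tuple[list[ClinicalDocument], list[GoldAnnotation]]:
    """Render one patient's record as documents plus gold annotations.

    Every true elementary symptom is planted as at least one
    positive-labelled mention; depending on ``noise``, negated and
    uncertain mentions of any concept may be planted as well. Gold spans
    cover exactly the keyword region of each planted template.
    """
    rng = np.random.default_rng(seed)
    n_docs, planted = _plant_plan(profile, noise, rng)

    per_doc: list[list[Template | str]] = [[] for _ in range(n_docs)]
    for doc_idx, tpl in planted:
        per_doc[doc_idx].append(tpl)
    for items in per_doc:
        k = int(rng.integers(noise.distractors_per_doc_min,
                             noise.distractors_per_doc_max + 1))
        k = min(max(k, 0 if items else 1), len(DISTRACTORS))
        for idx in rng.choice(len(DISTRACTORS), size=k, replace=False):
            items.append(DISTRACTORS[int(idx)])

    documents: list[ClinicalDocument] = []
    gold: list[GoldAnnotation] = []
    for j, items in enumerate(per_doc):
        order = rng.permutation(len(items))
        doc_id = f"{patient.patient_id}-D{j + 1}"
        parts: list[str] = []
        cursor = 0
        for idx in order:
            item = items[int(idx)]
            sentence = item.sentence if isinstance(item, Template) else item
            sentence = sentence[0].upper() + sentence[1:]
            if isinstance(item, Template):
                lo, hi = item.keyword_span
                gold.append(GoldAnnotation(doc_id, item.concept,
                                           cursor + lo, cursor + hi,
                                           item.label))
            parts.append(sentence + ".")
            cursor += len(sentence) + 2  # sentence, period, joining space
        documents.append(ClinicalDocument(doc_id, patient.patient_id,
                                          " ".join(parts)))
    return documents, gold


def generate_corpus(config: CorpusConfig, seed: int) -> Corpus:
    """End-to-end generation: cohort, documents and gold annotations."""
    cohort = generate_cohort(config.n_ad, config.n_dlb, config.params, seed)
    documents: list[ClinicalDocument] = []
    gold: list[GoldAnnotation] = []
    for patient, profile in cohort:
        index = int(patient.patient_id.split("-")[1]) - 1
        ss = np.random.SeedSequence(
            entropy=seed,
            spawn_key=(_GROUP_KEY[patient.diagnosis], index, _RENDER_STREAM))
        docs, anns = render_documents(patient, profile, config.noise, ss)
        documents.extend(docs)
        gold.extend(anns)
    return Corpus(cohort, documents, gold)


# ---------------------------------------------------------------------------
# corpus I/O (plain-text formats; deterministic byte-for-byte)

PATIENT_HEADER = ["patient_id", "diagnosis", "age_referral", "age_diagnosis",
                  "gender", "ethnicity", "marital"]
PROFILE_HEADER = ["patient_id", "vh", "fluct", "tremor", "bradykinesia",
                  "bad_dreams", "nightmares"]
GOLD_HEADER = ["doc_id", "concept", "start", "end", "label"]


def write_corpus(corpus: Corpus, out_dir: str | Path) -> dict[str, Path]:
    """Write patients.csv, true_profiles.csv, notes.jsonl and gold.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("patients", "patients.csv"), ("profiles", "true_profiles.csv"),
        ("notes", "notes.jsonl"), ("gold", "gold.csv")]}
    try:
        with open(paths["patients"], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(PATIENT_HEADER)
            for rec, _ in corpus.cohort:
                w.writerow([rec.patient_id, rec.diagnosis.value,
                            f"{rec.age_referral:.2f}",
                            f"{rec.age_diagnosis:.2f}",
                            rec.gender, rec.ethnicity, rec.marital])
        with open(paths["profiles"], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(PROFILE_HEADER)
            for rec, prof in corpus.cohort:
                w.writerow([rec.patient_id] +
                           [int(getattr(prof, f)) for f in PROFILE_HEADER[1:]])
        with open(paths["notes"], "w", encoding="utf-8") as fh:
            for doc in corpus.documents:
                fh.write(json.dumps({"doc_id": doc.doc_id,
                                     "patient_id": doc.patient_id,
                                     "text": doc.text}) + "\n")
        with open(paths["gold"], "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(GOLD_HEADER)
            for ann in corpus.gold:
                w.writerow([ann.doc_id, ann.concept.value, ann.start,
                            ann.end, ann.label.value])
    except OSError as exc:
        raise OSError(f"failed writing corpus under {out}: {exc}") from exc
    return paths


def read_corpus(out_dir: str | Path) -> Corpus:
    """Read a corpus written by :func:`write_corpus`."""
    out = Path(out_dir)
    profiles: dict[str, TrueProfile] = {}
    with open(out / "true_profiles.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            profiles[row["patient_id"]] = TrueProfile(
                **{f: bool(int(row[f])) for f in PROFILE_HEADER[1:]})
    cohort: list[tuple[PatientRecord, TrueProfile]] = []
    with open(out / "patients.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rec = PatientRecord(
                patient_id=row["patient_id"],
                diagnosis=Diagnosis(row["diagnosis"]),
                age_referral=float(row["age_referral"]),
                age_diagnosis=float(row["age_diagnosis"]),
                gender=row["gender"], ethnicity=row["ethnicity"],
                marital=row["marital"])
            cohort.append((rec, profiles[rec.patient_id]))
    documents = read_documents(out / "notes.jsonl")
    gold = read_gold(out / "gold.csv")
    return Corpus(cohort, documents, gold)


def read_documents(path: str | Path) -> list[ClinicalDocument]:
    documents = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                documents.append(ClinicalDocument(obj["doc_id"],
                                                  obj["patient_id"],
                                                  obj["text"]))
    return documents


def read_gold(path: str | Path) -> list[GoldAnnotation]:
    gold = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            gold.append(GoldAnnotation(row["doc_id"], Concept(row["concept"]),
                                       int(row["start"]), int(row["end"]),
                                       GoldLabel(row["label"])))
    return gold
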