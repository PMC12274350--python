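import pandas as pd
import pytest

from dlbtext.config import CorpusConfig, NoiseConfig
from dlbtext.corpus import Corpus, generate_corpus


def patients_frame(corpus: Corpus) -> pd.DataFrame:
    rows = [(r.patient_id, r.diagnosis.value, r.age_referral, r.age_diagnosis,
             r.gender, r.ethnicity, r.marital) for r, _ in corpus.cohort]
    return pd.DataFrame(rows, columns=["patient_id", "diagnosis",
                                       "age_referral", "age_diagnosis",
                                       "gender", "ethnicity", "marital"])


def gold_frame(corpus: Corpus) -> pd.DataFrame:
    rows = [(g.doc_id, g.concept.value, g.start, g.end, g.label.value)
            for g in corpus.gold]
    return pd.DataFrame(rows, columns=["doc_id", "concept", "start", "end",
                                       "label"])


@pytest.fixture(scope="session")
def small_corpus() -> Corpus:
    """60+60 patients with default (noisy) generation."""
    return generate_corpus(CorpusConfig(n_ad=60, n_dlb=60), seed=123)


@pytest.fixture(scope="session")
def noise_free_corpus() -> Corpus:
    """120+120 patients with no planted negated/uncertain mentions."""
    config = CorpusConfig(n_ad=120, n_dlb=120, noise=NoiseConfig.noise_free())
    return generate_corpus(config, seed=123)
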