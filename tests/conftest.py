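import pandas as pd
import pytest

from metacomplete.completeness import Claim
from metacomplete.miniml_io import parse_miniml
from metacomplete.synth import SyntheticConfig, generate_corpus
from metacomplete.vocab import default_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


def corpus_and_claims(**kwargs):
    """Generate a corpus plus its claims dict, parsed documents included."""
    corpus = generate_corpus(SyntheticConfig(**kwargs))
    docs = [parse_miniml(s.xml.encode()) for s in corpus.studies]
    claims = {}
    for _, row in corpus.claims_table.iterrows():
        claims.setdefault(row["study_accession"], []).append(
            Claim(
                attribute=row["attribute"],
                value=row["value"],
                uniform=bool(row["uniform"]),
            )
        )
    return corpus, docs, claims


@pytest.fixture(scope="session")
def clean_corpus():
    """50 clean studies, fixed seed: the round-trip reference corpus."""
    return corpus_and_claims(n_studies=50, seed=20)


def level_frame(matrix: pd.DataFrame) -> pd.Series:
    return matrix.set_index(["study", "sample", "attribute", "source"])["level"]
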