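import numpy as np
import pytest

from ogtpred.corpus import Corpus, GenomeRecord, ProteinRecord
from ogtpred.synthetic import SyntheticSpec, generate_corpus


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Hand-built corpus: one genome per class plus one excluded genome."""
    corpus = Corpus()
    for gid, species, ogt in [
        ("cold1", "Psychrobacter testii", 12.0),
        ("warm1", "Mesophila testii", 35.0),
        ("hot1", "Thermus testii", 75.0),
        ("mid1", "Ambigua testii", 25.0),  # excluded band
    ]:
        corpus.add_genome(GenomeRecord.from_metadata(gid, species, ogt))
    sequences = {
        "cold1": ["MKDDQLSTHA", "DDHHMMQQSSTT"],
        "warm1": ["MKAELVYGGA", "AAGGKKPPRR"],
        "hot1": ["ELVYELVYEL", "EEELLLVVYY"],
        "mid1": ["ACDEFGHIKL"],
    }
    for gid, seqs in sequences.items():
        genome = corpus.genomes[gid]
        label = None if genome.temp_class.value == "excluded" else genome.ogt_celsius
        for i, seq in enumerate(seqs):
            corpus.add_protein(
                ProteinRecord(f"{gid}|p{i:02d}", gid, seq, label_celsius=label)
            )
    return corpus


SMALL_SPEC = SyntheticSpec(
    n_genomes_per_class=2,
    proteins_per_genome=12,
    families=10,
    family_span={2: 1.0},
    length_range=(30, 50),
    seed=7,
)


@pytest.fixture(scope="session")
def small_synth():
    """Small synthetic corpus shared across tests (read-only)."""
    corpus, clusters, truth = generate_corpus(SMALL_SPEC)
    return corpus, clusters, truth


class StubModel:
    """Predicts a fixed mapping (or constant) without any learning."""

    def __init__(self, mapping=None, constant=None):
        self.mapping = mapping
        self.constant = constant

    def predict(self, proteins):
        if self.mapping is not None:
            return np.array([self.mapping[p.protein_id] for p in proteins], dtype=float)
        return np.full(len(proteins), self.constant, dtype=float)


class LabelStub:
    """Perfect oracle: returns each protein's own label."""

    def predict(self, proteins):
        return np.array([p.label_celsius for p in proteins], dtype=float)


@pytest.fixture
def stub_model_factory():
    def make(mapping=None, constant=None):
        return StubModel(mapping=mapping, constant=constant)

    return make


@pytest.fixture
def label_stub():
    return LabelStub()
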