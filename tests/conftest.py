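import numpy as np
import pytest

from imprintdiv.align import CodonAlignment, MultiCodonAlignment, ProteinAlignment


@pytest.fixture
def make_codon_alignment():
    def _make(row_a: str, row_b: str, gene_id: str = "g", sp_a: str = "human", sp_b: str = "mouse"):
        return CodonAlignment(gene_id, sp_a, sp_b, (row_a, row_b))

    return _make


@pytest.fixture
def make_protein_alignment():
    def _make(row_a: str, row_b: str, gene_id: str = "g"):
        return ProteinAlignment(gene_id, "human", "mouse", (row_a, row_b))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20210831)


@pytest.fixture(scope="session")
def toy_dataset():
    from imprintdiv.simulate import fixture_toy_dataset

    return fixture_toy_dataset()


@pytest.fixture
def quartet_alignment(rng):
    """A 60-codon simulated quartet alignment with known parameters."""
    from imprintdiv.simulate import SimulationSpec, simulate_quartet

    spec = SimulationSpec(codons=60, gene_rate_sd=0.0, cpg_bias=1.0)
    seqs, truth = simulate_quartet(spec, "q", rng, omega=0.2)
    rows = tuple(seqs[sp].dna for sp in ("human", "mouse", "rat", "cow"))
    return MultiCodonAlignment("q", ("human", "mouse", "rat", "cow"), rows), truth
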