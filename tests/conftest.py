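import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from codonopt.alphabet import AMINO_ACIDS
from codonopt.codon_model import CodonUsageTable, load_human_table

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)
proteins = st.text(alphabet="".join(AMINO_ACIDS), min_size=1, max_size=25)


@pytest.fixture(scope="session")
def human_table():
    return load_human_table()


def make_table(overrides=None, base=1.0):
    """Uniform-frequency table with selected codons overridden."""
    from codonopt.alphabet import CODONS

    freqs = {c: base for c in CODONS}
    freqs.update(overrides or {})
    return CodonUsageTable(frequencies=freqs, species_label="toy")


@pytest.fixture(scope="session")
def toy_table():
    """Ala family (30, 10, 5, 5); everything else uniform."""
    return make_table({"GCT": 30.0, "GCC": 10.0, "GCA": 5.0, "GCG": 5.0})
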