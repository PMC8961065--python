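import numpy as np
import pytest

from cubkit import CodingSequence, CodonCounts, GeneticCode


@pytest.fixture(scope="session")
def code():
    return GeneticCode()


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def make_counts(mapping, scope="toy"):
    return CodonCounts(scope=scope, counts=mapping)


def random_counts(rng, code, low=0, high=50):
    """Random 61-sense-codon count table (stops zero)."""
    return CodonCounts(
        scope="rand",
        counts={c: int(rng.integers(low, high)) for c in code.sense_codons},
    )


@pytest.fixture
def seven_rule_fixture():
    """Six sequences violating exactly one filter rule each, plus one clean CDS."""
    base = "ATG" + "GAT" * 98 + "TAA"  # 300 nt, valid
    return [
        CodingSequence(id="bad_alphabet", seq="ATG" + "GAN" + "GAT" * 97 + "TAA"),
        CodingSequence(id="bad_mod3", seq=base + "A"),
        CodingSequence(id="bad_start", seq="GTG" + "GAT" * 98 + "TAA"),
        CodingSequence(id="bad_stop", seq="ATG" + "GAT" * 98 + "AAA"),
        CodingSequence(id="bad_internal", seq="ATG" + "TAA" + "GAT" * 97 + "TAA"),
        CodingSequence(id="bad_short", seq="ATG" + "GAT" * 30 + "TAA"),
        CodingSequence(id="good", seq=base),
    ]


def uniform_usage_counts(code, per_codon=10):
    """Equal counts for every sense codon: RSCU = 1 everywhere."""
    return CodonCounts(scope="uniform", counts={c: per_codon for c in code.sense_codons})
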