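import numpy as np
import pytest

from dropdms import (
    CodingSequence,
    ScreenConfig,
    assign_ground_truth,
    simulate_epcr_library,
)

# deterministic 50-codon toy gene (ATG start, no internal stop)
_TOY_CODONS = (
    "ATG GCT TGG GAT CGT AAA GAA CAT TTG GGT GTT ACC ATC AGC TAC "
    "CCG GAC TTC AAC CTG GCA GTG AGA GAG CTC ATT GGC TGC CAT AAA "
    "GAG TTT ATG TCC AAC GGG CTG TAT CAG CCA ACG GTC GAC TGG AGG "
    "AAA CTA GAG TCA GGA"
).split()


@pytest.fixture(scope="session")
def toy_reference() -> CodingSequence:
    return CodingSequence(id="toy", nucleotides="".join(_TOY_CODONS))


@pytest.fixture(scope="session")
def toy_reference_offset() -> CodingSequence:
    # canonical numbering offset so construct position 4 (Asp) reports as 175
    return CodingSequence(id="toy_off", nucleotides="".join(_TOY_CODONS),
                          numbering_offset=171)


@pytest.fixture(scope="session")
def neutral_library(toy_reference):
    """2000-variant library with all-zero coefficients, 25% active."""
    lib = simulate_epcr_library(toy_reference, 2000, 4.5, seed=11)
    return assign_ground_truth(lib, {}, target_pi=0.25, seed=12)


@pytest.fixture
def default_screen_config():
    return ScreenConfig(seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
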