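import pytest

from gptspectrum.reference import ReferenceGene, load_gpt_reference

TOY_SEQUENCE = "ATGACGTAAAAACGCGT"


@pytest.fixture(scope="session")
def gpt():
    return load_gpt_reference()


@pytest.fixture(scope="session")
def toy():
    """Tiny reference with one CpG cluster and one 5-A run (positions 8-12)."""
    return ReferenceGene(name="toy", sequence=TOY_SEQUENCE)
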