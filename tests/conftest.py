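import pytest
from hypothesis import settings

from codonscan import synthetic_data

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def receptor_fixture():
    """One shared simulated receptor-style dataset with planted ground truth."""
    return synthetic_data.make_receptor_fixture(seed=7)


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">ref\nATGAAACGT\n>alt\nATGAAGCGT\n")
    return path


EIGHT_TAXON_TREE = (
    "((((t1:0.2,t2:0.2):0.1,(t3:0.2,t4:0.2):0.1):0.1,"
    "(t5:0.2,t6:0.2):0.2):0.1,(t7:0.3,t8:0.3):0.1);"
)


@pytest.fixture(scope="session")
def eight_taxon_tree():
    return EIGHT_TAXON_TREE
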