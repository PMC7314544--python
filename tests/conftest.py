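import pytest

from crispredit import simdata
from crispredit.seqio import NucleotideSequence


@pytest.fixture(scope="session")
def sim_locus():
    """A 300-nt locus with one planted motif-perfect guide."""
    return simdata.simulate_locus(300, seed=1)


@pytest.fixture(scope="session")
def sim_reference():
    """A 450-nt amplicon reference for pipeline tests."""
    return simdata.simulate_locus(450, seed=3).locus.seq


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">x\nACGT\n")
    return path


def make_locus(seq, name="locus"):
    return NucleotideSequence(name, seq, allow_n=True)
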