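import pytest

from cladolink import make_demarcation_instance, sequence_set


@pytest.fixture
def acgt_set():
    """The four-DNA-sequence worked example; ids are the sequences."""
    return sequence_set(["ACGT", "ACCT", "ACCG", "CCGT"])


@pytest.fixture
def prop2_set():
    """The chain-plus-outlier binary quadruple whose single-linkage
    topology admits no MST-weight labeling."""
    return make_demarcation_instance(3, 7)


@pytest.fixture
def acgt_fasta(tmp_path, acgt_set):
    from cladolink import write_fasta

    path = tmp_path / "acgt.fasta"
    write_fasta(acgt_set, path)
    return path


@pytest.fixture
def prop2_fasta(tmp_path, prop2_set):
    from cladolink import write_fasta

    path = tmp_path / "prop2.fasta"
    write_fasta(prop2_set, path)
    return path
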