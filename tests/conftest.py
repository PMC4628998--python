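import numpy as np
import pytest
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from kinselect import load_quinalizarin_panel


@pytest.fixture(scope="session")
def raw_panel():
    """Packaged quinalizarin panel, 141 rows as printed."""
    return load_quinalizarin_panel(collapsed=False)


@pytest.fixture(scope="session")
def collapsed_panel():
    """The 140-kinase panel with CK2 represented by the holoenzyme row."""
    return load_quinalizarin_panel(collapsed=True)


def make_alignment(rows):
    """Build a MultipleSeqAlignment from (id, sequence) pairs."""
    return MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in rows]
    )


@pytest.fixture
def write_alignment(tmp_path):
    """Factory writing (id, seq) rows to a FASTA or Clustal file."""

    def _write(rows, fmt="fasta", name="aln"):
        ext = ".fasta" if fmt == "fasta" else ".aln"
        path = tmp_path / (name + ext)
        AlignIO.write(make_alignment(rows), str(path), fmt)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20151019)
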