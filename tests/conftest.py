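import numpy as np
import pytest

from mitopop import Alignment, SampleRecord


@pytest.fixture
def make_alignment():
    """Factory: Alignment from a dict of id -> sequence string."""

    def _make(seqs: dict[str, str], coord_map=None) -> Alignment:
        bases = np.array([list(s) for s in seqs.values()], dtype="<U1")
        return Alignment(list(seqs.keys()), bases, coord_map)

    return _make


@pytest.fixture
def make_meta():
    """Factory: metadata records from a dict of id -> population."""

    def _make(pops: dict[str, str], **extra) -> list[SampleRecord]:
        return [
            SampleRecord(sample_id=s, population=p, **extra) for s, p in pops.items()
        ]

    return _make


@pytest.fixture
def write_fasta(tmp_path):
    """Factory: write sequences to a FASTA file and return its path."""

    def _write(seqs: dict[str, str], name="aln.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, seq in seqs.items():
                fh.write(f">{sid}\n{seq}\n")
        return path

    return _write
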