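import random

import numpy as np
import pytest

from sanslite.sequence_io import db_from_records


@pytest.fixture
def rng():
    return random.Random(20120903)


@pytest.fixture
def nprng():
    return np.random.default_rng(20120903)


@pytest.fixture
def two_protein_db():
    """The minimal worked database: proteins "AB" and "AC"."""
    return db_from_records([("p0", "AB"), ("p1", "AC")])


@pytest.fixture
def fasta_writer(tmp_path):
    def write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return write
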