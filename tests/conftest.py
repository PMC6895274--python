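import pytest

from cescore.msa_io import from_rows


@pytest.fixture
def toy_alignment():
    """5-column, 6-row alignment with a gappy column and an invariant one.

    Query 'Q' = AKDCE; column 3 (query D) carries 2/6 gaps, column 2 is
    invariant K across all rows.
    """
    ids = ("Q", "s1", "s2", "s3", "s4", "s5")
    rows = (
        "AKDCE",
        "AKDCE",
        "SKDME",
        "SK-MD",
        "AK-CD",
        "GKDCE",
    )
    return from_rows(ids, rows, "Q")


@pytest.fixture
def covarying_alignment():
    """8-row alignment whose columns 1 and 2 covary perfectly (A-K / S-E)
    while column 3 varies independently."""
    ids = tuple(f"r{k}" for k in range(8))
    rows = (
        "AKLW",
        "AKFW",
        "SELW",
        "SEFW",
        "AKLW",
        "SEFW",
        "AKFW",
        "SELW",
    )
    return from_rows(ids, rows, "r0")


@pytest.fixture
def fasta_file(tmp_path):
    p = tmp_path / "toy.fasta"
    p.write_text(">Q\nAKD-E\n>A\nAKDCE\n>B\nSKDC-\n")
    return p
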