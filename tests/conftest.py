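import pytest

from famkit.io import AlignedBlock, GeneModel, ProteinRecord


@pytest.fixture
def plus_gene() -> GeneModel:
    """Two-exon gene on the plus strand: CDS lengths 6 and 9."""
    return GeneModel("g1", "chr1", "+", ((1, 6), (10, 18)))


@pytest.fixture
def minus_gene() -> GeneModel:
    """Same intervals on the minus strand (transcription order reversed)."""
    return GeneModel("g1", "chr1", "-", ((10, 18), (1, 6)))


@pytest.fixture
def tiny_records() -> list[ProteinRecord]:
    return [
        ProteinRecord("a", "MKVLW"),
        ProteinRecord("b", "MKVL"),
        ProteinRecord("c", "GGGGG"),
    ]


def make_domain_row(
    col9: str = "H",
    col13: str = "E",
    col16: str = "R",
    col17: str = "R",
    extra_basic: int = 0,
    width: int = 65,
) -> str:
    """A 65-column domain row with controlled rule columns and basic count.

    Non-rule basic-region columns (1-8, 10-12, 14, 15) are filled with
    ``extra_basic`` arginines and alanines elsewhere; everything past the
    basic region is alanine.
    """
    fillers = ["R"] * extra_basic + ["A"] * (13 - extra_basic)
    row = []
    for col in range(1, width + 1):
        if col == 9:
            row.append(col9)
        elif col == 13:
            row.append(col13)
        elif col == 16:
            row.append(col16)
        elif col == 17:
            row.append(col17)
        elif col <= 17:
            row.append(fillers.pop(0))
        else:
            row.append("A")
    return "".join(row)


@pytest.fixture
def perfect_split_alignment() -> AlignedBlock:
    """Every column separates AB from CD, so AB|CD is certain."""
    return AlignedBlock(
        ("A", "B", "C", "D"),
        ("AAAAAAAAAA", "AAAAAAAAAA", "CCCCCCCCCC", "CCCCCCCCCC"),
    )
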