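import pytest

from karyoconvert import load_assembly, make_toy_bandmap


@pytest.fixture(scope="session")
def hg19():
    return load_assembly("hg19")


@pytest.fixture(scope="session")
def toy_map():
    """One chromosome, two acen bands: chr1 = p11 [0,50) + q11 [50,100)."""
    return make_toy_bandmap(1, 1, 100, seed=0)


TABLE1 = [
    ("ABC", "46,XY,der(1;19)(q10;p10)"),
    ("DEF", "47,XX,+der(10)t(10;21)(p13;q21)"),
    ("P_10", "47,X,+X[30]/48,XX,+ 7,+ 9 [50]"),
]

TABLE2 = [
    ("ABC_1", "chr1", 0, 125000000, "Loss", "unknown"),
    ("ABC_1", "chr19", 26500000, 59128983, "Loss", "unknown"),
    ("DEF_1", "chr10", 12200000, 135534747, "Gain", "unknown"),
    ("DEF_1", "chr21", 16400000, 48129895, "Gain", "unknown"),
    ("P_10_1", "chrX", 0, 155270560, "Gain", "30 of 80"),
    ("P_10_2", "chr7", 0, 159138663, "Gain", "50 of 80"),
    ("P_10_2", "chr9", 0, 141213431, "Gain", "50 of 80"),
]
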