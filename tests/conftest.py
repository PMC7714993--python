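import numpy as np
import pytest

from panelkit import GenotypeMatrix, LocusRecord, SampleRecord


@pytest.fixture
def small_loci() -> list[LocusRecord]:
    return [
        LocusRecord("snp1", "1", 100, "A", "C", qual=5000.0),
        LocusRecord("snp2", "1", 2_000_000, "G", "T", qual=20000.0),
        LocusRecord("snp3", "2", 500, "T", "A", qual=15000.0),
        LocusRecord("snp4", "3", 10_000, "C", "G", qual=800.0),
    ]


@pytest.fixture
def small_gm(small_loci) -> GenotypeMatrix:
    dosages = np.array(
        [
            [0, 1, 2, -1],
            [1, 1, 0, 0],
            [2, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["s1", "s2", "s3"], [l.locus_id for l in small_loci], dosages)


@pytest.fixture
def random_gm() -> GenotypeMatrix:
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(3, 4)).astype(np.int8)
    dosages[0, 1] = -1
    return GenotypeMatrix(
        ["a", "b", "c"], ["l1", "l2", "l3", "l4"], dosages
    )


@pytest.fixture
def labelled_metadata() -> list[SampleRecord]:
    return [
        SampleRecord("s1", "plains", 1, "herdA"),
        SampleRecord("s2", "plains", 2, "herdA"),
        SampleRecord("s3", "wood", 1, "herdB"),
    ]
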