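import numpy as np
import pandas as pd
import pytest

from mirswitch.core_io import CountMatrix, SampleSheet, SequenceRecord
from mirswitch.simulate import LET7C


@pytest.fixture
def let7c() -> SequenceRecord:
    return SequenceRecord("gga-let-7c", LET7C, "mature_mirna")


@pytest.fixture
def small_sheet() -> SampleSheet:
    return SampleSheet(
        sample_ids=("s1", "s2", "s3", "s4"),
        stages=("E18", "E18", "D3", "D3"),
        replicates=(1, 2, 1, 2),
        library_sizes=(1_000_000, 1_000_000, 1_000_000, 1_000_000),
    )


@pytest.fixture
def small_mirna_counts(small_sheet) -> CountMatrix:
    counts = pd.DataFrame(
        [[30, 40, 100, 120], [0, 5, 10, 8]],
        index=["mirA", "mirB"],
        columns=list(small_sheet.sample_ids),
    )
    return CountMatrix(counts, small_sheet, "mirna")


@pytest.fixture
def small_mrna_counts(small_sheet) -> CountMatrix:
    counts = pd.DataFrame(
        [[100, 110, 400, 380], [50, 60, 55, 45]],
        index=["geneA", "geneB"],
        columns=list(small_sheet.sample_ids),
    )
    lengths = pd.Series([1000, 2000], index=["geneA", "geneB"], name="length")
    return CountMatrix(counts, small_sheet, "mrna", lengths)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
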