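import numpy as np
import pytest

from methylpanel import builtin_panel, build_design
from methylpanel.panel import Amplicon, GenomicRegion
from methylpanel.simulate import TruthModel, null_truth


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_panel():
    """Two short amplicons with known CpG layout for hand-checkable tests."""
    return [
        Amplicon(
            gene="G1",
            region=GenomicRegion("chr1", 101, 120),
            sequence="AACGTTACGTATCGATTACA",  # CpGs at 3, 8, 13
            declared_n_cpg=3,
            declared_size=20,
        ),
        Amplicon(
            gene="G2",
            region=GenomicRegion("chr2", 51, 66),
            sequence="TTCGACCATGTGTCGA",  # CpGs at 3, 14
            declared_n_cpg=2,
            declared_size=16,
        ),
    ]


@pytest.fixture(scope="session")
def small_design():
    return build_design(
        n_control=4, n_mild=2, n_intermediary=2, n_severe=2,
        n_nec_missing=1, n_duplicated=1, seed=7,
    )


@pytest.fixture(scope="session")
def clean_truth():
    """No planted effects, no conversion failure, no sequencing error."""
    t = null_truth()
    t.conversion_failure = 0.0
    t.sequencing_error = 0.0
    return t
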