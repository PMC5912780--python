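import numpy as np
import pytest

from crispr_chromatin import SimulationConfig, simulate_study
from crispr_chromatin.genomic_io import GenomicInterval, Peak


@pytest.fixture(scope="session")
def small_study():
    """A 30-gene synthetic study shared by read-only tests."""
    return simulate_study(SimulationConfig(n_genes=30, seed=11))


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, small_study):
    """The small study written out as a file bundle."""
    from crispr_chromatin import write_study

    out = tmp_path_factory.mktemp("bundle")
    return write_study(small_study, out)


def make_peak(chrom, start, end, signal=1.0, name="p"):
    return Peak(GenomicInterval(chrom, start, end), name=name, signal_value=signal)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
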