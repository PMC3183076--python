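import numpy as np
import pytest

from hdna import SimConfig


def octad_signatures(n_markers: int, phase=(1, 1, 0, 0)) -> np.ndarray:
    """Mendelian octad call matrix: each chromatid's two cells carry its
    parental allele at every marker."""
    return np.tile(np.repeat(np.asarray(phase, dtype=np.int8), 2), (n_markers, 1))


def tetrad_signatures(n_markers: int, phase=(1, 1, 0, 0)) -> np.ndarray:
    return np.tile(np.asarray(phase, dtype=np.int8), (n_markers, 1))


@pytest.fixture
def small_sim_config() -> SimConfig:
    """Scaled-down genome keeping the study's marker density and DSB density
    per bp (four 800 kb chromosomes, 40 DSBs expected)."""
    return SimConfig(chromosome_sizes=[800_000] * 4, dsb_mean=40.0)
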