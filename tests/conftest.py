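import numpy as np
import pandas as pd
import pytest

from sdmap.genmap import MapAnchor, fit_map
from sdmap.io import library_frame
from sdmap.simulate import SimulationConfig, simulate_counts


@pytest.fixture
def linear_map():
    """1 cM/Mb over a 25 Mb chromosome named 'chr1'."""
    return fit_map([MapAnchor("chr1", 1, 0.0), MapAnchor("chr1", 25_000_000, 25.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


def make_paired_counts(n=200, seed=0, k=0.5, depth=30, length=25_000_000,
                       chromosome="chr1", **kwargs):
    cfg = SimulationConfig(
        n_sites=n, chrom_length=length, depth=depth, k=k,
        chromosome=chromosome, **kwargs,
    )
    sim = simulate_counts(cfg, seed=seed)
    return sim


def split_libs(counts: pd.DataFrame):
    return library_frame(counts, "germ"), library_frame(counts, "soma")


@pytest.fixture
def distorted_sim():
    """A strongly distorted chromosome (k = 0.64) at moderate size."""
    return make_paired_counts(n=1500, seed=11, k=0.64, depth=40, chromosome="sim1")


@pytest.fixture
def mendelian_sim():
    return make_paired_counts(n=1500, seed=12, k=0.5, depth=40, chromosome="sim1")
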