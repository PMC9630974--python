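import numpy as np
import pytest

from tissuemix.synthetic_data import SimulationConfig, simulate_two_tissue_sample

# study-condition configs: BH3-2-like PGE male and the X0 control, at a
# genome size giving >1e4 autosomal heterozygous sites
PGE_CONFIG = SimulationConfig(genome_size=8_000_000, fh_true=0.35, depth_2n=28.7, seed=7)
X0_CONFIG = SimulationConfig(genome_size=8_000_000, fh_true=0.0, depth_2n=28.7, seed=11)


@pytest.fixture(scope="session")
def pge_sample():
    return simulate_two_tissue_sample(PGE_CONFIG)


@pytest.fixture(scope="session")
def x0_sample():
    return simulate_two_tissue_sample(X0_CONFIG)


@pytest.fixture(scope="session")
def pge_bundle_dir(tmp_path_factory):
    """The PGE fixture written out as files (VCF, sync, tables, histogram)."""
    outdir = tmp_path_factory.mktemp("pge_bundle")
    simulate_two_tissue_sample(PGE_CONFIG, outdir=str(outdir))
    return outdir


@pytest.fixture(scope="session")
def x0_bundle_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("x0_bundle")
    simulate_two_tissue_sample(X0_CONFIG, outdir=str(outdir))
    return outdir


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
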