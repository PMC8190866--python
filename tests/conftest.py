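import pytest

from eretarget.ere_scan import ScorePValueTable, default_ere_motif
from eretarget.synthetic_data import SimConfig, generate


@pytest.fixture(scope="session")
def ere_motif():
    return default_ere_motif()


@pytest.fixture(scope="session")
def ere_table(ere_motif):
    return ScorePValueTable(ere_motif)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default-condition synthetic bundle, shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate(SimConfig(seed=11), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def big_bundle(tmp_path_factory):
    """Default conditions at 1,000 peaks (genome sized up to stay feasible)."""
    outdir = tmp_path_factory.mktemp("big_bundle")
    cfg = SimConfig(seed=1, n_peaks=1000, genome_length=2_600_000)
    truth = generate(cfg, outdir)
    return outdir, truth, cfg
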