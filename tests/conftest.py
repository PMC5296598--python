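import numpy as np
import pytest

from attmut import pipeline
from attmut.sim import SimConfig, build_att_locus


@pytest.fixture(scope="session")
def scarred_locus():
    """A 12B01-style locus: 2-bp scar riding on the left att core."""
    return build_att_locus(
        upstream_len=120, element_len=400, core_len=12, scar_offset=2,
        seed=11, downstream_len=210,
    )


@pytest.fixture(scope="session")
def clean_locus():
    """A locus whose excision restores the host gene exactly."""
    return build_att_locus(
        upstream_len=120, element_len=400, core_len=12, scar_offset=0,
        seed=12, downstream_len=210,
    )


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_lineages=3,
        n_rounds=4,
        genome_length=150_000,
        rate_mutator=0.1,
        rate_hypermutator=1.5,
        p_excise_per_round=0.5,
        p_reintegrate_per_round=0.2,
        seed=42,
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    """A small simulated study bundle on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle") / "study"
    truth = pipeline.run_simulate(small_config, outdir, element_length=5_000)
    return outdir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
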