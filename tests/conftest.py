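import pytest

from psychrocomp.pipeline import PipelineConfig, run_pipeline
from psychrocomp.synthetic_data import SimConfig, simulate_collection

SMALL_SIM = SimConfig(
    seed=11,
    hierarchy_sizes=(5, 3, 2),
    families_per_level=(20, 10, 8),
    private_families=5,
    n_hgt=4,
    mean_protein_len=150,
)


@pytest.fixture(scope="session")
def small_collection():
    """A 5-genome collection with planted nesting, shifts and transfers."""
    return simulate_collection(SMALL_SIM)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on the small collection, shared across tests."""
    workdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        workdir=str(workdir),
        seed=SMALL_SIM.seed,
        simulate=SMALL_SIM,
        conservation="inner",
        gc_correlation=True,
    )
    return cfg, run_pipeline(cfg)
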