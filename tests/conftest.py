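import numpy as np
import pytest

from sirtqsar.synthetic import SyntheticSARConfig, generate_synthetic_sar


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230114)


@pytest.fixture(scope="session")
def small_sar():
    """A small planted-signal dataset shared across tests (records, truth)."""
    cfg = SyntheticSARConfig(n_compounds=250, seed=11)
    return generate_synthetic_sar(cfg)


@pytest.fixture(scope="session")
def small_sar_csv(tmp_path_factory, small_sar):
    records, _ = small_sar
    path = tmp_path_factory.mktemp("sar") / "records.csv"
    records.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One small end-to-end pipeline run shared by workflow tests."""
    from sirtqsar.pipeline import PipelineConfig, run_pipeline

    workdir = tmp_path_factory.mktemp("mini_run")
    cfg = PipelineConfig(
        workdir=str(workdir), seed=3, budget=2, n_scramble=3,
        decoy_n_actives=4,
        synthetic=SyntheticSARConfig(n_compounds=250, seed=3),
    )
    report = run_pipeline(cfg)
    return cfg, report, workdir
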