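import pytest

from oocyteflux.library import load_reference_library, load_transporter_models
from oocyteflux.pipeline import PipelineConfig, run_profile, run_simulate


@pytest.fixture(scope="session")
def library():
    return load_reference_library()

@pytest.fixture(scope="session")
def by_name(library):
    return {rec.name: rec for rec in library}

@pytest.fixture(scope="session")
def transporters():
    return {m.name: m for m in load_transporter_models()}


@pytest.fixture(scope="session")
def snat2_result(tmp_path_factory):
    """One full simulate->profile run on a default SNAT2-like batch, shared
    across tests (regenerating it is covered by the determinism test)."""
    root = tmp_path_factory.mktemp("snat2")
    cfg = PipelineConfig(transporter="SNAT2-like", seed=1)
    run_simulate(cfg, root / "batch")
    result = run_profile(root / "batch", cfg, outdir=root / "reports")
    return cfg, root, result
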