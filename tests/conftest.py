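import numpy as np
import pytest

from ccfdgrid import AnalysisConfig, ScenarioParams, generate_case, run_case


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_case():
    """One rendered four-visit case (null scenario, default conditions)."""
    params = ScenarioParams(rng_seed=42)
    visits, truth = generate_case(params)
    return params, visits, truth


@pytest.fixture(scope="session")
def default_case_result(default_case, config):
    _, visits, _ = default_case
    return run_case(visits, config)


def make_image(arr, **kw):
    from ccfdgrid import EnFaceImage
    return EnFaceImage(np.asarray(arr, dtype=float), **kw)
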