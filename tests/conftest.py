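import pytest

from panorder.pipeline import run_pipeline
from panorder.synth import ScenarioConfig, generate, preset_scenarios


@pytest.fixture(scope="session")
def presets():
    return preset_scenarios(0)


@pytest.fixture(scope="session")
def collinear_pg(presets):
    return generate(presets["collinear"])


@pytest.fixture(scope="session")
def collinear_result(collinear_pg):
    return run_pipeline(collinear_pg.alignment_blocks, collinear_pg.catalog)


@pytest.fixture(scope="session")
def inversion_pg(presets):
    return generate(presets["inversion"])


@pytest.fixture(scope="session")
def inversion_result(inversion_pg):
    return run_pipeline(inversion_pg.alignment_blocks, inversion_pg.catalog)


@pytest.fixture(scope="session")
def translocation_pg(presets):
    return generate(presets["translocation"])


@pytest.fixture(scope="session")
def translocation_result(translocation_pg):
    return run_pipeline(translocation_pg.alignment_blocks, translocation_pg.catalog)


def make_scenario(seed: int, **overrides) -> ScenarioConfig:
    defaults = dict(
        n_genomes=4, n_core=20, n_dispensable=8, n_unique_per_genome=3, seed=seed
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)
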