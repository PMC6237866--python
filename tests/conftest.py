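import pytest

from petkin import core, synthetic as syn


@pytest.fixture(scope="session")
def schedule():
    return core.make_study_schedule()


@pytest.fixture(scope="session")
def aif():
    return syn.AifParams()


@pytest.fixture(scope="session")
def hill():
    return syn.HillParams()


@pytest.fixture(scope="session")
def atlas():
    return syn.make_synthetic_atlas()


@pytest.fixture(scope="session")
def regional_params():
    """Male-mean kinetics for every atlas region (cerebellum k3 = 0)."""
    return {r: syn.tcm_for_bpnd(m[1]) for r, m in syn.default_region_means().items()}


@pytest.fixture(scope="session")
def noiseless_phantom(atlas, regional_params, aif, schedule):
    return syn.build_phantom(atlas, regional_params, aif, schedule,
                             noise_fraction=0.0, seed=0)
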