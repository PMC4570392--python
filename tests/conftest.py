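import pytest

from uavweed import compact_scenario, generate_scene, render_image


@pytest.fixture(scope="session")
def compact_field():
    """One 24 x 24 m field shared by the read-only tests."""
    scenario = compact_scenario(seed=1)
    truth = generate_scene(scenario)
    return scenario, truth


@pytest.fixture(scope="session")
def rgb_image(compact_field):
    scenario, truth = compact_field
    return render_image(truth, scenario, 1.07, "RGB")


@pytest.fixture(scope="session")
def rnir_image(compact_field):
    scenario, truth = compact_field
    return render_image(truth, scenario, 1.6, "R-NIR")
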