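import numpy as np
import pytest

from conephys import FlashTemplateParams, template_for


@pytest.fixture(scope="session")
def fs() -> float:
    return 10_000.0


@pytest.fixture(scope="session")
def generic_template() -> FlashTemplateParams:
    """A representative flash template (not tied to any calibration entry)."""
    return FlashTemplateParams(8.0, 30.0, 30.0, 180.0, -np.pi / 4)


@pytest.fixture(scope="session")
def s_cone_template() -> FlashTemplateParams:
    return template_for("S", 5000.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
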