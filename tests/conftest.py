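import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from flightload.optics import OpticsConfig
from flightload.series import HemoglobinSeries
from flightload.task_engine import OperatorProfile, TaskConfig


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture
def default_profile():
    return OperatorProfile()


@pytest.fixture
def random_hemo():
    """8-channel random hemoglobin series on the standard 2-Hz grid."""
    rng = np.random.default_rng(42)
    t = np.arange(480) / 2.0
    return HemoglobinSeries(t_s=t, delta_hbo=rng.normal(size=(8, 480)),
                            delta_hbr=rng.normal(size=(8, 480)))


def make_task(condition="low", seed=0, **kw):
    return TaskConfig(condition=condition, rng_seed=seed, **kw)
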