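import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240904)


@pytest.fixture
def survey_csv(tmp_path):
    """A tiny valid survey CSV in the standard age,haz,whz,waz,wt schema."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "age,haz,whz,waz,wt\n"
        "24,-1.2,0.3,-0.5,1.0\n"
        "36.5,-2.4,,-1.1,2.0\n"
        "10,0.1,-0.2,0.4,0.5\n"
    )
    return path
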