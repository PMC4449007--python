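import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    from gt43scan import default_panel

    return default_panel()


@pytest.fixture()
def sim_dir(tmp_path):
    """A small simulated study with planted truth."""
    from gt43scan import simulate_dataset

    paths = simulate_dataset(5, 5, seed=11, outdir=tmp_path / "sim")
    return paths
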