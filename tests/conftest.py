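import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")

from chemofdt.synthetic_data import make_fixture  # noqa: E402


@pytest.fixture(scope="session")
def wt_ensemble():
    """200 wild-type-in-buffer cells, 1800 s (OU τ=9.5 s, V_A=0.46, shot)."""
    return make_fixture("wt_buffer", 200, 1)


@pytest.fixture(scope="session")
def rb_ensemble():
    """200 adaptation-deficient cells at intermediate activity (τ=34 s)."""
    return make_fixture("rb_minus_intermediate", 200, 1)


@pytest.fixture(scope="session")
def receptorless_ensemble():
    """100 receptorless (shot-noise-only) control cells."""
    return make_fixture("receptorless", 100, 2)


@pytest.fixture(scope="session")
def wt_psd(wt_ensemble):
    from chemofdt.spectral import compute_psd
    return compute_psd(wt_ensemble)


@pytest.fixture(scope="session")
def rb_psd(rb_ensemble):
    from chemofdt.spectral import compute_psd
    return compute_psd(rb_ensemble)


@pytest.fixture(scope="session")
def noise_psd(receptorless_ensemble):
    from chemofdt.spectral import compute_psd
    return compute_psd(receptorless_ensemble)
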