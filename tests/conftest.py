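import numpy as np
import pytest

from duplexkin import build_preset, simulate_equilibrium

PRESET_NAMES = ["AT-all", "GC-end", "GC-core", "GC-mix"]


@pytest.fixture(scope="session", params=PRESET_NAMES)
def preset(request):
    return build_preset(request.param)


@pytest.fixture(scope="session")
def at_all():
    return build_preset("AT-all")


@pytest.fixture(scope="session")
def gc_mix():
    return build_preset("GC-mix")


@pytest.fixture(scope="session")
def gc_core():
    return build_preset("GC-core")


@pytest.fixture(scope="session")
def small_traj(at_all):
    """20k-frame AT-all equilibrium trajectory shared across tests."""
    return simulate_equilibrium(at_all, 20_000, 0.6, seed=42)


def rng(seed=0):
    return np.random.default_rng(seed)
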