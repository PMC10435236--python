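import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gbcsim import cable, membrane
from gbcsim import morphology as mor
from gbcsim import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_cell() -> mor.Morphology:
    """Reference toy GBC morphology (mean population geometry)."""
    return syn.make_toy_cell(syn.CellTemplate(), seed=2)


@pytest.fixture(scope="session")
def toy_model_half_active(toy_cell):
    """Decorated half-active toy GBC with the default channel scale."""
    from gbcsim import experiments as X

    return X.build_gbc(toy_cell, "half_active")


@pytest.fixture()
def passive_compartment():
    """Single-compartment passive cylinder (1460 um^2, leak only)."""
    L = float(np.sqrt(1460.0 / np.pi))
    sec = mor.Section(
        0, None, mor.Tag.SOMA, np.array([[0.0, 0.0, 0.0, L / 2], [L, 0.0, 0.0, L / 2]])
    )
    model = cable.discretize(mor.Morphology([sec]), Ra=150.0, cm=0.9)
    model.density["Leak"][:] = 0.1385
    return model


def rc_constants(model):
    """(R_MOhm, C_nF, tau_ms) of a leak-only model, from its parameters."""
    area = model.area.sum()
    g_uS = float((model.density["Leak"] * model.area).sum() * 1e-5)
    c_nF = float(model.cm * area * 1e-5)
    return 1.0 / g_uS, c_nF, c_nF / g_uS
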