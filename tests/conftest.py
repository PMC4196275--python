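import numpy as np
import pytest

from cisclock.grn_model import GrnModel, ParameterSet, canonical_initial_state


@pytest.fixture(scope="session")
def model() -> GrnModel:
    return GrnModel()


def run_two_cell(model: GrnModel, minutes: float, dt: float = 0.1,
                 scale=(1.0, 1.0), record: str = "hes7.mC") -> np.ndarray:
    """Integrate the mutually coupled two-cell system; returns (n_t, 2)."""
    S = np.tile(canonical_initial_state(model), (2, 1))
    S *= np.asarray(scale)[:, None]
    i_d = model.index["dll1.pM"]
    i_n = model.index["notch1.pM"]
    i_r = model.index[record]
    n = int(round(minutes / dt))
    out = np.empty((n + 1, 2))
    out[0] = S[:, i_r]
    for t in range(n):
        nb_d = S[::-1, i_d].copy()
        nb_n = S[::-1, i_n].copy()
        S = np.maximum(S + dt * model.derivatives(S, nb_d, nb_n), 0.0)
        out[t + 1] = S[:, i_r]
    return out


@pytest.fixture(scope="session")
def two_cell_trace(model) -> np.ndarray:
    """Synchronized default two-cell run, 3000 min at dt=0.1."""
    return run_two_cell(model, 3000.0)
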