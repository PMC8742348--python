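import numpy as np
import pytest

from nucleodyn.types import FcsParams


@pytest.fixture
def two_population_params() -> FcsParams:
    """A representative full model: half free, 30% short-, 20% long-bound."""
    return FcsParams(
        n_molecules=2.0,
        f_diff=0.5,
        f_short=0.3,
        f_long=0.2,
        tau_diff=2e-3,
        omega=5.0,
        tau_short=2e-2,
        tau_long=1.5,
    )


@pytest.fixture
def lag_grid() -> np.ndarray:
    """Log-spaced lags spanning 10 us .. 10 s (6 decades)."""
    return np.geomspace(1e-5, 10.0, 160)
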