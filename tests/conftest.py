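import numpy as np
import pytest

from adaptsat import (
    ParameterGrid,
    SATParams,
    SOADesign,
    SessionConfig,
    VirtualParticipant,
    build_grid,
)


@pytest.fixture
def small_grid() -> ParameterGrid:
    """A 5 x 4 x 3 grid cheap enough for exhaustive checks."""
    return build_grid(
        lam_range=(0.4, 0.5), n_lam=5,
        gamma_range=(5.0, 25.0), n_gamma=4,
        delta_range=(0.05, 0.35), n_delta=3,
    )


@pytest.fixture
def toy2_grid() -> ParameterGrid:
    """Two cells differing only in asymptote; at long RT psi -> (0.6, 0.9)."""
    return ParameterGrid([0.1, 0.4], [30.0], [0.02])


@pytest.fixture
def design() -> SOADesign:
    return SOADesign.default()


@pytest.fixture
def tiny_config(small_grid) -> SessionConfig:
    """Short two-condition session on the small grid for fast end-to-end runs."""
    return SessionConfig(
        grid=small_grid,
        soa_design=SOADesign(np.linspace(0.0, 1.2, 13)),
        n_blocks=3,
        n_per_condition=4,
    )


@pytest.fixture
def participant() -> VirtualParticipant:
    return VirtualParticipant({
        "congruent": SATParams(0.45, 25.0, 0.20),
        "incongruent": SATParams(0.45, 25.0, 0.30),
    })
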