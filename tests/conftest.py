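import numpy as np
import pytest

from gsemkit import presets
from gsemkit.ldblocks import LdBlockDesign


@pytest.fixture
def small_design():
    """Desk-scale block design (M=2000) for fast unit tests."""
    n_blocks = 50
    return LdBlockDesign(
        n_blocks=n_blocks, m=40,
        r1=np.linspace(0.05, 0.5, n_blocks),
        r2=np.linspace(0.1, 0.45, n_blocks),
    )


@pytest.fixture
def nine_trait_run():
    """One simulated nine-trait panel with its S/V structure (module-scope
    work kept small: preset LD design but a single replicate)."""
    import gsemkit as gk

    scenario = presets.fourfactor9(seed=42)
    panel, truth = gk.simulate_panel(scenario)
    structure = gk.build_S_V(panel)
    return scenario, panel, truth, structure
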