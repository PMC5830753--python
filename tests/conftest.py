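import numpy as np
import pytest
from dataclasses import replace

from casparks import SimulationConfig, generate_layout, run_fig2_quark
from casparks.simulator import run_simulation


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def coarse_single_cfg():
    """5x5 µm single-site domain at the coarse mesh used for fast tests."""
    return SimulationConfig().with_(
        domain_size_x=5.0, domain_size_y=5.0, mesh_size=0.1,
        single_site=True, duration=0.08)


@pytest.fixture(scope="session")
def quark_run():
    """Forced single-rogue 20 ms opening (the QCR-QCD pair protocol),
    coarse mesh for speed; shared across observable/simulator tests."""
    return run_fig2_quark(mesh_size=0.1, seed=1)


@pytest.fixture(scope="session")
def spark_run(coarse_single_cfg):
    """Forced single-CRU opening with spontaneous gating disabled."""
    cfg = coarse_single_cfg.with_(
        duration=0.06, record_linescan=True,
        gating=replace(coarse_single_cfg.gating, p_max=0.0))
    layout = generate_layout(cfg, 1)
    cru = layout.sites[0].units[0]
    return run_simulation(cfg, layout=layout, seed=1,
                          forced_openings=[(0.0, 0, 0)],
                          probes=[cru.position], record_lumen_sites=[0])
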