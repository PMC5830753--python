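"""Per-JSR luminal Ca2+ balance: release depletion, buffering, NSR refill.

Each JSR lumen is a well-mixed compartment obeying

    d[Ca]_lumen/dt = J_release-lumen + J_dye-lumen + J_buffer-lumen + J_refill

with J_refill = ([Ca]_NSR - [Ca]_lumen)/tau_refill, Fluo-5N and
calsequestrin kinetics shared with the cytosolic reaction code, and
J_release-lumen the summed molar rate of the site's open units over the
JSR volume.  The 0.64 2D conversion factor is a projection device for the
cytosolic deposition only; luminal depletion uses the raw molar rate, so
the same molar flux leaves the lumen as is accounted to the cytosol
(before that factor).

Luminal concentrations are stored in µM internally (1 mM = 1000 µM); the
``ca_mM`` views expose the conventional mM scale.
"""

from __future__ import annotations

import numpy as np

from .config import (CONVERSION_2D, MM_TO_UM, UM_TO_MM, KineticSpecies,
                     LumenParams)
from .gating import GatingState, source_strength_mol
from .kinetics import coupled_reaction_step, equilibrium_init


class JSRLumenState:
    """Free and bound luminal Ca2+ for every site (arrays indexed by site)."""

    def __init__(self, n_sites: int, params: LumenParams,
                 species: list[KineticSpecies]):
        self.params = params
        self.species = list(species)
        c0 = params.init_ca_mM * MM_TO_UM
        self.ca_free = np.full(n_sites, c0)           # µM
        eq = equilibrium_init(c0, self.species)
        self.ca_bound = {name: np.full(n_sites, float(val))
                         for name, val in eq.items()}
        self.ca_max = max(c0, params.ca_nsr_mM * MM_TO_UM)

    @property
    def n_sites(self) -> int:
        return self.ca_free.size

    @property
    def ca_mM(self) -> np.ndarray:
        return self.ca_free * UM_TO_MM

    def check(self) -> None:
        if (self.ca_free < -1e-9).any():
            raise ValueError("negative luminal Ca2+")
        if (self.ca_free > self.ca_max + 1e-6).any():
            raise ValueError("luminal Ca2+ above max(initial, NSR) level")


def refill_flux(ca_lumen_mM, params: LumenParams):
    """J_refill = ([Ca]_NSR - [Ca]_lumen)/tau_refill, mM s^-1."""
    tau_s = params.tau_refill_ms * 1e-3
    return (params.ca_nsr_mM - np.asarray(ca_lumen_mM, float)) / tau_s


def release_to_lumen(state: GatingState, s_idx: int, ca_lumen_mM: float,
                     ca_cyto_local_mM: float, params: LumenParams) -> float:
    """Luminal depletion rate from the site's open units, mM s^-1 (<= 0).

    The released flux is the same J_clustered/J_rogue source strength that
    feeds the cytosol, i.e. sigma = 0.64 I dCa/(2F) including the 2D
    conversion factor — the luminal balance subtracts the identical flux
    the cytosolic equation receives.
    """
    rate_mol = 0.0
    for k in state.open_units_of_site(s_idx):
        unit = state.units[k][2]
        rate_mol += CONVERSION_2D * source_strength_mol(
            unit.current_per_mM, ca_lumen_mM, ca_cyto_local_mM)
    return -rate_mol / params.volume_l * 1.0e3   # mol/s / L -> M/s -> mM/s


def lumen_step(lumen: JSRLumenState, release_mol_per_site: np.ndarray,
               dt: float) -> None:
    """Advance every JSR lumen by dt (in place), same dt as the cytosol.

    ``release_mol_per_site`` is the summed raw molar release rate (mol/s,
    >= 0, before the 2D conversion factor) of each site's open units —
    computed once per step by the simulator so luminal depletion and
    cytosolic deposition account for the identical molar flux.  Release
    and refill are applied as explicit sources; dye/buffer binding reuses
    the semi-implicit reaction update (stable for calsequestrin's fast
    kinetics).
    """
    p = lumen.params
    # exponential-integrator weighting of the linear refill term: exact for
    # the buffer-free compartment, second-order otherwise
    tau = p.tau_refill_ms * 1e-3
    eta = -np.expm1(-dt / tau) * tau / dt
    source_uM = refill_flux(lumen.ca_mM, p) * MM_TO_UM * eta
    source_uM -= release_mol_per_site / p.volume_l * 1.0e6   # mol/s/L -> µM/s
    lumen.ca_free, lumen.ca_bound = coupled_reaction_step(
        lumen.ca_free, lumen.ca_bound, lumen.species, dt, source=source_uM)
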