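"""Stochastic gating of clustered and rogue RyRs and their release sources.

A closed unit opens in a time step with probability

    P_firing = P_cyto * Phi_lumen
    P_cyto   = 1 - (1 - p_1)^n_RyR,   p_1 = 1 - exp(-p_ryr(c_local) dt)
    Phi_lumen = phi(c_lumen)^m,       phi(c) = (c / c_NSR)^nu  (clipped to 1)

with p_ryr a Hill hazard of the cytosolic Ca2+ in the grid cell containing
the unit, m = 1 for rogue and m = 10 for clustered units.  An open unit
releases for its fixed duration (20 ms rogue / 10 ms clustered), then
closes and stays refractory for a configurable period.

Source strengths follow sigma = 0.64 I (c_lumen - c_cyto)/(2F) with the
currents 0.07 / 0.7 pA mM^-1; each open unit deposits its strength into
exactly the grid cell containing it (discrete Dirac delta over the cell
volume h^2 x 1 µm).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .config import (CONVERSION_2D, FARADAY, SLAB_DEPTH_UM, UM_TO_MM,
                     GatingParams)
from .geometry import ReleaseUnit, RyRLayout

CLOSED, OPEN, REFRACTORY = 0, 1, 2


@dataclass
class EventRecord:
    site_id: int
    kind: str
    unit_index: int            # index within the site's unit tuple
    position: tuple[float, float]
    t_open: float              # s
    duration_ms: float
    ca_local: float            # µM at the opening instant
    forced: bool = False


@dataclass
class EventLog:
    """Append-only ground-truth record of channel openings."""

    records: list[EventRecord] = field(default_factory=list)

    def append(self, rec: EventRecord) -> None:
        self.records.append(rec)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def of_kind(self, kind: str) -> list[EventRecord]:
        return [r for r in self.records if r.kind == kind]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_open_s", "duration_ms", "kind", "site_id",
                        "unit_index", "x_um", "y_um", "ca_local_uM", "forced"])
            for r in self.records:
                w.writerow([f"{r.t_open:.6f}", r.duration_ms, r.kind,
                            r.site_id, r.unit_index,
                            f"{r.position[0]:.4f}", f"{r.position[1]:.4f}",
                            f"{r.ca_local:.4f}", int(r.forced)])


class GatingState:
    """Open/closed/refractory bookkeeping for every unit of a layout.

    Units are indexed by (site_index, unit_index) flattened in layout
    order: for each site, CRUs first, then rogues.
    """

    def __init__(self, layout: RyRLayout):
        self.layout = layout
        self.units: list[tuple[int, int, ReleaseUnit]] = []
        for s_idx, site in enumerate(layout.sites):
            for u_idx, unit in enumerate(site.units):
                self.units.append((s_idx, u_idx, unit))
        n = len(self.units)
        self.status = np.full(n, CLOSED, dtype=np.int8)
        self.scheduled_close = np.full(n, np.inf)
        self.refractory_until = np.zeros(n)
        self.site_index = np.array([s for s, _, _ in self.units], dtype=int)
        self.kind_rogue = np.array(
            [u.kind == "rogue" for _, _, u in self.units])
        self.n_channels = np.array(
            [u.n_channels for _, _, u in self.units], dtype=float)
        self.release_ms = np.array(
            [u.release_time_ms for _, _, u in self.units])
        self.current = np.array(
            [u.current_per_mM for _, _, u in self.units])
        self.pos = np.array([u.position for _, _, u in self.units])

    @property
    def n_units(self) -> int:
        return len(self.units)

    def open_mask(self) -> np.ndarray:
        return self.status == OPEN

    def open_units_of_site(self, s_idx: int) -> np.ndarray:
        return np.flatnonzero((self.status == OPEN)
                              & (self.site_index == s_idx))


# ---------------------------------------------------------------------------
# Elementary probability pieces (Eq-level contracts).
# ---------------------------------------------------------------------------

def p_cyto(p_single: float | np.ndarray, n_channels) -> float | np.ndarray:
    """Cluster-coupled opening probability 1 - (1 - P_RyR)^n."""
    return 1.0 - (1.0 - np.asarray(p_single, float)) ** np.asarray(n_channels)


def p_ryr(ca_local, params: GatingParams):
    """Single-channel opening hazard (s^-1), Hill in local cytosolic Ca2+."""
    c = np.maximum(np.asarray(ca_local, float), 0.0)
    cg = c ** params.gamma
    return params.p_max * cg / (cg + params.k_p ** params.gamma)


def phi_lumen(ca_lumen_mM, m: float, params: GatingParams,
              ca_nsr_mM: float | None = None):
    """Luminal regulation factor Phi = phi^m, phi = (c/c_ref)^nu, in [0, 1].

    The reference load c_ref is the physiological NSR level (1.0 mM,
    ``params.phi_ref_mM``) — a fixed property of the regulation curve, not
    the configured NSR of a particular sweep condition.
    """
    ref = params.phi_ref_mM if ca_nsr_mM is None else ca_nsr_mM
    c = np.maximum(np.asarray(ca_lumen_mM, float), 0.0)
    phi = np.minimum((c / ref) ** params.phi_exponent, 1.0)
    return phi ** m

def firing_prob(ca_local, ca_lumen_mM, unit: ReleaseUnit, dt: float,
                params: GatingParams, ca_nsr_mM: float | None = None):
    """Per-step opening probability of one closed unit."""
    p1 = 1.0 - np.exp(-p_ryr(ca_local, params) * dt)
    m = params.m_rogue if unit.kind == "rogue" else params.m_clustered
    p = p_cyto(p1, unit.n_channels) * phi_lumen(ca_lumen_mM, m, params,
                                                ca_nsr_mM)
    return np.minimum(p, 1.0)


def source_strength_mol(current_pA_per_mM: float, ca_lumen_mM: float,
                        ca_cyto_mM: float) -> float:
    """Raw molar release rate I*dCa/(2F) in mol s^-1 (driving force >= 0)."""
    d = max(ca_lumen_mM - ca_cyto_mM, 0.0)
    return current_pA_per_mM * 1.0e-12 * d / (2.0 * FARADAY)


def source_strength(unit: ReleaseUnit, ca_lumen_mM: float,
                    ca_cyto_local_uM: float, mesh_size: float) -> float:
    """Cytosolic deposition rate of one open unit, µM s^-1 per grid cell.

    Applies the 0.64 2D conversion and spreads the molar rate over the
    cell volume h^2 x SLAB_DEPTH_UM (unit-depth slab convention).
    """
    mol = CONVERSION_2D * source_strength_mol(
        unit.current_per_mM, ca_lumen_mM, ca_cyto_local_uM * UM_TO_MM)
    cell_volume_l = mesh_size * mesh_size * SLAB_DEPTH_UM * 1.0e-15
    return mol / cell_volume_l * 1.0e6   # mol/L -> µM


def _cell_index(pos, mesh_size, nx, ny):
    ix = min(max(int(pos[0] / mesh_size), 0), nx - 1)
    iy = min(max(int(pos[1] / mesh_size), 0), ny - 1)
    return iy, ix


def deposit_sources(state: GatingState, ca_free: np.ndarray,
                    lumen_ca_mM: np.ndarray, mesh_size: float) -> np.ndarray:
    """Rate field (µM s^-1) from all open units (discrete delta deposition).

    ``lumen_ca_mM`` holds the free luminal Ca2+ of each site (mM), indexed
    by site.  Co-located open units add linearly.
    """
    ny, nx = ca_free.shape
    out = np.zeros_like(ca_free)
    for k in np.flatnonzero(state.open_mask()):
        s_idx, _, unit = state.units[k]
        iy, ix = _cell_index(unit.position, mesh_size, nx, ny)
        out[iy, ix] += source_strength(unit, float(lumen_ca_mM[s_idx]),
                                       float(ca_free[iy, ix]), mesh_size)
    return out


def step_gating(state: GatingState, t: float, dt: float,
                ca_free: np.ndarray, lumen_ca_mM: np.ndarray,
                params: GatingParams, rng: np.random.Generator,
                log: EventLog, mesh_size: float,
                ca_nsr_mM: float | None = None,
                forced: list[tuple[int, int]] | None = None) -> None:
    """One stochastic gating update (in place).

    Closes units past their scheduled close time (entering refractory),
    then draws openings for closed, non-refractory units.  ``forced`` is a
    list of (site_index, unit_index) pairs to open unconditionally at this
    step (the forced-opening hook used by the single-event protocols).
    """
    ny, nx = ca_free.shape
    # close due units
    due = (state.status == OPEN) & (t >= state.scheduled_close)
    state.status[due] = REFRACTORY if params.refractory_ms > 0 else CLOSED
    state.refractory_until[due] = t + params.refractory_ms * 1e-3
    # release refractory units
    done = (state.status == REFRACTORY) & (t >= state.refractory_until)
    state.status[done] = CLOSED

    def open_unit(k, forced_flag):
        s_idx, u_idx, unit = state.units[k]
        iy, ix = _cell_index(unit.position, mesh_size, nx, ny)
        state.status[k] = OPEN
        state.scheduled_close[k] = t + unit.release_time_ms * 1e-3
        log.append(EventRecord(state.layout.sites[s_idx].site_id, unit.kind,
                               u_idx, unit.position, t, unit.release_time_ms,
                               float(ca_free[iy, ix]), forced_flag))

    if forced:
        site_of = {(s, u): True for s, u in forced}
        for k, (s_idx, u_idx, _) in enumerate(state.units):
            if (s_idx, u_idx) in site_of and state.status[k] == CLOSED:
                open_unit(k, True)

    closed = np.flatnonzero(state.status == CLOSED)
    if closed.size == 0:
        return
    # local Ca2+ at each closed unit's cell
    ix = np.clip((state.pos[closed, 0] / mesh_size).astype(int), 0, nx - 1)
    iy = np.clip((state.pos[closed, 1] / mesh_size).astype(int), 0, ny - 1)
    c_local = ca_free[iy, ix]
    p1 = 1.0 - np.exp(-p_ryr(c_local, params) * dt)
    pc = p_cyto(p1, state.n_channels[closed])
    m = np.where(state.kind_rogue[closed], params.m_rogue, params.m_clustered)
    lum = lumen_ca_mM[state.site_index[closed]]
    p = np.minimum(pc * phi_lumen(lum, m, params, ca_nsr_mM), 1.0)
    draws = rng.random(closed.size)
    for k in closed[draws < p]:
        open_unit(int(k), False)


def max_gating_hazard(state: GatingState, ca_free: np.ndarray,
                      lumen_ca_mM: np.ndarray, params: GatingParams,
                      mesh_size: float, ca_nsr_mM: float | None = None) -> float:
    """Largest per-unit opening hazard (s^-1), used by the dt controller."""
    closed = np.flatnonzero(state.status == CLOSED)
    if closed.size == 0:
        return 0.0
    ny, nx = ca_free.shape
    ix = np.clip((state.pos[closed, 0] / mesh_size).astype(int), 0, nx - 1)
    iy = np.clip((state.pos[closed, 1] / mesh_size).astype(int), 0, ny - 1)
    h = p_ryr(ca_free[iy, ix], params) * state.n_channels[closed]
    m = np.where(state.kind_rogue[closed], params.m_rogue, params.m_clustered)
    h = h * phi_lumen(lumen_ca_mM[state.site_index[closed]], m, params,
                      ca_nsr_mM)
    return float(h.max())
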