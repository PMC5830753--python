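"""Coupled time loop: gating + release + reactions + fractional diffusion
+ luminal dynamics, Monte-Carlo ensembles, and the canonical experiment
presets (single forced quark, release-mode snapshots, quantal-unit
probabilities, luminal-load sweeps, rogue on/off comparisons).

Each step advances, in order: (a) stochastic gating, (b) per-unit molar
release rates (shared by cytosolic deposition and luminal depletion),
(c) coupled implicit local reactions + pump on the cytosolic grid,
(d) implicit direction-split fractional diffusion of free Ca2+ (with the
release sources integrated in the solve) and of mobile dye, (e) the
per-JSR lumen balance.  The time step is adaptive on
a dyadic ladder between dt_min and dt_max, limited by the realized
relative field change, the per-step gating probability, and pending
open/close/forced event times.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .config import (MM_TO_UM, UM_TO_MM, CONVERSION_2D, SLAB_DEPTH_UM,
                     SimulationConfig, validate_config)
from .fractional import DiffusionStepper, build_operator
from .gating import (EventLog, GatingState, max_gating_hazard,
                     source_strength_mol, step_gating)
from .geometry import RyRLayout, generate_layout
from .kinetics import (CytosolState, ReactionSystem,
                       equilibrium_init, pump_flux)
from .lumen import JSRLumenState, lumen_step


class SimulationInstability(RuntimeError):
    def __init__(self, msg, state=None):
        super().__init__(msg)
        self.state = state


@dataclass
class LineScanRecord:
    positions: np.ndarray          # µm along the scan line
    times: list = dc_field(default_factory=list)
    dye: list = dc_field(default_factory=list)      # bound-dye rows
    ca: list = dc_field(default_factory=list)


@dataclass
class SimulationResult:
    """Everything one run produces; (config echo, layout, seed) reproduce it."""

    config: SimulationConfig
    layout: RyRLayout
    seed: int
    event_log: EventLog
    times: np.ndarray                      # per-step time stamps, s
    probe_positions: tuple = ()
    probe_free: np.ndarray | None = None   # (n_steps, n_probes) µM
    probe_dye: np.ndarray | None = None    # bound cytosolic dye at probes
    lumen_sites: tuple = ()
    lumen_free: np.ndarray | None = None   # (n_steps, n_sites_recorded) µM
    lumen_dye: np.ndarray | None = None    # bound Fluo-5N, µM
    linescan: LineScanRecord | None = None
    snapshots: dict = dc_field(default_factory=dict)   # t -> {"ca":..,"dye":..}
    final_state: CytosolState | None = None
    n_steps: int = 0

    @property
    def dye_name(self) -> str:
        return self.config.dye_params[0].name


def _dt_ladder(config: SimulationConfig) -> np.ndarray:
    lv = [config.dt_min_ms * 1e-3]
    while lv[-1] * 2 <= config.dt_max_ms * 1e-3 + 1e-15:
        lv.append(lv[-1] * 2)
    return np.array(lv)


def run_simulation(config: SimulationConfig,
                   layout: RyRLayout | None = None,
                   seed: int | None = None,
                   forced_openings: Sequence[tuple[float, int, int]] = (),
                   probes: Sequence[tuple[float, float]] = (),
                   record_lumen_sites: Sequence[int] = (),
                   record_traces: bool = True) -> SimulationResult:
    """Run one stochastic realization.

    ``forced_openings`` are (time_s, site_index, unit_index) triples opened
    unconditionally at the first step reaching that time (unit indices
    follow each site's unit tuple: CRUs first, then rogues).  ``probes``
    are cytosolic probe positions (µm) whose free-Ca2+ and bound-dye time
    courses are recorded every step, as are the luminal traces of
    ``record_lumen_sites``.
    """
    diags = [d for d in validate_config(config) if d.level == "error"]
    if diags:
        raise ValueError("invalid config: "
                         + "; ".join(f"{d.field_name}: {d.message}" for d in diags))
    if seed is None:
        seed = config.seed
    if layout is None:
        layout = generate_layout(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5eed]))

    h = config.mesh_size
    nx, ny = config.nx, config.ny
    order = config.operator_order
    op_x = build_operator(nx, h, order, config.side_mode, "zero_flux",
                          config.normalization_mode, axis="x")
    op_y = build_operator(ny, h, order, config.side_mode, "zero_flux",
                          config.normalization_mode, axis="y")
    ca_stepper = DiffusionStepper(op_x, op_y, config.Dx, config.Dy)
    dye_stepper = DiffusionStepper(op_x, op_y, config.dye_Dx, config.dye_Dy)

    species = list(config.cytosol_species)
    mobile_idx = [i for i, sp in enumerate(species) if sp.mobile]
    rest = config.resting_ca
    ca = np.full((ny, nx), rest)
    eq = equilibrium_init(rest, species)
    b_stack = np.stack([np.full((ny, nx), float(eq[sp.name]))
                        for sp in species])
    rsys = ReactionSystem(species)
    sp_index = {sp.name: i for i, sp in enumerate(species)}
    def bound(name):
        return b_stack[sp_index[name]]

    gstate = GatingState(layout)
    lstate = JSRLumenState(layout.n_sites, config.lumen,
                           list(config.lumen_species))
    log = EventLog()

    dye_name = config.dye_params[0].name
    lumen_dye_name = "Fluo-5N" if config.lumen.include_dye else None

    # recording setup
    probe_idx = [( min(max(int(p[1] / h), 0), ny - 1),
                   min(max(int(p[0] / h), 0), nx - 1)) for p in probes]
    rec_times, rec_pf, rec_pd, rec_lf, rec_ld = [], [], [], [], []
    linescan = None
    next_scan = 0.0
    if config.record_linescan:
        if config.linescan_axis == "x":
            off = (config.domain_size_y / 2 if config.linescan_offset is None
                   else config.linescan_offset)
            row = min(max(int(off / h), 0), ny - 1)
            linescan = LineScanRecord((np.arange(nx) + 0.5) * h)
            scan_take = lambda f: f[row, :].copy()
        else:
            off = (config.domain_size_x / 2 if config.linescan_offset is None
                   else config.linescan_offset)
            col = min(max(int(off / h), 0), nx - 1)
            linescan = LineScanRecord((np.arange(ny) + 0.5) * h)
            scan_take = lambda f: f[:, col].copy()
    snap_times = sorted(config.snapshot_times)
    snapshots = {}

    forced = sorted(forced_openings)
    ladder = _dt_ladder(config)
    level = 0
    t = 0.0
    n_steps = 0
    release_mol = np.zeros(layout.n_sites)
    deposit = np.zeros_like(ca)

    while t < config.duration - 1e-12:
        dt = ladder[level]
        # event-time clamps: pending forced openings and scheduled closes
        t_next = t + dt
        if forced and forced[0][0] < t_next - 1e-12:
            t_next = max(forced[0][0], t + ladder[0])
        open_mask = gstate.open_mask()
        if open_mask.any():
            nc = gstate.scheduled_close[open_mask].min()
            if t < nc < t_next - 1e-12:
                t_next = nc
        for st in snap_times:
            if t < st < t_next - 1e-12:
                t_next = st
        t_next = min(t_next, config.duration)
        dt = t_next - t

        # (a) gating
        fire_now = []
        while forced and forced[0][0] <= t + 1e-12:
            _, s_i, u_i = forced.pop(0)
            fire_now.append((s_i, u_i))
        opened_before = len(log)
        step_gating(gstate, t, dt, ca, lstate.ca_mM, config.gating, rng, log,
                    h, forced=fire_now)
        if len(log) > opened_before:
            level = 0   # resolve the onset of a new release finely

        # (b) per-unit molar release rates -> deposition + per-site totals
        release_mol[:] = 0.0
        deposit[:] = 0.0
        cell_volume_l = h * h * SLAB_DEPTH_UM * 1.0e-15
        for k in np.flatnonzero(gstate.open_mask()):
            s_idx, _, unit = gstate.units[k]
            ix = min(max(int(unit.position[0] / h), 0), nx - 1)
            iy = min(max(int(unit.position[1] / h), 0), ny - 1)
            mol = CONVERSION_2D * source_strength_mol(
                unit.current_per_mM, float(lstate.ca_mM[s_idx]),
                float(ca[iy, ix]) * UM_TO_MM)
            release_mol[s_idx] += mol
            deposit[iy, ix] += mol / cell_volume_l * 1.0e6

        ca_prev = ca
        lum_prev = lstate.ca_free.copy()

        # (c) local reactions + pump (deposition is integrated inside the
        # implicit diffusion solve below, where it balances transport)
        c_flat, b_flat = rsys.step(ca.reshape(-1),
                                   b_stack.reshape(len(species), -1), dt)
        ca = c_flat.reshape(ny, nx)
        b_stack = b_flat.reshape(len(species), ny, nx)
        J = pump_flux(ca, config.pump)
        ca = np.where(ca > config.pump.resting_ca,
                      np.maximum(config.pump.resting_ca, ca + dt * J), ca)

        # (d) fractional diffusion of free Ca2+ and mobile dye
        # the fractional stencil is not an M-matrix: tolerate (and clip)
        # sub-resting-scale undershoots, abort only on real blow-up
        ca = ca_stepper.step(ca, dt, source=deposit if release_mol.any() else None)
        if ca.min() < -0.02 * max(float(ca.max()), 10.0 * rest):
            raise SimulationInstability(
                f"negative concentration {ca.min():.3g} µM at t={t:.6f}s",
                state=CytosolState(ca, {}))
        np.maximum(ca, 0.0, out=ca)
        for i in mobile_idx:
            b_stack[i] = np.clip(dye_stepper.step(b_stack[i], dt), 0.0, None)

        # (e) luminal balance
        lumen_step(lstate, release_mol, dt)

        if not np.isfinite(ca).all() or not np.isfinite(lstate.ca_free).all():
            raise SimulationInstability(f"non-finite state at t={t:.6f}s",
                                        state=CytosolState(ca, {}))
        t = t_next
        n_steps += 1

        # adaptive dt from realized relative change
        r = np.max(np.abs(ca - ca_prev) / (ca_prev + 0.02))
        if lum_prev.size:
            r = max(r, np.max(np.abs(lstate.ca_free - lum_prev)
                              / (lum_prev + 1.0)))
        hz = max_gating_hazard(gstate, ca, lstate.ca_mM, config.gating, h)
        if r > config.max_rel_change:
            level = max(level - 1, 0)
        elif r < config.max_rel_change / 3:
            level = min(level + 1, len(ladder) - 1)
        while level > 0 and hz * ladder[level] > config.gating.p_step_max:
            level -= 1

        # recording
        if record_traces:
            rec_times.append(t)
            if probe_idx:
                rec_pf.append([ca[i] for i in probe_idx])
                rec_pd.append([bound(dye_name)[i] for i in probe_idx])
            if record_lumen_sites:
                rec_lf.append([lstate.ca_free[s] for s in record_lumen_sites])
                if lumen_dye_name:
                    rec_ld.append([lstate.ca_bound[lumen_dye_name][s]
                                   for s in record_lumen_sites])
        if linescan is not None and t >= next_scan - 1e-12:
            linescan.times.append(t)
            linescan.dye.append(scan_take(bound(dye_name)))
            linescan.ca.append(scan_take(ca))
            next_scan += config.linescan_cadence_ms * 1e-3
        while snap_times and t >= snap_times[0] - 1e-12:
            snapshots[snap_times.pop(0)] = {"ca": ca.copy(),
                                            "dye": bound(dye_name).copy()}

    return SimulationResult(
        config=config, layout=layout, seed=seed, event_log=log,
        times=np.asarray(rec_times),
        probe_positions=tuple(probes),
        probe_free=np.asarray(rec_pf) if rec_pf else None,
        probe_dye=np.asarray(rec_pd) if rec_pd else None,
        lumen_sites=tuple(record_lumen_sites),
        lumen_free=np.asarray(rec_lf) if rec_lf else None,
        lumen_dye=np.asarray(rec_ld) if rec_ld else None,
        linescan=linescan, snapshots=snapshots,
        final_state=CytosolState(
            ca, {sp.name: b_stack[i] for i, sp in enumerate(species)}),
        n_steps=n_steps)


# ---------------------------------------------------------------------------
# Monte-Carlo ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    n: int
    spark_freq: tuple[float, float]        # mean, sd (per 100 µm per s)
    quark_freq: tuple[float, float]
    qcr_triggered: tuple[float, float]     # proportion of sparks (0..1)
    quantal_counts: dict
    spark_freqs: np.ndarray
    quark_freqs: np.ndarray
    proportions: np.ndarray


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds derived from base_seed (< 2^31)."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def run_monte_carlo(config: SimulationConfig, n_replicates: int | None = None,
                    base_seed: int | None = None) -> tuple[list, EnsembleSummary]:
    """Run a replicate ensemble (fresh random layout per replicate) and
    summarize spark/quark frequencies, the QCR-triggered proportion and the
    quantal-unit distribution from the ground-truth event logs."""
    from . import observables as obs

    if n_replicates is None:
        n_replicates = config.n_replicates
    if base_seed is None:
        base_seed = config.seed
    seeds = replicate_seeds(base_seed, n_replicates)
    results, sf, qf, pr = [], [], [], []
    quantal: dict[int, int] = {}
    n_rows = max(1, int(round(config.domain_size_y / config.lattice_spacing_y)))
    scan_length = n_rows * config.domain_size_x
    for sd in seeds:
        res = run_simulation(config, seed=sd, record_traces=False)
        results.append(res)
        events = obs.classify_sparks(res.event_log)
        freq = obs.frequencies(events, scan_length, config.duration)
        sf.append(freq.spark_freq)
        qf.append(freq.quark_freq)
        pr.append(freq.qcr_triggered_proportion)
        for ev in events:
            if ev.kind == "spark":
                quantal[ev.quantal_units] = quantal.get(ev.quantal_units, 0) + 1
    sf, qf = np.asarray(sf), np.asarray(qf)
    pr = np.asarray(pr, dtype=float)
    pr_valid = pr[~np.isnan(pr)]
    summary = EnsembleSummary(
        n=n_replicates,
        spark_freq=(float(sf.mean()), float(sf.std(ddof=1)) if len(sf) > 1 else 0.0),
        quark_freq=(float(qf.mean()), float(qf.std(ddof=1)) if len(qf) > 1 else 0.0),
        qcr_triggered=((float(pr_valid.mean()) if pr_valid.size else float("nan")),
                       (float(pr_valid.std(ddof=1)) if pr_valid.size > 1 else 0.0)),
        quantal_counts=quantal, spark_freqs=sf, quark_freqs=qf, proportions=pr)
    return results, summary


# ---------------------------------------------------------------------------
# Experiment presets
# ---------------------------------------------------------------------------

PRESET_NAMES = ("fig2_quark", "fig3_modes", "fig4_quantal", "fig5_sweep",
                "fig6_rogue_onoff", "fig6c_sensitivity")


def preset(name: str, mesh_size: float | None = None) -> dict:
    """Fully-specified run plans for the canonical experiments.

    Returns a dict with a base ``config`` plus preset-specific entries
    (forced openings, sweep levels, replicate counts).  Unknown names
    raise with the list of valid presets.
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; valid: {PRESET_NAMES}")
    base = SimulationConfig()
    single = base.with_(domain_size_x=5.0, domain_size_y=5.0,
                        mesh_size=mesh_size or 0.025, single_site=True,
                        dt_min_ms=0.0125, dt_max_ms=0.2)
    lattice = base.with_(domain_size_x=20.0, domain_size_y=20.0,
                         mesh_size=mesh_size or 0.1, duration=2.0,
                         dt_min_ms=0.05)
    if name == "fig2_quark":
        cfg = single.with_(duration=0.08, record_linescan=True)
        # rogue unit index: CRUs occupy indices 0..n_cru-1
        return {"config": cfg,
                "forced_openings": [(0.0, 0, cfg.n_cru_per_site)],
                "probe_unit": ("rogue", 0)}
    if name == "fig3_modes":
        cfg = single.with_(duration=0.05,
                           snapshot_times=(0.010, 0.020, 0.040))
        n_cru = cfg.n_cru_per_site
        return {"config": cfg,
                "forced_openings": [(0.0, 0, n_cru + i) for i in range(3)]}
    if name == "fig4_quantal":
        cfg = single.with_(duration=0.1)
        return {"config": cfg, "n_replicates": 20,
                "initial_rogue_openings": list(range(1, 9))}
    if name == "fig5_sweep":
        return {"config": lattice, "n_replicates": 10,
                "lumen_levels_mM": [0.2, 0.4, 0.6, 0.8, 1.0]}
    if name == "fig6_rogue_onoff":
        return {"config": lattice, "n_replicates": 10,
                "lumen_levels_mM": [1.0, 0.6, 0.2],
                "rogue_enabled": [True, False]}
    return {"config": lattice, "n_replicates": 10,
            "rogue_counts": list(range(2, 15, 2)),
            "lumen_levels_mM": [1.0, 0.6, 0.2]}


def config_at_lumen_level(config: SimulationConfig,
                          level_mM: float) -> SimulationConfig:
    """Set a sustained luminal load: initial JSR level and the NSR source
    are both moved to ``level_mM`` (the refill otherwise restores 1.0 mM
    within tens of ms, leaving no sustained low-load condition)."""
    from dataclasses import replace
    return config.with_(lumen=replace(config.lumen, ca_nsr_mM=level_mM,
                                      init_ca_mM=level_mM))


def run_fig2_quark(mesh_size: float | None = None,
                   seed: int = 0) -> SimulationResult:
    """Forced 20 ms single-rogue opening on the 5x5 µm single-site domain,
    recording the cytosolic trace at the release position and the site's
    luminal trace (the QCR-QCD pair protocol)."""
    from dataclasses import replace
    plan = preset("fig2_quark", mesh_size)
    cfg = plan["config"]
    # isolated-event protocol: only the forced rogue opens, so the QCR/QCD
    # pair is a deterministic response (matching the single-quark figure)
    cfg = cfg.with_(gating=replace(cfg.gating, p_max=0.0))
    layout = generate_layout(cfg, seed)
    rogue = layout.sites[0].units[cfg.n_cru_per_site]
    return run_simulation(cfg, layout=layout, seed=seed,
                          forced_openings=plan["forced_openings"],
                          probes=[rogue.position], record_lumen_sites=[0])
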