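"""Model parameters for the Ca2+ spark/quark simulator.

All parameters of the coupled cytosol/JSR model live here: domain and mesh
geometry, the anomalous-diffusion order and coefficients, dye and buffer
kinetics, SERCA pump constants, RyR gating constants and the luminal
(JSR/NSR) parameters.

Internal unit system
--------------------
lengths        µm
time           s   (durations that are naturally milliseconds carry an
                    explicit ``_ms`` suffix in field names)
cytosolic conc µM
luminal conc   stored in µM internally; mM at public interfaces that mirror
               the conventional luminal notation (``*_mM`` suffix)

Conversions between mM and µM happen only through :data:`MM_TO_UM` /
:data:`UM_TO_MM` so the layer is auditable in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import yaml

MM_TO_UM = 1.0e3
UM_TO_MM = 1.0e-3

#: Faraday constant, C mol^-1.
FARADAY = 96_500.0

#: 3D->2D source-strength conversion factor for RyR release.
CONVERSION_2D = 0.64

#: Depth of the 2D slab used to convert molar deposition rates into
#: concentration rates (µm).  See docs/methods.md.
SLAB_DEPTH_UM = 1.0


@dataclass(frozen=True)
class KineticSpecies:
    """One Ca2+-binding species (fluorescent dye or endogenous buffer).

    Kinetics follow simple bimolecular binding
    d[CaX]/dt = k_on*[Ca][X_free] - k_off*[CaX].
    """

    name: str
    total_conc: float          # µM
    k_on: float                # µM^-1 s^-1
    k_off: float               # s^-1
    compartment: Literal["cytosol", "lumen"] = "cytosol"
    mobile: bool = False       # dyes are mobile, endogenous buffers are not

    @property
    def kd(self) -> float:
        """Dissociation constant k_off/k_on (µM)."""
        if self.k_on == 0:
            return float("inf")
        return self.k_off / self.k_on


# Standard dye/buffer kinetics (total conc µM, k_on µM^-1 s^-1, k_off s^-1).
RHOD2 = KineticSpecies("Rhod-2", 5.0, 130.0, 69.0, "cytosol", mobile=True)
FLUO4 = KineticSpecies("Fluo-4-AM", 50.0, 80.0, 90.0, "cytosol", mobile=True)
CALMODULIN = KineticSpecies("calmodulin", 24.0, 100.0, 38.0, "cytosol")
TROPONIN = KineticSpecies("troponin", 70.0, 39.0, 20.0, "cytosol")
SR_BUFFER = KineticSpecies("SR", 47.0, 115.0, 100.0, "cytosol")
SL_BUFFER = KineticSpecies("SL", 1124.0, 115.0, 1000.0, "cytosol")
FLUO5N = KineticSpecies("Fluo-5N", 20.0, 48.8, 19_520.0, "lumen", mobile=True)
CALSEQUESTRIN = KineticSpecies("calsequestrin", 14_000.0, 100.0, 60_000.0, "lumen")

SPECIES_TABLE = {
    s.name: s
    for s in (RHOD2, FLUO4, CALMODULIN, TROPONIN, SR_BUFFER, SL_BUFFER,
              FLUO5N, CALSEQUESTRIN)
}


@dataclass(frozen=True)
class PumpParams:
    """SERCA (SR Ca2+-ATPase) Hill-type pump.

    The rate constants are not printed in the source model description
    (cited to its own references); the defaults below are the standard
    values of that modelling lineage and are flagged as such in the docs.
    The pump is thresholded: it is off at or below the resting cytosolic
    Ca2+ level.
    """

    v_max: float = 208.0       # µM s^-1
    k_pump: float = 0.184      # µM
    hill: float = 3.9
    resting_ca: float = 0.1    # µM, activation threshold


@dataclass(frozen=True)
class GatingParams:
    """Stochastic RyR gating constants.

    The single-channel opening hazard is a Hill function of local cytosolic
    Ca2+, ``p_ryr(c) = p_max * c^gamma / (c^gamma + k_p^gamma)`` (s^-1).
    ``p_max`` and the luminal-regulation exponent ``phi_exponent`` are
    calibrated against the published spontaneous spark frequencies (see
    scripts/calibrate.py); the calibrated values are frozen here.
    """

    p_max: float = 150.0       # s^-1, calibrated
    gamma: float = 12.0        # steepness of local CICR activation
    k_p: float = 0.25          # µM
    phi_exponent: float = 0.092  # nu in phi(c) = (c/phi_ref)^nu, calibrated
    phi_ref_mM: float = 1.0    # physiological NSR load phi normalizes to
    m_rogue: float = 1.0
    m_clustered: float = 10.0
    refractory_ms: float = 300.0   # spark-restitution scale
    release_time_rogue_ms: float = 20.0
    release_time_clustered_ms: float = 10.0
    current_rogue: float = 0.07      # pA mM^-1
    current_clustered: float = 0.7   # pA mM^-1
    n_channels_rogue: int = 3
    n_channels_clustered: int = 22
    p_step_max: float = 0.2    # per-step probability ceiling driving dt


@dataclass(frozen=True)
class LumenParams:
    """Junctional-SR luminal compartment parameters."""

    ca_nsr_mM: float = 1.0         # network-SR free Ca2+, mM
    tau_refill_ms: float = 10.0    # JSR<->NSR transfer time constant
    volume_ul: float = 1.0e-11     # JSR lumen volume, µl
    init_ca_mM: float = 1.0        # initial JSR free Ca2+, mM
    include_dye: bool = True       # Fluo-5N on by default

    @property
    def volume_l(self) -> float:
        return self.volume_ul * 1.0e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one simulation.

    Defaults reproduce the published model: 5x5 µm single-site domain,
    0.025 µm mesh, anomalous order beta = 2.25, Dx = 300 / Dy = 150,
    Rhod-2 cytosolic readout, Fluo-5N + calsequestrin in the lumen.
    """

    domain_size_x: float = 5.0     # µm
    domain_size_y: float = 5.0     # µm
    mesh_size: float = 0.025       # µm
    beta: float = 2.25             # anomalous subdiffusion order
    Dx: float = 300.0              # µm^beta s^-1 (printed as µm^2 s^-1)
    Dy: float = 150.0
    dye_Dx: float = 30.0           # mobile-dye transport coefficients
    dye_Dy: float = 15.0
    resting_ca: float = 0.1       # µM
    dye_params: tuple[KineticSpecies, ...] = (RHOD2,)
    buffer_params: tuple[KineticSpecies, ...] = (
        CALMODULIN, TROPONIN, SR_BUFFER, SL_BUFFER)
    pump: PumpParams = field(default_factory=PumpParams)
    gating: GatingParams = field(default_factory=GatingParams)
    lumen: LumenParams = field(default_factory=LumenParams)
    duration: float = 0.1          # s
    seed: int = 0
    n_replicates: int = 1
    rogue_enabled: bool = True
    # geometry
    lattice_spacing_x: float = 2.0   # µm
    lattice_spacing_y: float = 0.8   # µm
    jsr_footprint: float = 0.6       # µm, side of the square JSR footprint
    subgrid: float = 0.1             # µm, RyR placement sub-grid
    n_cru_per_site: int = 2
    n_rogue_per_site: int = 8
    poisson_counts: bool = False     # draw site counts ~ Poisson(2)/Poisson(8)
    single_site: bool = False        # one JSR at the domain centre
    # numerics
    discretization_order: Literal["beta", "beta_minus_one"] = "beta"
    side_mode: Literal["left", "right", "riesz_symmetric"] = "riesz_symmetric"
    normalization_mode: Literal["normalized", "paper_literal"] = "normalized"
    dt_max_ms: float = 0.4           # adaptive-dt ceiling
    dt_min_ms: float = 0.025
    max_rel_change: float = 0.05     # reaction-accuracy dt limiter
    # recording
    snapshot_times: tuple[float, ...] = ()
    linescan_cadence_ms: float = 2.0
    snapshot_cadence_ms: float = 1.0
    record_linescan: bool = False
    linescan_axis: Literal["x", "y"] = "x"
    linescan_offset: float | None = None   # µm; None -> through domain centre

    @property
    def nx(self) -> int:
        return int(round(self.domain_size_x / self.mesh_size))

    @property
    def ny(self) -> int:
        return int(round(self.domain_size_y / self.mesh_size))

    @property
    def operator_order(self) -> float:
        """Order actually handed to the Grünwald discretization."""
        if self.discretization_order == "beta_minus_one":
            return self.beta - 1.0
        return self.beta

    @property
    def cytosol_species(self) -> tuple[KineticSpecies, ...]:
        return tuple(self.dye_params) + tuple(self.buffer_params)

    @property
    def lumen_species(self) -> tuple[KineticSpecies, ...]:
        sp = []
        if self.lumen.include_dye:
            sp.append(FLUO5N)
        sp.append(CALSEQUESTRIN)
        return tuple(sp)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Functional update (dataclasses.replace wrapper)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Diagnostic:
    level: Literal["error", "warning"]
    field_name: str
    message: str


def validate_config(config: SimulationConfig) -> list[Diagnostic]:
    """Check a configuration against the model's invariants.

    Returns a list of diagnostics (empty for the default parameterization);
    nothing is raised so callers can report all problems at once.
    """
    diags: list[Diagnostic] = []

    def err(name, msg):
        diags.append(Diagnostic("error", name, msg))

    def warn(name, msg):
        diags.append(Diagnostic("warning", name, msg))

    if config.mesh_size <= 0:
        err("mesh_size", "mesh_size must be > 0")
    if config.domain_size_x <= 0 or config.domain_size_y <= 0:
        err("domain_size", "domain sizes must be > 0")
    if config.Dx <= 0:
        err("Dx", "diffusion coefficient Dx must be > 0")
    if config.Dy <= 0:
        err("Dy", "diffusion coefficient Dy must be > 0")
    if config.duration <= 0:
        err("duration", "duration must be > 0")
    if config.beta == 2.0:
        warn("beta", "beta = 2 is the classical-diffusion limit "
                     "(allowed for testing)")
    elif not (2.0 < config.beta < 3.0):
        err("beta", "anomalous order beta must lie in (2, 3)")
    elif config.operator_order > 2.25 and config.discretization_order == "beta":
        warn("beta", "shifted-Grünwald operator validated for order <= 2.25")
    for sp in list(config.cytosol_species) + list(config.lumen_species):
        if sp.total_conc < 0:
            err(f"species[{sp.name}].total_conc", "total_conc must be >= 0")
        if sp.k_on < 0 or sp.k_off < 0:
            err(f"species[{sp.name}]", "kinetic rates must be >= 0")
    if config.pump.v_max < 0:
        err("pump.v_max", "v_max must be >= 0")
    if config.pump.k_pump <= 0:
        err("pump.k_pump", "k_pump must be > 0")
    if config.pump.hill <= 0:
        err("pump.hill", "hill exponent must be > 0")
    if config.lumen.tau_refill_ms <= 0:
        err("lumen.tau_refill_ms", "tau_refill must be > 0")
    if config.lumen.volume_ul <= 0:
        err("lumen.volume_ul", "JSR volume must be > 0")
    if not config.single_site and (
            config.domain_size_x < config.lattice_spacing_x
            or config.domain_size_y < config.lattice_spacing_y):
        err("domain_size", "domain smaller than one JSR lattice cell")
    return diags


# ---------------------------------------------------------------------------
# Flat config-file round trip.  An empty file reproduces the default model.
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = [
    "domain_size_x", "domain_size_y", "mesh_size", "beta", "Dx", "Dy",
    "dye_Dx", "dye_Dy", "resting_ca", "duration", "seed", "n_replicates",
    "rogue_enabled", "lattice_spacing_x", "lattice_spacing_y",
    "jsr_footprint", "subgrid", "n_cru_per_site", "n_rogue_per_site",
    "poisson_counts", "single_site", "discretization_order", "side_mode",
    "normalization_mode", "dt_max_ms", "dt_min_ms", "max_rel_change",
    "record_linescan", "linescan_axis", "linescan_cadence_ms",
    "snapshot_cadence_ms",
]
_PUMP_FIELDS = ["v_max", "k_pump", "hill", "resting_ca"]
_GATING_FIELDS = [
    "p_max", "gamma", "k_p", "phi_exponent", "m_rogue", "m_clustered",
    "refractory_ms", "release_time_rogue_ms", "release_time_clustered_ms",
    "current_rogue", "current_clustered", "n_channels_rogue",
    "n_channels_clustered", "p_step_max",
]
_LUMEN_FIELDS = ["ca_nsr_mM", "tau_refill_ms", "volume_ul", "init_ca_mM",
                 "include_dye"]


def load_config(path) -> SimulationConfig:
    """Load a flat YAML/JSON-style config file; missing keys take defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_from_dict(data: dict) -> SimulationConfig:
    cfg = SimulationConfig()
    top = {k: data[k] for k in _SCALAR_FIELDS if k in data}
    pump = {k: data[f"pump_{k}"] for k in _PUMP_FIELDS if f"pump_{k}" in data}
    gating = {k: data[f"gating_{k}"] for k in _GATING_FIELDS
              if f"gating_{k}" in data}
    lumen = {k: data[f"lumen_{k}"] for k in _LUMEN_FIELDS
             if f"lumen_{k}" in data}
    if "cytosolic_dye" in data:
        top["dye_params"] = (SPECIES_TABLE[data["cytosolic_dye"]],)
    if pump:
        top["pump"] = replace(cfg.pump, **pump)
    if gating:
        top["gating"] = replace(cfg.gating, **gating)
    if lumen:
        top["lumen"] = replace(cfg.lumen, **lumen)
    unknown = set(data) - set(_SCALAR_FIELDS) - {"cytosolic_dye"} \
        - {f"pump_{k}" for k in _PUMP_FIELDS} \
        - {f"gating_{k}" for k in _GATING_FIELDS} \
        - {f"lumen_{k}" for k in _LUMEN_FIELDS}
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return cfg.with_(**top)


def config_to_dict(config: SimulationConfig) -> dict:
    out = {k: getattr(config, k) for k in _SCALAR_FIELDS}
    out["cytosolic_dye"] = config.dye_params[0].name
    out.update({f"pump_{k}": getattr(config.pump, k) for k in _PUMP_FIELDS})
    out.update({f"gating_{k}": getattr(config.gating, k)
                for k in _GATING_FIELDS})
    out.update({f"lumen_{k}": getattr(config.lumen, k)
                for k in _LUMEN_FIELDS})
    return out


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
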