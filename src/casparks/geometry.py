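"""JSR lattice geometry and randomized RyR placement.

Ca2+ release sites (JSRs) sit on a rectangular lattice with spacing
l_x = 2 µm (longitudinal) by l_y = 0.8 µm (transverse).  Each JSR holds
~2 Ca2+ release units (CRUs, 22 coupled RyR channels each) surrounded by
~8 rogue RyR units (3 channels each), placed at random on a 0.1 µm
sub-grid inside a 0.6 µm square footprint centred on the lattice point.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig


class PlacementError(RuntimeError):
    """Footprint cannot accommodate the requested number of units."""


class ConfigurationError(ValueError):
    """Domain geometry cannot hold the lattice."""


@dataclass(frozen=True)
class ReleaseUnit:
    """One stochastic release unit: a clustered-RyR CRU or a rogue RyR."""

    kind: str                  # "clustered" | "rogue"
    position: tuple[float, float]   # (x, y) µm, absolute
    n_channels: int
    release_time_ms: float
    current_per_mM: float      # pA mM^-1

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.release_time_ms <= 0:
            raise ValueError("release_time must be > 0")
        if self.current_per_mM <= 0:
            raise ValueError("current_per_mM must be > 0")


@dataclass(frozen=True)
class JSRSite:
    site_id: int
    center: tuple[float, float]
    crus: tuple[ReleaseUnit, ...]
    rogues: tuple[ReleaseUnit, ...]

    @property
    def units(self) -> tuple[ReleaseUnit, ...]:
        return self.crus + self.rogues

    @property
    def total_channels(self) -> int:
        return sum(u.n_channels for u in self.units)


@dataclass(frozen=True)
class RyRLayout:
    sites: tuple[JSRSite, ...]
    lattice_spacing: tuple[float, float]
    rng_seed: int
    domain_size: tuple[float, float] = (0.0, 0.0)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def all_units(self):
        for site in self.sites:
            for unit in site.units:
                yield site, unit


def _place_units(center, config: SimulationConfig, n_cru, n_rogue,
                 rng: np.random.Generator):
    """Sample distinct sub-grid slots inside the footprint for all units."""
    half = config.jsr_footprint / 2.0
    offsets = np.arange(-half, half + 1e-9, config.subgrid)
    slots = [(float(center[0] + ox), float(center[1] + oy))
             for ox in offsets for oy in offsets]
    n_units = n_cru + n_rogue
    if n_units > len(slots):
        raise PlacementError(
            f"footprint holds {len(slots)} sub-grid slots, "
            f"{n_units} units requested")
    idx = rng.choice(len(slots), size=n_units, replace=False)
    g = config.gating
    crus = tuple(
        ReleaseUnit("clustered", slots[i], g.n_channels_clustered,
                    g.release_time_clustered_ms, g.current_clustered)
        for i in idx[:n_cru])
    rogues = tuple(
        ReleaseUnit("rogue", slots[i], g.n_channels_rogue,
                    g.release_time_rogue_ms, g.current_rogue)
        for i in idx[n_cru:])
    return crus, rogues


def generate_layout(config: SimulationConfig, seed: int) -> RyRLayout:
    """Generate the JSR lattice with randomized CRU/rogue placement.

    Deterministic for a fixed ``seed``.  In the default mode every site
    holds exactly ``n_cru_per_site`` CRUs and ``n_rogue_per_site`` rogue
    units; with ``poisson_counts`` the per-site counts are Poisson with
    those means (at least 1 CRU).  ``single_site`` puts one JSR at the
    domain centre (the 5x5 µm single-release-site configuration).
    """
    rng = np.random.default_rng(seed)
    lx, ly = config.lattice_spacing_x, config.lattice_spacing_y
    Lx, Ly = config.domain_size_x, config.domain_size_y

    if config.single_site:
        centers = [(Lx / 2.0, Ly / 2.0)]
    else:
        n_col = int(Lx / lx + 1e-9)
        n_row = int(Ly / ly + 1e-9)
        if n_col < 1 or n_row < 1:
            raise ConfigurationError(
                f"domain {Lx}x{Ly} µm smaller than one lattice cell "
                f"({lx}x{ly} µm)")
        centers = [((i + 0.5) * lx, (j + 0.5) * ly)
                   for j in range(n_row) for i in range(n_col)]

    margin = config.jsr_footprint / 2.0
    sites = []
    for sid, c in enumerate(centers):
        if not (margin <= c[0] <= Lx - margin and margin <= c[1] <= Ly - margin):
            raise ConfigurationError(
                f"site {sid} footprint at {c} extends outside the domain")
        if config.poisson_counts:
            n_cru = max(1, int(rng.poisson(config.n_cru_per_site)))
            n_rogue = int(rng.poisson(config.n_rogue_per_site))
        else:
            n_cru, n_rogue = config.n_cru_per_site, config.n_rogue_per_site
        if not config.rogue_enabled:
            n_rogue = 0
        crus, rogues = _place_units(c, config, n_cru, n_rogue, rng)
        sites.append(JSRSite(sid, c, crus, rogues))
    return RyRLayout(tuple(sites), (lx, ly), seed, (Lx, Ly))


def layout_to_csv(layout: RyRLayout, path) -> None:
    """Export a layout as tabular text (site_id, kind, x_um, y_um, n_channels)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "kind", "x_um", "y_um", "n_channels"])
        for site, unit in layout.all_units():
            w.writerow([site.site_id, unit.kind, f"{unit.position[0]:.6g}",
                        f"{unit.position[1]:.6g}", unit.n_channels])


def layout_from_csv(path, config: SimulationConfig) -> RyRLayout:
    """Read a layout previously written by :func:`layout_to_csv`."""
    g = config.gating
    per_site: dict[int, dict[str, list[ReleaseUnit]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = int(row["site_id"])
            kind = row["kind"]
            pos = (float(row["x_um"]), float(row["y_um"]))
            if kind == "clustered":
                unit = ReleaseUnit(kind, pos, int(row["n_channels"]),
                                   g.release_time_clustered_ms,
                                   g.current_clustered)
            else:
                unit = ReleaseUnit(kind, pos, int(row["n_channels"]),
                                   g.release_time_rogue_ms, g.current_rogue)
            per_site.setdefault(sid, {"clustered": [], "rogue": []})
            per_site[sid][kind].append(unit)
    sites = []
    for sid in sorted(per_site):
        units = per_site[sid]["clustered"] + per_site[sid]["rogue"]
        cx = float(np.mean([u.position[0] for u in units]))
        cy = float(np.mean([u.position[1] for u in units]))
        sites.append(JSRSite(sid, (cx, cy),
                             tuple(per_site[sid]["clustered"]),
                             tuple(per_site[sid]["rogue"])))
    return RyRLayout(tuple(sites),
                     (config.lattice_spacing_x, config.lattice_spacing_y),
                     rng_seed=-1,
                     domain_size=(config.domain_size_x, config.domain_size_y))
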