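"""Measured quantities: fluorescence, line scans, ΔF/F0, t67, FWHM,
spark/quark classification and event frequencies.

Fluorescence is the Ca-bound dye concentration (Rhod-2 or Fluo-4 in the
cytosol, Fluo-5N in the JSR lumen).  Event analytics come in two flavours:
ground-truth classification straight from the simulator's event log (the
default for all frequency statistics — the simulation knows truth), and an
image-based threshold detector on line-scan images used as a cross-check.

t67 definition
--------------
The event time-scale metric t67 is computed as the width of the time
interval during which |ΔF| stays at or above 67% of its peak (a
duration-at-67%-of-maximum, the temporal analogue of FWHM).  The
definition is isolated in :func:`t67_duration` so an alternative can be
swapped without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import EventLog
from .kinetics import CytosolState
from .lumen import JSRLumenState


@dataclass(frozen=True)
class LineScan:
    positions: np.ndarray      # µm
    times: np.ndarray          # s
    fluorescence: np.ndarray   # (n_times, n_positions)
    f0: np.ndarray             # baseline per position

    def dff(self) -> np.ndarray:
        return (self.fluorescence - self.f0) / self.f0


@dataclass(frozen=True)
class EventMetrics:
    amplitude: float           # peak |ΔF|/F0
    t67_ms: float
    onset_s: float
    peak_time_s: float
    fwhm_um: float = float("nan")
    kind: str = ""
    quantal_units: int = 0

    @property
    def found(self) -> bool:
        return np.isfinite(self.amplitude)


NO_EVENT = EventMetrics(float("nan"), float("nan"), float("nan"), float("nan"))


def fluorescence(state, dye_name: str, blur_sigma_um: float = 0.0,
                 mesh_size: float | None = None) -> np.ndarray:
    """F = [Ca-bound dye] for a cytosolic grid state or a lumen state."""
    if isinstance(state, (CytosolState, JSRLumenState)):
        bound = state.ca_bound
    else:
        bound = state
    if dye_name not in bound:
        raise KeyError(f"dye {dye_name!r} not present in state")
    F = np.asarray(bound[dye_name], dtype=float)
    if blur_sigma_um > 0:
        from scipy.ndimage import gaussian_filter
        if mesh_size is None:
            raise ValueError("mesh_size required for blurring")
        F = gaussian_filter(F, blur_sigma_um / mesh_size)
    return F


def extract_linescan(result, axis: str = "x",
                     offset: float | None = None) -> LineScan:
    """Build a LineScan from a simulation's recorded scan rows.

    The simulation must have been run with ``record_linescan``; the F0
    baseline is the first recorded frame (the resting field — events are
    not instantaneous, so frame 0 precedes any fluorescence response).
    """
    rec = result.linescan
    if rec is None or not rec.times:
        raise ValueError("simulation carries no line-scan record "
                         "(set record_linescan)")
    F = np.asarray(rec.dye)
    f0 = F[0].copy()
    if (f0 <= 0).any():
        raise ValueError("non-positive baseline F0")
    return LineScan(np.asarray(rec.positions), np.asarray(rec.times), F, f0)


def _interp_crossing(t, y, i, level):
    """Linear-interpolated time where y crosses level between i-1 and i."""
    if i == 0 or y[i] == y[i - 1]:
        return t[i]
    w = (level - y[i - 1]) / (y[i] - y[i - 1])
    return t[i - 1] + w * (t[i] - t[i - 1])


def t67_duration(times: np.ndarray, dff_abs: np.ndarray,
                 peak_idx: int) -> float:
    """Width (ms) of the interval with |ΔF|/F0 >= 67% of its peak."""
    level = 0.67 * dff_abs[peak_idx]
    above = dff_abs >= level
    i = peak_idx
    while i > 0 and above[i - 1]:
        i -= 1
    t_up = _interp_crossing(times, dff_abs, i, level) if i > 0 else times[0]
    j = peak_idx
    while j < len(dff_abs) - 1 and above[j + 1]:
        j += 1
    if j < len(dff_abs) - 1:
        t_down = _interp_crossing(times, dff_abs, j + 1, level)
    else:
        t_down = times[-1]
    return (t_down - t_up) * 1e3


def event_metrics(times: np.ndarray, trace: np.ndarray, f0: float,
                  onset_threshold: float = 1e-4) -> EventMetrics:
    """Amplitude and t67 of a single-event fluorescence time course.

    ``trace`` is F(t) at one position; works for upward (cytosolic QCR/
    spark) and downward (luminal QCD depletion) events via |ΔF|.  Returns
    :data:`NO_EVENT` when nothing rises above the onset threshold.
    """
    times = np.asarray(times, float)
    dff = (np.asarray(trace, float) - f0) / f0
    a = np.abs(dff)
    if a.max() <= onset_threshold:
        return NO_EVENT
    peak = int(np.argmax(a))
    onset_idx = int(np.argmax(a > onset_threshold))
    return EventMetrics(amplitude=float(a[peak]),
                        t67_ms=float(t67_duration(times, a, peak)),
                        onset_s=float(times[onset_idx]),
                        peak_time_s=float(times[peak]))


def spatial_fwhm(positions: np.ndarray, dff_profile: np.ndarray) -> float:
    """Full width at half maximum (µm) of a spatial ΔF/F0 profile."""
    a = np.abs(np.asarray(dff_profile, float))
    peak = int(np.argmax(a))
    half = a[peak] / 2.0
    left = right = None
    for i in range(peak, 0, -1):
        if a[i - 1] < half <= a[i]:
            left = _interp_crossing(positions, a, i, half)
            break
    for i in range(peak, len(a) - 1):
        if a[i + 1] < half <= a[i]:
            right = _interp_crossing(positions, a, i + 1, half)
            break
    if left is None or right is None:
        return float("nan")
    return float(right - left)


# ---------------------------------------------------------------------------
# Ground-truth event classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifiedEvent:
    kind: str                  # "spark" | "quark"
    site_id: int
    t_start: float
    t_end: float
    quantal_units: int         # distinct CRUs (sparks), 0 for quarks
    triggered_by_qcr: bool


def classify_sparks(log: EventLog, window_ms: float = 20.0) -> list[ClassifiedEvent]:
    """Merge the event log into spark and quark episodes.

    CRU openings at one site whose release intervals overlap (gap up to
    ``window_ms``) merge into one spark; quantal units = number of
    distinct CRUs involved.  A spark is QCR-triggered when at least one
    rogue opening at the same site precedes its first CRU opening within
    the window.  Rogue openings that are not absorbed into a spark's
    trigger/accompaniment merge (same site, same overlap rule) into quark
    episodes.
    """
    window = window_ms * 1e-3
    events: list[ClassifiedEvent] = []
    by_site: dict[int, list] = {}
    for r in log:
        by_site.setdefault(r.site_id, []).append(r)
    for site_id, recs in by_site.items():
        recs.sort(key=lambda r: r.t_open)
        crus = [r for r in recs if r.kind == "clustered"]
        rogues = [r for r in recs if r.kind == "rogue"]
        # merge CRU openings into spark episodes
        episodes: list[list] = []
        for r in crus:
            if episodes and r.t_open <= episodes[-1][-1].t_open \
                    + episodes[-1][-1].duration_ms * 1e-3 + window:
                episodes[-1].append(r)
            else:
                episodes.append([r])
        used_rogues = set()
        for ep in episodes:
            t0 = ep[0].t_open
            t1 = max(r.t_open + r.duration_ms * 1e-3 for r in ep)
            trig = False
            for rg in rogues:
                if t0 - window <= rg.t_open < t0:
                    trig = True
                if t0 - window <= rg.t_open <= t1:
                    used_rogues.add(id(rg))
            events.append(ClassifiedEvent(
                "spark", site_id, t0, t1,
                quantal_units=len({r.unit_index for r in ep}),
                triggered_by_qcr=trig))
        free_rogues = [rg for rg in rogues if id(rg) not in used_rogues]
        q_episodes: list[list] = []
        for r in free_rogues:
            if q_episodes and r.t_open <= q_episodes[-1][-1].t_open \
                    + q_episodes[-1][-1].duration_ms * 1e-3 + window:
                q_episodes[-1].append(r)
            else:
                q_episodes.append([r])
        for ep in q_episodes:
            events.append(ClassifiedEvent(
                "quark", site_id, ep[0].t_open,
                max(r.t_open + r.duration_ms * 1e-3 for r in ep),
                quantal_units=0, triggered_by_qcr=False))
    events.sort(key=lambda e: e.t_start)
    return events


@dataclass(frozen=True)
class FrequencySummary:
    spark_freq: float              # per 100 µm per s
    quark_freq: float
    qcr_triggered_proportion: float    # NaN when no sparks
    n_sparks: int
    n_quarks: int


def frequencies(events: list[ClassifiedEvent], scan_length_um: float,
                duration_s: float) -> FrequencySummary:
    """Event frequencies per 100 µm of (pooled) scan line per second."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    sparks = [e for e in events if e.kind == "spark"]
    quarks = [e for e in events if e.kind == "quark"]
    norm = (scan_length_um / 100.0) * duration_s
    prop = (sum(e.triggered_by_qcr for e in sparks) / len(sparks)
            if sparks else float("nan"))
    return FrequencySummary(len(sparks) / norm, len(quarks) / norm, prop,
                            len(sparks), len(quarks))


# ---------------------------------------------------------------------------
# Image-based detection (cross-check against ground truth)
# ---------------------------------------------------------------------------

def detect_events_image(scan: LineScan, dff_threshold: float = 0.2,
                        min_separation_ms: float = 20.0) -> list[dict]:
    """Threshold detector on a line-scan image.

    Connected (time, position) regions with ΔF/F0 >= threshold become
    events with their peak time/position.  The 0.2 default mirrors the
    noise floor below which experimental quark events are not measured.
    """
    from scipy import ndimage
    dff = scan.dff()
    mask = dff >= dff_threshold
    labels, n = ndimage.label(mask)
    out = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        vals = dff[labels == lab]
        k = int(np.argmax(vals))
        ti, xi = idx[k]
        out.append({"t_peak": float(scan.times[ti]),
                    "x_peak": float(scan.positions[xi]),
                    "amplitude": float(vals[k])})
    out.sort(key=lambda d: d["t_peak"])
    # merge detections closer than min_separation at similar position
    merged = []
    for d in out:
        if merged and (d["t_peak"] - merged[-1]["t_peak"]) * 1e3 \
                < min_separation_ms and abs(d["x_peak"] - merged[-1]["x_peak"]) < 1.0:
            if d["amplitude"] > merged[-1]["amplitude"]:
                merged[-1] = d
        else:
            merged.append(d)
    return merged


# ---------------------------------------------------------------------------
# Tabular / image export
# ---------------------------------------------------------------------------

def metrics_to_csv(metrics: list[EventMetrics], path) -> None:
    pd.DataFrame([m.__dict__ for m in metrics]).to_csv(path, index=False)


def linescan_to_csv(scan: LineScan, path) -> None:
    df = pd.DataFrame(scan.fluorescence, index=scan.times,
                      columns=scan.positions)
    df.index.name = "time_s"
    df.to_csv(path)


def linescan_to_tiff(scan: LineScan, path, normalized: bool = True) -> None:
    import tifffile
    img = scan.dff() if normalized else scan.fluorescence
    tifffile.imwrite(path, img.astype(np.float32))
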