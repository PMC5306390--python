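"""Quantification of the activity bump from spike rasters.

Spike rasters are convolved with a Gaussian kernel (sd 24 ms) to produce a
pseudo-Ca²⁺ signal.  The bump position is the circular centroid, modulo
eight, of the convolved P-EN signal in each hemisphere; the two hemisphere
centroids are combined by a circular mean weighted by each hemisphere's
total signal.  Each P-EN sits at the azimuth of its home wedge, so the left
and right populations interleave at 22.5° spacing — this is what gives the
position histogram its 22.5° mode structure.

Bump width is the full width at half maximum of the azimuthal profile pooled
across hemispheres by PB glomerulus index (8 bins of 45°), expressed as a
percentage of the full axis: a one-glomerulus bump reads 12.5%, two
glomeruli 25%, three 37.5%.

Frames whose total P-EN signal falls below a floor (1% of the run median by
default) are flagged invalid; the bump can vanish from the spike raster for
tens of milliseconds while persisting in subthreshold voltages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmax

from . import connectome as _conn

__all__ = [
    "ConvolvedRaster",
    "BumpTrace",
    "convolve_raster",
    "bump_centroid",
    "bump_width",
    "width_trace",
    "drift_rate",
    "position_modes",
    "speed_distribution",
    "selectivity_index",
    "GLOM_PER_TURN",
]

#: glomerulus (azimuthal-position) units per full circle
GLOM_PER_TURN = 8

_TWO_PI = 2 * np.pi


def _wrap(a):
    return -((-np.asarray(a) + np.pi) % _TWO_PI - np.pi)


@dataclass
class ConvolvedRaster:
    """Gaussian-convolved raster on a coarse time grid.

    ``signal[i, k]`` is neuron i's pseudo-Ca²⁺ signal at time ``t[k]``; each
    spike contributes one unit-area Gaussian (sd 24 ms), so the signal has
    units of 1/s and integrates to the spike count.
    """

    signal: np.ndarray
    t: np.ndarray
    grid: float
    sd: float


@dataclass
class BumpTrace:
    """Centroid azimuth over time, with a per-frame validity flag."""

    t: np.ndarray
    centroid: np.ndarray  # radians in (−π, π]; NaN where invalid
    valid: np.ndarray
    total_signal: np.ndarray = None

    def glomeruli(self) -> np.ndarray:
        """Centroid in glomerulus units (8 per full circle)."""
        return self.centroid * GLOM_PER_TURN / _TWO_PI


def convolve_raster(
    result_or_raster,
    n_neurons: int | None = None,
    duration: float | None = None,
    sd: float = 0.024,
    grid: float = 0.001,
) -> ConvolvedRaster:
    """Convolve spike times with a unit-area Gaussian kernel.

    Accepts a :class:`~pbring.lif_engine.SimulationResult` or a list of
    per-neuron spike-time arrays.  The kernel is truncated at ±4 sd and
    renormalized so one spike integrates to exactly 1.
    """
    if hasattr(result_or_raster, "spike_neurons"):
        res = result_or_raster
        n = res.n_neurons if n_neurons is None else n_neurons
        duration = res.duration if duration is None else duration
        raster = [res.spikes_of(i) for i in range(n)]
    else:
        raster = [np.asarray(r, dtype=float) for r in result_or_raster]
        n = len(raster) if n_neurons is None else n_neurons
        if duration is None:
            duration = max((r.max() for r in raster if r.size), default=0.0) + 4 * sd
    T = max(1, int(round(duration / grid)))
    t = (np.arange(T) + 0.5) * grid
    half = int(np.ceil(4 * sd / grid))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * grid) / sd) ** 2)
    k /= k.sum() * grid  # unit area on the grid
    signal = np.zeros((n, T))
    for i, times in enumerate(raster):
        if len(times) == 0:
            continue
        counts = np.bincount(
            np.clip((np.asarray(times) / grid).astype(int), 0, T - 1), minlength=T
        ).astype(float)
        signal[i] = np.convolve(counts, k, mode="same")
    return ConvolvedRaster(signal=signal, t=t, grid=grid, sd=sd)


def _pen_geometry(neurons):
    """Per-hemisphere P-EN row indices, azimuths, and glomerulus bins."""
    out = {}
    for hemi in ("L", "R"):
        rows, az, gbin = [], [], []
        for nrn in neurons:
            if nrn.neuron_class != "P-EN" or nrn.hemisphere != hemi:
                continue
            (g,) = [c.index for c in nrn.dendrite_compartments if c.neuropil == "PB"]
            rows.append(nrn.id)
            az.append(_conn.wedge_azimuth(_conn.wedge_of_glomerulus(hemi, g)))
            gbin.append(g % GLOM_PER_TURN)
        out[hemi] = (np.array(rows), np.array(az), np.array(gbin))
    return out


def bump_centroid(
    cr: ConvolvedRaster,
    neurons,
    floor_frac: float = 0.01,
) -> BumpTrace:
    """Circular centroid of the P-EN signal, combined across hemispheres.

    Frames with total P-EN signal below ``floor_frac`` × the run median (or
    with a vanishing resultant vector) are marked invalid.
    """
    geo = _pen_geometry(neurons)
    vec = np.zeros(cr.t.shape, dtype=complex)
    total = np.zeros(cr.t.shape)
    for hemi in ("L", "R"):
        rows, az, _ = geo[hemi]
        sig = cr.signal[rows]
        w = sig.sum(axis=0)
        resultant = (sig * np.exp(1j * az)[:, None]).sum(axis=0)
        mag = np.abs(resultant)
        # a hemisphere with a (near-)zero resultant has no defined centroid
        # and contributes nothing to the combined estimate
        defined = mag > 1e-9 * np.maximum(w, 1e-300)
        theta = np.where(defined, np.angle(resultant), 0.0)
        vec += w * np.exp(1j * theta) * defined
        total += w
    med = np.median(total)
    floor = floor_frac * med if med > 0 else np.inf
    valid = (total > floor) & (np.abs(vec) > 1e-12 * np.maximum(total, 1e-300))
    centroid = np.where(valid, _wrap(np.angle(vec)), np.nan)
    return BumpTrace(t=cr.t.copy(), centroid=centroid, valid=valid, total_signal=total)


def _glomerular_profile(cr: ConvolvedRaster, neurons) -> np.ndarray:
    """(8, T) P-EN signal pooled over hemispheres by glomerulus index."""
    geo = _pen_geometry(neurons)
    prof = np.zeros((GLOM_PER_TURN, cr.signal.shape[1]))
    for hemi in ("L", "R"):
        rows, _, gbin = geo[hemi]
        for r, g in zip(rows, gbin):
            prof[g] += cr.signal[r]
    return prof


def _fwhm_pct(profile: np.ndarray) -> float:
    """FWHM of a wrapped profile over equally spaced bins, as % of 360°."""
    nb = profile.shape[0]
    if np.all(profile <= 0):
        return 0.0
    peak = float(profile.max())
    if np.all(profile >= peak / 2):
        return 100.0
    # rotate the peak to the center, then interpolate the half-max crossings
    ipk = int(np.argmax(profile))
    prof = np.roll(profile, nb // 2 - ipk)
    half = peak / 2.0
    c = nb // 2
    right = c
    while prof[(right + 1) % nb] >= half and right < c + nb:
        right += 1
    left = c
    while prof[(left - 1) % nb] >= half and left > c - nb:
        left -= 1
    # fractional positions via linear interpolation into the sub-half bins
    def frac(a, b):
        pa, pb = prof[a % nb], prof[b % nb]
        return (pa - half) / (pa - pb) if pa != pb else 0.0

    width_bins = (right - left) + frac(right, right + 1) + frac(left, left - 1)
    return float(min(width_bins, nb) / nb * 100.0)


def _frames_with_signal(cr: ConvolvedRaster, neurons, floor_frac: float = 0.01):
    """Frames whose total P-EN signal clears the validity floor.

    Unlike centroid validity this does not require a nonzero resultant, so
    a spatially uniform (degenerate-centroid) profile still has a width.
    """
    geo = _pen_geometry(neurons)
    total = sum(cr.signal[geo[h][0]].sum(axis=0) for h in ("L", "R"))
    med = np.median(total)
    floor = floor_frac * med if med > 0 else np.inf
    return total > floor


def bump_width(cr: ConvolvedRaster, neurons, t: float) -> float:
    """FWHM (% of azimuth) of the pooled glomerular profile at time ``t``."""
    k = int(np.argmin(np.abs(cr.t - t)))
    if not _frames_with_signal(cr, neurons)[k]:
        raise ValueError(f"no valid bump at t={t}")
    return _fwhm_pct(_glomerular_profile(cr, neurons)[:, k])


def width_trace(cr: ConvolvedRaster, neurons) -> np.ndarray:
    """Per-frame FWHM (% of azimuth); NaN on invalid frames."""
    ok = _frames_with_signal(cr, neurons)
    prof = _glomerular_profile(cr, neurons)
    out = np.full(cr.t.shape, np.nan)
    for k in np.flatnonzero(ok):
        out[k] = _fwhm_pct(prof[:, k])
    return out


def drift_rate(trace: BumpTrace, t_start: float = 0.0, t_end: float = np.inf) -> float:
    """Mean absolute wrapped centroid displacement per second, in glomeruli.

    Computed over consecutive valid frame pairs within [t_start, t_end];
    8 glomeruli correspond to a full circle.
    """
    sel = trace.valid & (trace.t >= t_start) & (trace.t < t_end)
    idx = np.flatnonzero(sel)
    if idx.size < 2:
        return 0.0
    pairs = idx[:-1][np.diff(idx) == 1]
    if pairs.size == 0:
        return 0.0
    d = np.abs(_wrap(trace.centroid[pairs + 1] - trace.centroid[pairs]))
    dt = trace.t[1] - trace.t[0]
    return float(d.mean() / dt * GLOM_PER_TURN / _TWO_PI)


def position_modes(
    histogram: np.ndarray,
    bin_edges: np.ndarray | None = None,
    prominence_floor: float = 0.001,
    smooth_bins: float = 1.0,
):
    """Detect discrete preferred positions in a circular position histogram.

    The histogram (counts per azimuth bin over 2π) is circularly smoothed,
    local maxima are found, every bin is assigned to its nearest mode, and
    modes whose basin holds less than ``prominence_floor`` of all frames are
    dropped.  Returns (mode_azimuths, occupancies, adjacent_spacings_deg).
    """
    h = np.asarray(histogram, dtype=float)
    nb = h.size
    if bin_edges is None:
        bin_edges = np.linspace(-np.pi, np.pi, nb + 1)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    if smooth_bins > 0:
        half = int(np.ceil(4 * smooth_bins))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / smooth_bins) ** 2)
        k /= k.sum()
        hs = np.convolve(np.concatenate([h[-half:], h, h[:half]]), k, mode="same")[
            half:-half
        ]
    else:
        hs = h
    ext = np.concatenate([hs[-1:], hs, hs[:1]])
    (imax,) = argrelmax(ext, mode="wrap")
    peaks = sorted({(i - 1) % nb for i in imax if 0 < i <= nb})
    if not peaks and hs.max() > 0:
        peaks = [int(np.argmax(hs))]
    peaks = np.array(peaks, dtype=int)
    if peaks.size == 0:
        return np.empty(0), np.empty(0), np.empty(0)
    # basin assignment: each bin goes to the circularly nearest peak
    d = np.abs(_wrap(centers[:, None] - centers[peaks][None, :]))
    nearest = np.argmin(d, axis=1)
    occ = np.array([h[nearest == k].sum() for k in range(peaks.size)])
    tot = h.sum()
    occ = occ / tot if tot > 0 else occ
    keep = occ >= prominence_floor
    mode_az = centers[peaks][keep]
    occ = occ[keep]
    order = np.argsort(mode_az)
    mode_az, occ = mode_az[order], occ[order]
    if mode_az.size > 1:
        spac = np.degrees(
            np.diff(np.concatenate([mode_az, [mode_az[0] + _TWO_PI]]))
        )
    else:
        spac = np.empty(0)
    return mode_az, occ, spac


def speed_distribution(
    trace: BumpTrace,
    window: float = 0.02,
    stay_thresh: float = 0.5,
    jump_thresh: float = 1.5,
):
    """Wrapped bump displacement statistics over a sliding window.

    Displacements are measured in wedge units (16 per circle) over
    ``window`` seconds.  Categories: stay (< ``stay_thresh`` wedges), slide
    (between the thresholds — motion to an adjacent position), jump
    (≥ ``jump_thresh`` wedges, a non-adjacent transition).  Returns a dict
    with the per-frame speed samples (glomeruli/s) and category counts and
    mean speeds.
    """
    dt = trace.t[1] - trace.t[0]
    lag = max(1, int(round(window / dt)))
    ok = trace.valid[:-lag] & trace.valid[lag:]
    disp = np.abs(_wrap(trace.centroid[lag:] - trace.centroid[:-lag]))[ok]
    disp_wedges = disp / (_TWO_PI / 16)
    speeds = disp / (lag * dt) * GLOM_PER_TURN / _TWO_PI
    cats = np.full(disp.shape, "slide", dtype=object)
    cats[disp_wedges < stay_thresh] = "stay"
    cats[disp_wedges >= jump_thresh] = "jump"
    summary = {}
    for name in ("stay", "slide", "jump"):
        m = cats == name
        summary[name] = {
            "count": int(m.sum()),
            "mean_speed": float(speeds[m].mean()) if m.any() else 0.0,
        }
    return {"speeds": speeds, "categories": cats, "summary": summary}


def selectivity_index(
    trace: BumpTrace,
    competitor_azimuths,
    t_start: float,
    t_end: float,
    debounce: float = 0.05,
):
    """Fraction of valid frames spent at the winning one of two cues.

    Each valid frame in [t_start, t_end) is assigned to the circularly
    nearer cue; the index is the fraction assigned to the majority cue
    (∈ [0.5, 1]).  Switches are majority-cue changes that persist for at
    least ``debounce`` seconds.  Returns (index, n_switches).
    """
    a1, a2 = competitor_azimuths
    sel = trace.valid & (trace.t >= t_start) & (trace.t < t_end)
    th = trace.centroid[sel]
    if th.size == 0:
        return 0.5, 0
    near1 = np.abs(_wrap(th - a1)) <= np.abs(_wrap(th - a2))
    frac1 = near1.mean()
    index = float(max(frac1, 1.0 - frac1))
    dt = trace.t[1] - trace.t[0]
    need = max(1, int(round(debounce / dt)))
    switches = 0
    cur = near1[0]
    run_val, run_len = near1[0], 1
    for v in near1[1:]:
        if v == run_val:
            run_len += 1
        else:
            run_val, run_len = v, 1
        if v != cur and run_len >= need:
            switches += 1
            cur = v
    return index, switches
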