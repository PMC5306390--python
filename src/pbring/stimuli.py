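"""Upstream input generation for the E-PGs.

Inputs to the circuit are action potentials in unmodeled neurons upstream of
the 18 E-PG channels.  Every channel carries 5 Hz Poisson background
activity; sensory epochs (static bars, rotating bars, paired competitors)
add Poisson spikes peaking at 120 Hz on the channels of the stimulated EB
tile.  Each upstream spike injects exactly one unit PSC of excitatory
current into its E-PG.

Azimuths follow the EB convention: tile k is centered at −π + (k + ½)·π/4;
a bar at azimuth a drives the nearest tile (both wedge channels, including
the G9 wrap partners), with immediate neighbor tiles receiving a
configurable fraction of the peak rate (0 by default).

Spike trains are sampled with the thinning algorithm for inhomogeneous
Poisson processes, one named generator per render, so a (program, seed) pair
is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import connectome as _conn
from .lif_engine import NeuronParams, psc_template

__all__ = [
    "BACKGROUND_RATE_HZ",
    "BAR_PEAK_RATE_HZ",
    "StimulusEpoch",
    "InputSpikeTrains",
    "epoch_rates",
    "render_program",
    "single_spike_input",
    "input_current",
    "bar_epoch",
    "rotating_bar_epoch",
    "competitor_epoch",
    "N_CHANNELS",
]

BACKGROUND_RATE_HZ = 5.0
BAR_PEAK_RATE_HZ = 120.0
N_CHANNELS = 18

_TWO_PI = 2 * np.pi


def _wrap(a):
    """Wrap angle(s) to (−π, π]."""
    return -((-np.asarray(a) + np.pi) % _TWO_PI - np.pi)


def _nearest_tile(azimuth: float) -> int:
    d = _wrap(np.array([_conn.tile_azimuth(k) for k in range(_conn.N_TILES)]) - azimuth)
    return int(np.argmin(np.abs(d)))


@dataclass(frozen=True)
class StimulusEpoch:
    """One timed input epoch.

    ``kind`` is one of dark, bar, rotating_bar, competitors, single_spike,
    custom_rates.  ``azimuths`` holds one angle (bar/rotating start) or two
    (competitors), in radians in (−π, π].  ``angular_speed`` (rad/s) applies
    to rotating bars; if None, one full revolution over the epoch.
    ``neighbor_frac`` sets the rate of tiles adjacent to the peak tile as a
    fraction of ``peak_rate``.  ``rates`` (length 18, Hz) is used by
    custom_rates epochs only.
    """

    kind: str
    t_start: float
    t_end: float
    azimuths: tuple = ()
    peak_rate: float = BAR_PEAK_RATE_HZ
    angular_speed: float | None = None
    neighbor_frac: float = 0.0
    rates: tuple = ()

    def __post_init__(self):
        if self.t_start >= self.t_end:
            raise ValueError("epoch must have t_start < t_end")
        if self.peak_rate < 0:
            raise ValueError("peak_rate must be ≥ 0")
        if self.kind == "competitors" and len(self.azimuths) != 2:
            raise ValueError("competitor epochs carry exactly two azimuths")
        if self.kind in ("bar", "rotating_bar") and len(self.azimuths) != 1:
            raise ValueError(f"{self.kind} epochs carry exactly one azimuth")

    def azimuth_at(self, t: float) -> float:
        """Bar azimuth at time t (rotating bars advance and wrap)."""
        a0 = self.azimuths[0]
        if self.kind != "rotating_bar":
            return a0
        speed = self.angular_speed
        if speed is None:
            speed = _TWO_PI / (self.t_end - self.t_start)
        return float(_wrap(a0 + speed * (t - self.t_start)))


def bar_epoch(t_start, t_end, azimuth, peak_rate=BAR_PEAK_RATE_HZ, **kw):
    return StimulusEpoch("bar", t_start, t_end, (float(azimuth),), peak_rate, **kw)


def rotating_bar_epoch(t_start, t_end, azimuth0=None, angular_speed=None,
                       peak_rate=BAR_PEAK_RATE_HZ, **kw):
    if azimuth0 is None:
        azimuth0 = _conn.tile_azimuth(0)
    return StimulusEpoch(
        "rotating_bar", t_start, t_end, (float(azimuth0),), peak_rate,
        angular_speed=angular_speed, **kw,
    )


def competitor_epoch(t_start, t_end, tiles=(2, 6), peak_rate=BAR_PEAK_RATE_HZ, **kw):
    """Two firing-rate-matched cues at non-adjacent tiles (default 2 and 6)."""
    az = tuple(float(_conn.tile_azimuth(t)) for t in tiles)
    return StimulusEpoch("competitors", t_start, t_end, az, peak_rate, **kw)


@dataclass
class InputSpikeTrains:
    """Rendered upstream spike times, one sorted array per E-PG channel."""

    channels: list
    duration: float
    seed: int | None = None

    def __post_init__(self):
        for c, times in enumerate(self.channels):
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValueError(f"channel {c} has spikes outside [0, duration)")
            self.channels[c] = np.sort(t)

    def rate(self, channel: int) -> float:
        return len(self.channels[channel]) / self.duration


_CHANNEL_TILES = None


def _channel_tiles() -> list:
    """channel id → list of tiles whose input it receives (wrap cells: 1)."""
    global _CHANNEL_TILES
    if _CHANNEL_TILES is None:
        by_tile = _conn.epg_channels_by_tile(_conn.enumerate_neurons())
        out = [[] for _ in range(N_CHANNELS)]
        for t, chans in enumerate(by_tile):
            for c in chans:
                out[c].append(t)
        _CHANNEL_TILES = out
    return _CHANNEL_TILES


def epoch_rates(epoch: StimulusEpoch, t: float) -> np.ndarray:
    """Added firing rate (Hz) per E-PG channel contributed by ``epoch`` at t.

    Dark epochs add nothing (background is rendered separately); bar-like
    epochs put ``peak_rate`` on the channels of the tile nearest each bar
    azimuth and ``neighbor_frac``·peak_rate on the two adjacent tiles.
    """
    if not (epoch.t_start <= t < epoch.t_end):
        raise ValueError("t outside epoch")
    rates = np.zeros(N_CHANNELS)
    if epoch.kind == "dark":
        return rates
    if epoch.kind == "custom_rates":
        r = np.asarray(epoch.rates, dtype=float)
        if r.shape != (N_CHANNELS,):
            raise ValueError("custom_rates epochs need 18 rates")
        return r
    if epoch.kind == "single_spike":
        return rates
    tile_rate = np.zeros(_conn.N_TILES)
    azimuths = (
        [epoch.azimuth_at(t)]
        if epoch.kind in ("bar", "rotating_bar")
        else list(epoch.azimuths)
    )
    for a in azimuths:
        k = _nearest_tile(a)
        tile_rate[k] = max(tile_rate[k], epoch.peak_rate)
        if epoch.neighbor_frac > 0:
            for dk in (-1, 1):
                kk = (k + dk) % _conn.N_TILES
                tile_rate[kk] = max(tile_rate[kk], epoch.neighbor_frac * epoch.peak_rate)
    for c, tiles in enumerate(_channel_tiles()):
        for k in tiles:
            rates[c] = max(rates[c], tile_rate[k])
    return rates


def _total_rate(program, t: float, background: float) -> np.ndarray:
    rates = np.full(N_CHANNELS, background)
    for ep in program:
        if ep.t_start <= t < ep.t_end:
            rates = rates + epoch_rates(ep, t)
    return rates


def render_program(
    program: list,
    duration: float,
    seed: int | None,
    background_rate: float = BACKGROUND_RATE_HZ,
) -> InputSpikeTrains:
    """Render a stimulus program to Poisson spike trains (thinning sampler).

    Each channel's rate is ``background_rate`` plus the sum of concurrent
    epoch rates.  Epochs must not overlap in time.
    """
    program = sorted(program, key=lambda e: e.t_start)
    for a, b in zip(program, program[1:]):
        if b.t_start < a.t_end:
            raise ValueError("overlapping stimulus epochs")
    for ep in program:
        if ep.t_end > duration + 1e-12:
            raise ValueError("duration does not cover all epochs")
    rng = np.random.default_rng(seed)
    peak = max([background_rate] + [
        background_rate + ep.peak_rate for ep in program if ep.kind != "dark"
    ])
    channels = []
    for c in range(N_CHANNELS):
        if duration <= 0 or peak <= 0:
            channels.append(np.empty(0))
            continue
        n_cand = rng.poisson(peak * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        keep = np.empty(n_cand, dtype=bool)
        for idx, t in enumerate(cand):
            keep[idx] = rng.uniform() * peak < _total_rate(program, t, background_rate)[c]
        channels.append(cand[keep])
    return InputSpikeTrains(channels=channels, duration=duration, seed=seed)


def single_spike_input(channel: int, t_spike: float, duration: float) -> InputSpikeTrains:
    """Exactly one upstream spike on one channel, no background."""
    if not 0 <= t_spike < duration:
        raise ValueError("t_spike must lie in [0, duration)")
    channels = [np.empty(0) for _ in range(N_CHANNELS)]
    channels[channel] = np.array([t_spike])
    return InputSpikeTrains(channels=channels, duration=duration, seed=None)


def input_current(
    trains: InputSpikeTrains,
    params: NeuronParams | None = None,
    n_neurons: int = _conn.N_NEURONS,
    epg_rows: np.ndarray | None = None,
) -> np.ndarray:
    """Convert upstream spike trains to the (n, T) E-PG input-current array.

    Each spike adds one unit PSC template (peak I_PSC, positive) starting at
    the spike time on its channel's row; superposition is additive and
    templates running past the end are truncated.
    """
    p = params or NeuronParams()
    if epg_rows is None:
        epg_rows = np.arange(N_CHANNELS)
    T = int(round(trains.duration / p.dt))
    psc = psc_template(p)
    L = psc.shape[0]
    I = np.zeros((n_neurons, T))
    for c, times in enumerate(trains.channels):
        row = epg_rows[c]
        for t in times:
            s = int(round(t / p.dt))
            if s >= T:
                continue
            stop = min(L, T - s)
            I[row, s : s + stop] += psc[:stop]
    return I
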