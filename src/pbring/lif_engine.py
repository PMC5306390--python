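"""Leaky-integrate-and-fire simulation of the 60-neuron PB-EB circuit.

Each neuron integrates a leak toward rest plus external, synaptic and ectopic
currents under forward Euler (Δt = 10⁻⁴ s).  When the membrane voltage
reaches threshold, a templated action-potential trace is inserted into the
voltage time series (integration is suspended for the 2 ms AP window and
resumes from the −72 mV undershoot), and a templated postsynaptic-current
trace is added to the neuron's output current.  Synaptic drive onto neuron i
is Σ_j M[j, i]·I_out_j(t), with M in units of PSCs per action potential.

All quantities are SI internally (volts, amperes, farads, ohms, seconds);
the conventional unit mix (mV, nA, μF, MΩ, ms) is converted at construction.

Gaussian voltage noise (sd 3×10⁻¹⁰ V per neuron per time step) breaks the
initial symmetry so the bump can move spontaneously.

The Euler core is written once (:func:`_lif_core`) and compiled with numba
for production; the uncompiled Python function is retained so tests can
cross-check the two paths bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
from numba import njit

__all__ = [
    "NeuronParams",
    "EctopicSchedule",
    "SimulationResult",
    "ap_template",
    "psc_template",
    "simulate",
]


@dataclass(frozen=True)
class NeuronParams:
    """Physiology of a generic model neuron (SI units).

    Defaults: C_m = 0.002 μF, V_0 = −52 mV, R_m = 10 MΩ (so the membrane time
    constant is 20 ms), V_thr = −45 mV, V_max = +20 mV, V_min = −72 mV,
    t_AP = 2 ms, I_PSC = 5 nA, t_PSC (decay half-life) = 5 ms, per-step noise
    sd 3×10⁻¹⁰ V, Δt = 10⁻⁴ s.
    """

    C_m: float = 2e-9  # F
    V_0: float = -52e-3  # V
    R_m: float = 1e7  # Ω
    V_thr: float = -45e-3  # V
    V_max: float = 20e-3  # V
    V_min: float = -72e-3  # V
    t_AP: float = 2e-3  # s
    I_PSC: float = 5e-9  # A
    t_PSC: float = 5e-3  # s
    noise_sd: float = 3e-10  # V per step
    dt: float = 1e-4  # s

    def __post_init__(self):
        if not (self.V_min < self.V_0 < self.V_thr < self.V_max):
            raise ValueError("require V_min < V_0 < V_thr < V_max")
        for name in ("t_AP", "t_PSC", "R_m", "C_m", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt >= self.t_AP:
            raise ValueError("dt must be smaller than t_AP")

    @property
    def tau_m(self) -> float:
        return self.R_m * self.C_m


@dataclass
class EctopicSchedule:
    """Constant per-neuron ectopic current with an optional time window.

    ``amplitudes`` is a length-n vector in amperes; the current is applied
    for t in [t_start, t_end) (defaults: the whole simulation).
    """

    amplitudes: np.ndarray
    t_start: float = 0.0
    t_end: float = np.inf

    def render(self, n: int, n_steps: int, dt: float) -> np.ndarray:
        amp = np.asarray(self.amplitudes, dtype=float)
        if amp.shape != (n,):
            raise ValueError(f"amplitudes must have shape ({n},)")
        if not np.all(np.isfinite(amp)):
            raise ValueError("ectopic amplitudes must be finite")
        if self.t_start < 0 or self.t_start > self.t_end:
            raise ValueError("bad ectopic window")
        out = np.zeros((n, n_steps))
        i0 = int(round(self.t_start / dt))
        i1 = n_steps if np.isinf(self.t_end) else int(round(self.t_end / dt))
        out[:, i0 : min(i1, n_steps)] = amp[:, None]
        return out


@dataclass
class SimulationResult:
    """Raster, voltage and output-current traces of one run."""

    spike_neurons: np.ndarray  # neuron id per spike
    spike_times: np.ndarray  # seconds, grouped by neuron, ascending
    V: np.ndarray | None  # (n, T) volts, or None if not recorded
    I_out: np.ndarray | None  # (n, T) amperes, or None if not recorded
    dt: float
    duration: float
    seed: int | None
    params: NeuronParams

    @property
    def n_neurons(self) -> int:
        return 60 if self.V is None else self.V.shape[0]

    def spikes_of(self, i: int) -> np.ndarray:
        return self.spike_times[self.spike_neurons == i]

    def raster(self, n: int | None = None) -> list:
        n = n or self.n_neurons
        return [self.spikes_of(i) for i in range(n)]


def ap_template(params: NeuronParams | None = None, dt: float | None = None) -> np.ndarray:
    """Templated action potential, sampled at dt over [0, t_AP].

    First half: threshold-to-peak rise shaped like a unit-normalized Gaussian
    pdf evaluated at −1 + t/(t_AP/2); second half: peak-to-undershoot fall
    shaped like a unit-normalized quarter-to-three-quarter sine.  Endpoint
    identities: trace[0] = V_thr, trace[t_AP/2] = V_max, trace[t_AP] = V_min.
    """
    p = params or NeuronParams()
    dt = dt or p.dt
    if p.t_AP <= 2 * dt:
        raise ValueError("t_AP must exceed two Euler steps")
    n = int(round(p.t_AP / dt))
    t = np.arange(n + 1) * dt
    half = p.t_AP / 2
    out = np.empty(n + 1)
    rise = t <= half
    x = -1.0 + t[rise] / half
    pdf = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
    lo, hi = np.exp(-0.5) / np.sqrt(2 * np.pi), 1.0 / np.sqrt(2 * np.pi)
    out[rise] = p.V_thr + (p.V_max - p.V_thr) * (pdf - lo) / (hi - lo)
    tf = t[~rise]
    s = np.sin((tf - half) * 2 * np.pi / p.t_AP + np.pi / 2)
    out[~rise] = p.V_min + (p.V_max - p.V_min) * (s + 1.0) / 2.0
    return out


def psc_template(params: NeuronParams | None = None, dt: float | None = None) -> np.ndarray:
    """Templated postsynaptic current, sampled at dt over [0, 2 ms + 7·t_PSC].

    A 2 ms sine rise from 0 to I_PSC followed by an exponential decay with
    half-life t_PSC, each segment normalized to [0, 1] before scaling, so the
    trace starts and ends at exactly zero and peaks at exactly I_PSC.
    """
    p = params or NeuronParams()
    dt = dt or p.dt
    t_rise = 2e-3
    total = t_rise + 7 * p.t_PSC
    n = int(round(total / dt))
    t = np.arange(n + 1) * dt
    out = np.empty(n + 1)
    rise = t <= t_rise
    s = np.sin((t[rise] / 1e-3) * np.pi / 2 - np.pi / 2)  # formula in ms
    out[rise] = p.I_PSC * (s + 1.0) / 2.0
    td = t[~rise]
    raw = 2.0 ** (-(td - t_rise) / p.t_PSC)
    lo = 2.0**-7
    out[~rise] = p.I_PSC * (raw - lo) / (1.0 - lo)
    return out


def _lif_core(MT, I_ext, noise, ap, psc, v_init, V0, Vthr, leak, dt_over_Cm,
              spk_i, spk_t):
    """Forward-Euler LIF loop.  MT is M transposed (MT[i, j] = M[j, i]).

    Written in no-object numba-compatible style; compiled below.  Returns the
    spike count; fills V, I_out and the spike arrays in place.
    """
    n, T = I_ext.shape
    n_ap = ap.shape[0] - 1
    n_psc = psc.shape[0]
    V = np.empty((n, T))
    I_out = np.zeros((n, T))
    phase = np.full(n, -1, dtype=np.int64)  # ≥0: index into AP template
    for i in range(n):
        V[i, 0] = v_init[i]
    count = 0
    for t in range(1, T):
        for i in range(n):
            if phase[i] >= 0:
                phase[i] += 1
                if phase[i] <= n_ap:
                    V[i, t] = ap[phase[i]]
                    continue
                phase[i] = -1  # window over; resume integration from V_min
            syn = 0.0
            for j in range(n):
                syn += MT[i, j] * I_out[j, t - 1]
            v = V[i, t - 1]
            v += dt_over_Cm * ((V0 - v) * leak + I_ext[i, t - 1] + syn)
            v += noise[i, t]
            if v >= Vthr:
                # spike: insert AP template, emit one PSC
                V[i, t] = ap[0]
                phase[i] = 0
                spk_i[count] = i
                spk_t[count] = t
                count += 1
                stop = min(n_psc, T - t)
                for k in range(stop):
                    I_out[i, t + k] += psc[k]
            else:
                V[i, t] = v
    return count, V, I_out


_lif_core_jit = njit(cache=True)(_lif_core)


def simulate(
    M: np.ndarray,
    I_in: np.ndarray,
    params: NeuronParams | None = None,
    *,
    duration: float | None = None,
    ectopic: EctopicSchedule | None = None,
    seed: int | None = 0,
    noise: bool = True,
    record: bool = True,
    epg_rows: np.ndarray | None = None,
    v_init: np.ndarray | float | None = None,
    compiled: bool = True,
) -> SimulationResult:
    """Simulate the circuit.

    Parameters
    ----------
    M : (n, n) array
        Connectivity, ``M[j, i]`` = strength (PSCs/spike) of synapse j → i.
    I_in : (n, T) array
        External input current in amperes, one row per neuron.  Per the
        model's input convention only E-PG rows may be nonzero; pass
        ``epg_rows`` to enforce this.
    duration : float, optional
        Simulated seconds; defaults to ``I_in.shape[1] * dt``.
    ectopic : EctopicSchedule, optional
        Constant per-neuron current emulating thermo-/optogenetic drive.
    seed : int or None
        Seeds the membrane noise; ``noise=False`` runs deterministically.
    record : bool
        Keep the full V and I_out traces (≈40 MB for a 4 s run).
    compiled : bool
        Use the numba-compiled core (the pure-Python path is for testing).
    """
    p = params or NeuronParams()
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n):
        raise ValueError("M must be square")
    if duration is not None:
        T = int(round(duration / p.dt))
        if I_in.shape[1] < T:
            pad = np.zeros((n, T - I_in.shape[1]))
            I_in = np.concatenate([I_in, pad], axis=1)
        I_in = I_in[:, :T]
    I_in = np.ascontiguousarray(I_in, dtype=float)
    if I_in.shape[0] != n:
        raise ValueError("I_in must have one row per neuron")
    T = I_in.shape[1]
    if epg_rows is not None:
        outside = np.setdiff1d(np.arange(n), epg_rows)
        if np.any(I_in[outside] != 0):
            raise ValueError("I_in must be zero outside the E-PG rows")
    I_ext = I_in
    if ectopic is not None:
        I_ext = I_ext + ectopic.render(n, T, p.dt)

    if noise:
        rng = np.random.default_rng(seed)
        noise_arr = rng.normal(0.0, p.noise_sd, size=(n, T))
    else:
        noise_arr = np.zeros((n, T))

    ap = ap_template(p)
    psc = psc_template(p)
    cap = n * (T // (ap.shape[0] - 1) + 2)
    spk_i = np.empty(cap, dtype=np.int64)
    spk_t = np.empty(cap, dtype=np.int64)
    if v_init is None:
        v0_arr = np.full(n, p.V_0)
    else:
        v0_arr = np.broadcast_to(np.asarray(v_init, dtype=float), (n,)).copy()
    core = _lif_core_jit if compiled else _lif_core
    count, V, I_out = core(
        np.ascontiguousarray(M.T),
        I_ext,
        noise_arr,
        ap,
        psc,
        v0_arr,
        p.V_0,
        p.V_thr,
        1.0 / p.R_m,
        p.dt / p.C_m,
        spk_i,
        spk_t,
    )
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("membrane voltage diverged (non-finite)")
    return SimulationResult(
        spike_neurons=spk_i[:count].copy(),
        spike_times=spk_t[:count] * p.dt,
        V=V if record else None,
        I_out=I_out if record else None,
        dt=p.dt,
        duration=T * p.dt,
        seed=seed,
        params=p,
    )
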