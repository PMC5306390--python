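# pbring

Spiking and graded-potential models of the *Drosophila* protocerebral
bridge / ellipsoid body (PB–EB) circuit — the fly brain's candidate ring
attractor for heading direction — with tools for building the connectome,
driving it with visual-like input, quantifying the activity "bump", and
mapping how the dynamics degrade as synaptic parameters are perturbed.

The package is aimed at computational neuroscientists who want a compact,
fully reproducible sandbox for ring-attractor dynamics in an anatomically
grounded 60-neuron circuit: 18 E-PG, 16 P-EN and 16 P-EG columnar neurons
plus 10 inhibitory PB-intrinsic (Δ7-type) neurons, with synapses inferred
from axon/dendrite compartment overlap, local excitation closed through
the EB's 16-wedge / 8-tile ring, and long-range inhibition from the Δ7
pool.

## Model in brief

Each neuron is a leaky integrate-and-fire unit, integrated by forward
Euler at Δt = 10⁻⁴ s:

    dV_i/dt = (1/C_m) [ (V₀ − V_i)/R_m + I_in,i + Σ_j M_ji I_j + I_ect,i ]

with C_m = 2 nF, V₀ = −52 mV, R_m = 10 MΩ, threshold −45 mV.  A threshold
crossing inserts a 2 ms templated action potential (peak +20 mV, undershoot
−72 mV) into the voltage trace and adds a templated postsynaptic current
(5 nA peak, 5 ms decay half-life, 37 ms long) to the neuron's output.
`M_ji` is the signed connectivity matrix in PSCs per spike: baseline +20
for the excitatory classes, −15 for Pintr→P-EN/P-EG, −20 for Pintr→Pintr.
Upstream input is Poisson spiking on one channel per E-PG (5 Hz
background; bars and competitors peak at 120 Hz), one unit PSC per
upstream spike.  A graded (non-spiking) variant replaces spikes with a
tanh current–voltage transfer.  Bump position is the circular centroid of
the Gaussian-convolved (σ = 24 ms) P-EN activity, modulo the eight
azimuthal positions, per hemisphere and then combined.

See `docs/methods.md` for the full model description, the package's design
decisions, and a documented discrepancy: in this reconstruction the
baseline bump is *more stable* than originally reported (it ignites,
persists and stays localized, but does not track moving cues or drift at
~1 glomerulus/s; the affected acceptance tests are left failing by
design).

## Worked example

```python
import numpy as np
from pbring import baseline_matrix, render_program, input_current, simulate
from pbring import bump_metrics as bm
from pbring.stimuli import bar_epoch
from pbring.connectome import tile_azimuth

cm = baseline_matrix()                                  # 60x60 signed matrix
program = [bar_epoch(0.0, 0.2, tile_azimuth(3))]        # brief cue at tile 3
trains = render_program(program, duration=2.0, seed=1)
result = simulate(cm.M, input_current(trains), duration=2.0, seed=1)

cr = bm.convolve_raster(result, n_neurons=60, duration=2.0)
trace = bm.bump_centroid(cr, cm.neurons)
widths = bm.width_trace(cr, cm.neurons)
dark = trace.t > 0.2
print(f"spikes: {len(result.spike_times)}")
print(f"bump present in darkness: {trace.valid[dark].mean():.1%} of frames")
print(f"median centroid: {np.degrees(np.median(trace.centroid[trace.valid & dark])):.1f} deg "
      f"(cue at {np.degrees(tile_azimuth(3)):.1f} deg)")
print(f"median width: {np.nanmedian(widths[dark]):.1f}% of the azimuth")
print(f"drift rate: {bm.drift_rate(trace, 0.2, 2.0):.3f} glomeruli/s")
```

prints

```
spikes: 8013
bump present in darkness: 100.0% of frames
median centroid: -22.5 deg (cue at -22.5 deg)
median width: 25.0% of the azimuth
drift rate: 0.008 glomeruli/s
```

A 0.2 s bar ignites a bump at the cue's azimuth; after the bar disappears
the bump persists through 1.8 s of darkness, stays two glomeruli wide
(25% of the azimuthal axis) and, in this reconstruction, barely moves.

## Command line

`pbring` exposes the pipeline as subcommands over the same library code:

```sh
pbring build-connectome --out out/
pbring simulate --config cfg.json --out run/ --seed 3
pbring analyze --raster run/raster.csv --duration 2.0 --out analysis/
pbring dither-sweep --n 100 --sigma 0.2 --k 15 --seed 0 --out modes/
pbring class-sweep --name "EPG>PEN" --out sweep/
pbring inject --subtype P-EN --out inject/
pbring fixture --out fixture/
```

Configs are JSON (YAML accepted); unknown keys are rejected by name; every
run writes a manifest (config hash, seed, versions).

## Acceptance script

`scripts/acceptance.py` recomputes the headline bump statistics from
scratch — it builds the connectome, runs bar-ignited and dark ensembles of
4 s spiking simulations, and measures the median bump width, the mean
spontaneous drift speed, and the mode structure (count and spacing) of the
pooled bump-position histogram:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes a few minutes and writes one JSON object with the measured
values and ensemble sizes.
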