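# Methods

`pbring` simulates the recurrent circuit linking the *Drosophila*
protocerebral bridge (PB) and ellipsoid body (EB), the candidate neural
substrate of the fly's head-direction ring attractor, and quantifies the
"bump" of activity it carries.  This note records the model, the package's
own design decisions where the published description leaves the design
open, and — importantly — a known dynamical discrepancy between this
reconstruction and the originally reported phenomenology.

## Circuit model

**Neurons and compartments.**  The model contains 60 neurons in four
classes: 18 E-PGs (dendrites in one EB wedge, axon in one PB glomerulus
plus the gall), 16 P-ENs (dendrites in PB glomeruli G2–G9, axon in one EB
tile plus the noduli), 16 P-EGs (G1–G8, axon in one EB tile plus the
gall), and 10 PB-intrinsic neurons (8 Δ7-type cells with dendrites in all
18 glomeruli and boutons in one bilateral glomerulus pair, and 2 cells
targeting G9).  A synapse is postulated wherever an axonal arbor overlaps a
dendritic arbor within one compartment (a tile overlapping both of its
wedges); no autapses.  Eight synapse classes result; within a class all
synapses share one signed strength, in units of postsynaptic currents
(PSCs) per presynaptic action potential.

**Azimuthal map.**  The wedge↔glomerulus correspondence interleaves the
hemispheres with a one-step offset (even wedges w = 2k ↔ R(k+1); odd
wedges w = 2k+1 ↔ L(k+2), wrapping w15 ↔ L1; the two G9 E-PGs share the
wrap-around wedges w0/w15).  This mirrored interleaving is what closes the
ring: a P-EN or P-EG re-exciting the tile of its home wedge reaches both
its own E-PG and the E-PG one wedge over, so local excitation spreads one
22.5° step per hop, right-hemisphere cells one way and left-hemisphere
cells the other.  A same-index map (w = 2k+1 ↔ L(k+1)) was rejected: under
it each tile's recurrence closes on itself and the excitatory graph
decomposes into eight disconnected islands, which cannot express any ring
phenomenology.  The network's bilateral symmetry is the geometric mirror
(hemisphere swap combined with azimuth reflection), an involution that
leaves the connectivity matrix exactly invariant.

**Baseline strengths.**  All excitatory classes +20 PSCs/spike; the
inhibitory Pintr→P-EN and Pintr→P-EG classes −15; Pintr→Pintr −20
(the Pintr pool is treated as inhibitory throughout, so its self-connections
are negative even though one reading of the source text groups them with
the excitatory classes).

## Spiking dynamics

Forward Euler with Δt = 10⁻⁴ s integrates, per neuron,

    dV/dt = (1/C_m) [ (V₀ − V)/R_m + I_in + Σ_j M_ji I_j + I_ect ]

with C_m = 2 nF, V₀ = −52 mV, R_m = 10 MΩ (membrane time constant 20 ms).
At threshold (−45 mV) a 2 ms templated action potential (Gaussian-pdf rise
to +20 mV, sine fall to −72 mV, each segment normalized to [0, 1] before
voltage scaling) is inserted into the voltage trace; integration is
suspended for the window and resumes from the −72 mV undershoot, with
further threshold crossings ignored inside the window.  Each spike also
adds one PSC template to the neuron's output current: a 2 ms sine rise to
5 nA followed by an exponential decay with 5 ms half-life, 37 ms total,
starting and ending at exactly zero.  PSCs superpose additively and are
truncated at the end of the run.  Gaussian voltage noise (sd 3×10⁻¹⁰ V per
neuron per step) breaks the initial symmetry.  Internally everything is SI;
the conventional units (mV, nA, MΩ, μF, ms) are converted at construction.

Upstream input: each of the 18 E-PGs owns one input channel carrying 5 Hz
Poisson background spikes; sensory epochs (bars at a fixed azimuth,
rotating bars, two matched competitors) add Poisson spikes peaking at
120 Hz on the channels of the stimulated EB tile (both wedge channels,
including the G9 wrap partners; the spatial spread to neighboring tiles is
configurable and defaults to none, the narrowest reading of the published
input description).  Every upstream spike injects exactly one unit PSC
into its E-PG.  Spike trains are drawn by thinning, one named generator
per render, so (program, seed) pairs reproduce exactly.  Ectopic currents
(thermo-/optogenetic analogs) are constant per-neuron offsets with an
optional time window.

The Euler core is written once and compiled with numba; the identical
uncompiled function is kept as an independent execution path and the two
are checked for bitwise agreement in the tests.

## Graded variant

The non-spiking variant replaces thresholded spikes with a saturating
current–voltage transfer: synaptic drive I_max Σ_j M_ji tanh(20·(V_j−V₀)),
I_max = 5 nA, the tanh argument in volts.  Because the transfer is steep,
working states sit at voltage-saturated fixed points; bumps appear as a
localized persistently depolarized region.  The published work does not
print the graded model's synapse strengths; the package ships a set found
by its own stagewise stochastic search (multiplicative Gaussian dithering
at 100%, then 10%, then 5% sd, 120 candidates per stage, greedy elitism,
fixed seed), scored by a documented bump score: the circular resultant
ratio of the rectified P-EN depolarization (localization) times a
saturating function of its total (persistence), evaluated after input
offset.  The score is this package's stand-in for the original manual
screening.

## Bump quantification

Spike rasters are convolved with a unit-area Gaussian kernel (sd 24 ms,
truncated at ±4 sd, 1 ms grid) as a pseudo-Ca²⁺ signal.  Bump position is
the circular (vector-sum) centroid of the P-EN signal per hemisphere —
each P-EN placed at its home wedge's azimuth, so the two hemispheres
interleave at 22.5° — combined across hemispheres by a circular mean
weighted by each hemisphere's total signal.  Frames whose total P-EN
signal falls below 1% of the run median, or whose resultant vanishes
(e.g. two antipodal bumps), are flagged invalid.  Bump width is the FWHM
(linear interpolation, wrapped) of the P-EN profile pooled across
hemispheres by glomerulus index — 8 bins of 45°, so one glomerulus reads
12.5%, two 25%, three 37.5%, matching the published "two or three
glomeruli (25–38%)" convention.  Drift rate is the mean absolute wrapped
frame-to-frame centroid displacement per second, in glomerulus units
(8 per turn).  Position modes are local maxima of the circularly smoothed
96-bin position histogram with basin occupancy ≥ 0.1% of frames; bump
speeds are classified stay / slide / jump by displacement over a 20 ms
window (< 0.5 wedge, 0.5–1.5 wedges, ≥ 1.5 wedges).  Competitor
selectivity is the fraction of valid frames nearer the majority cue, with
switches debounced at 50 ms.

## Parameter-space pipeline

Class strengths are dithered multiplicatively, s′ = s(1 + N(0, σ)) (σ = 1
flips a sign 16% of the time, Φ(−1)); per-synapse dithering applies the
same formula entrywise to the matrix.  Each configuration is simulated
under a fixed 2 s diagnostic program — one bar revolution during
[0.2, 1.0] s, competitors at tiles 2 and 6 during [1.2, 2.0] s — and
summarized by a 12,000-dimensional feature: the pseudo-Ca²⁺ signal of all
60 neurons in two 200 ms windows ([0.5, 0.7] and [1.2, 1.4] s), subsampled
20:1 (100 + 100 time points).  Features are clustered by k-means in the
original space (k = 15 for the catalog, k = 400 for the broad search; PCA
is 2-D visualization only).  Cluster means are labeled by a rule-based
classifier whose gates are this package's own and live in one config
block: seizure (mean activity > 3× baseline and azimuthal width > 75%),
silent (any class below 5% of its baseline mean), then localized
(median FWHM ≤ 50%), tracking (circular correlation with the bar azimuth
> 0.7), selective (index > 0.8); localized + tracking + selective =
proper bump, localized only = too stable, and so on.  Seizure is tested
before silence because disinhibited runs seize with a mute Pintr class.

## Known discrepancy: bump stability

This reconstruction reproduces ignition of a persistent bump from a single
upstream spike, its 25–38% width, the Δ7 pool's synchronous firing, the
discrete 22.5°-spaced position modes of the dark ensemble, and the failure
taxonomy under parameter manipulation (class silencing, network seizure).
It does **not** reproduce the mobile bump of the original report: here an
established bump is effectively immortal.  The arithmetic is simple: each
P-EN or P-EG has exactly one E-PG afferent (+20) and essentially one
Pintr afferent (−15), and both afferent populations are capped at the same
refractory-limited rate, so recurrent excitation always out-votes
inhibition once a bump saturates (~100 ms after ignition).  A 120 Hz bar
delivers far less drive than the saturated loop, so the bump neither
tracks a moving cue, nor switches between competitors, nor drifts
(~0.01 glomeruli/s for a single bump versus the reported ~1).  In
darkness-from-rest, background spikes can ignite two coexisting bumps
whose combined centroid wobbles, which makes the ensemble-mean drift
statistic unstable.  A systematic exploration of the mechanically
ambiguous choices (hyperpolarization floors, action-potential reset
conventions, PSC superposition versus replacement, the Pintr→Pintr sign,
and Δ7 bouton coverage from one bilateral pair to all eighteen glomeruli)
found no variant that is simultaneously ignitable and displaceable: the
window requires the inhibitory veto to exceed the recurrent drive while
staying below the bar drive, which is empty at the stated strengths.  The
affected acceptance tests assert the published phenomenology and are left
failing, with their docstrings marking them as mobility checks.

## What the synthetic world does and does not establish

All inputs are generated internally; there is no recorded data anywhere in
the pipeline.  A green test therefore establishes a property of the model
under the stated input statistics (5 Hz background, 120 Hz cues, the
diagnostic program), not agreement with any physiological recording.  The
generator emulates Poisson upstream spiking only; it has no adaptation, no
correlated noise across channels, and no closed-loop coupling between the
bump and the stimulus.

## Numerical choices

Euler at Δt = 10⁻⁴ s (passive relaxation matches the closed form to
< 0.1% of the initial offset; halving Δt moves early spike times by less
than 1 ms).  Spike-time arrays are preallocated at the refractory-limited
maximum.  The convolution grid is 1 ms (the 24 ms kernel makes a finer
grid pointless).  k-means uses 10 restarts by default with a fixed seed;
ties in the graded refinement go to the first candidate.  Degenerate
inputs raise: non-finite voltages, all-identical features, overlapping
stimulus epochs, inputs outside the E-PG rows.
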