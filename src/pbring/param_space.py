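"""Synapse-strength parameter-space exploration and mode cataloging.

The pipeline: dither the eight class strengths multiplicatively
(s′ = s·(1 + N(0, σ))), simulate each configuration under a fixed diagnostic
stimulus (a rotating bar then two static competitors), summarize each run by
a 12,000-dimensional dynamics feature (200 diagnostic time points × 60
neurons of the Gaussian-convolved raster), cluster features with k-means in
the original space (PCA is used for 2-D visualization only), and label each
cluster's mean dynamics with a rule-based failure-mode classifier (silent /
proper_bump / too_stable / no_selectivity / seizure / mixed).

Systematic single-class sweeps (multipliers −9× to 10×) and constant ectopic
current injections into anatomical subtypes are projected into the same
feature space, so manipulation effects can be compared directly with synapse
strength changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import connectome as conn
from . import stimuli as stim
from . import lif_engine as lif
from . import bump_metrics as bm

__all__ = [
    "DitherSpec",
    "MatrixDitherSpec",
    "ModeCatalog",
    "MODE_CLASSES",
    "CLASSIFIER_THRESHOLDS",
    "DIAGNOSTIC",
    "diagnostic_program",
    "dither_params",
    "dither_matrix",
    "run_diagnostic",
    "diagnostic_features",
    "cluster_modes",
    "classify_mode",
    "sweep_class",
    "bump_success_rate",
    "inject_current",
]

MODE_CLASSES = (
    "silent",
    "proper_bump",
    "too_stable",
    "no_selectivity",
    "seizure",
    "mixed",
)

#: Diagnostic stimulus timing (seconds).  2 s total: one bar revolution,
#: a dark gap, then two static competitors; the two 200 ms feature windows
#: sit inside the bar epoch and at competitor onset.
DIAGNOSTIC = {
    "duration": 2.0,
    "bar": (0.2, 1.0),
    "competitors": (1.2, 2.0),
    "competitor_tiles": (2, 6),
    "window_bar": (0.5, 0.7),
    "window_comp": (1.2, 1.4),
    "subsample": 20,  # 20:1 on the dt grid -> one point per 2 ms
}

#: Rule-based mode-classifier gates (this module's own, centralized here):
#: silent: some class's mean activity below 5% of the baseline class mean;
#: seizure: mean activity > 3× baseline and azimuthal width > 75%;
#: tracking: circular correlation(bar azimuth, centroid) > 0.7;
#: selectivity: competitor-window selectivity index > 0.8;
#: localized: median FWHM ≤ 50% of the azimuth.
CLASSIFIER_THRESHOLDS = {
    "silent_frac": 0.05,
    "seizure_activity": 3.0,
    "seizure_width": 75.0,
    "track_corr": 0.7,
    "selectivity": 0.8,
    "localized_width": 50.0,
}


@dataclass(frozen=True)
class DitherSpec:
    """Multiplicative Gaussian dithering of the 8 class strengths."""

    sigma_frac: float
    n: int
    seed: int = 0

    def __post_init__(self):
        if self.sigma_frac < 0 or self.n < 1:
            raise ValueError("sigma_frac must be ≥ 0 and n ≥ 1")


@dataclass(frozen=True)
class MatrixDitherSpec:
    """Per-synapse multiplicative noise (developmental variability analog)."""

    sigma: float
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be ≥ 0")


@dataclass
class ModeCatalog:
    k: int
    labels: np.ndarray  # cluster id per sample
    means: np.ndarray  # (k, 12000) cluster-mean dynamics
    mode_class: list  # per-cluster failure-mode label
    pca_coords: np.ndarray  # (n, 2) visualization coordinates

    def sample_classes(self) -> np.ndarray:
        return np.array([self.mode_class[l] for l in self.labels], dtype=object)


def diagnostic_program() -> list:
    d = DIAGNOSTIC
    return [
        stim.rotating_bar_epoch(*d["bar"]),
        stim.competitor_epoch(*d["competitors"], tiles=d["competitor_tiles"]),
    ]


def dither_params(baseline: conn.SynapseClassParams, spec: DitherSpec) -> list:
    """s′_k = s_k · (1 + N(0, σ)) independently per class and sample.

    At σ = 1 a strength flips sign with probability Φ(−1) ≈ 16%.
    """
    rng = np.random.default_rng(spec.seed)
    base = baseline.as_array()
    return [
        conn.SynapseClassParams.from_array(
            base * (1.0 + rng.normal(0.0, spec.sigma_frac, 8))
        )
        for _ in range(spec.n)
    ]


def dither_matrix(cm: conn.ConnectivityMatrix, spec: MatrixDitherSpec) -> conn.ConnectivityMatrix:
    """M′[j,i] = M[j,i]·(1 + N(0, σ)) per nonzero entry; zeros stay zero."""
    rng = np.random.default_rng(spec.seed)
    M = cm.M.copy()
    nz = M != 0
    M[nz] = M[nz] * (1.0 + rng.normal(0.0, spec.sigma, nz.sum()))
    return conn.ConnectivityMatrix(M=M, class_label=cm.class_label, neurons=cm.neurons)


def run_diagnostic(
    M: np.ndarray,
    seed: int,
    ectopic: lif.EctopicSchedule | None = None,
) -> lif.SimulationResult:
    """Simulate the canonical 2 s diagnostic program."""
    prog = diagnostic_program()
    trains = stim.render_program(prog, DIAGNOSTIC["duration"], seed)
    I = stim.input_current(trains)
    return lif.simulate(
        M, I, duration=DIAGNOSTIC["duration"], seed=seed, ectopic=ectopic,
        record=False,
    )


def diagnostic_features(result: lif.SimulationResult, program: list | None = None) -> np.ndarray:
    """12,000-vector: convolved raster in the two 200 ms diagnostic windows.

    The pseudo-Ca²⁺ signal is sampled on the Euler grid inside each window
    and subsampled 20:1 (100 + 100 time points), then flattened time-major
    (all 60 neurons per time point).  Raises if the program lacks a
    rotating-bar or competitor epoch.
    """
    program = program if program is not None else diagnostic_program()
    kinds = {ep.kind for ep in program}
    if "rotating_bar" not in kinds or "competitors" not in kinds:
        raise ValueError("diagnostic program needs rotating_bar and competitors")
    d = DIAGNOSTIC
    step = result.dt * d["subsample"]
    cr = bm.convolve_raster(result, n_neurons=60, grid=step)
    feats = []
    for w0, w1 in (d["window_bar"], d["window_comp"]):
        k0 = int(round(w0 / step))
        n_pts = int(round((w1 - w0) / step))
        feats.append(cr.signal[:, k0 : k0 + n_pts].T)  # (100, 60)
    return np.concatenate(feats, axis=0).ravel()


@lru_cache(maxsize=1)
def _baseline_reference(seed: int = 12345) -> np.ndarray:
    M = conn.baseline_matrix().M
    return diagnostic_features(run_diagnostic(M, seed))


def _feature_view(feature: np.ndarray) -> np.ndarray:
    return np.asarray(feature).reshape(200, 60)


_CLASS_SLICES = {
    "E-PG": slice(0, 18),
    "P-EN": slice(18, 34),
    "P-EG": slice(34, 50),
    "Pintr": slice(50, 60),
}


def _pen_centroid_series(fv: np.ndarray, neurons) -> np.ndarray:
    geo = {}
    for nrn in neurons:
        if nrn.neuron_class != "P-EN":
            continue
        (g,) = [c.index for c in nrn.dendrite_compartments if c.neuropil == "PB"]
        geo[nrn.id] = conn.wedge_azimuth(conn.wedge_of_glomerulus(nrn.hemisphere, g))
    rows = np.array(sorted(geo))
    az = np.array([geo[r] for r in rows])
    sig = fv[:, rows]
    vec = (sig * np.exp(1j * az)[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(np.abs(vec) > 0, np.angle(vec), np.nan)


def _glom_profile(fv: np.ndarray, neurons) -> np.ndarray:
    prof = np.zeros((fv.shape[0], 8))
    for nrn in neurons:
        if nrn.neuron_class != "P-EN":
            continue
        (g,) = [c.index for c in nrn.dendrite_compartments if c.neuropil == "PB"]
        prof[:, g % 8] += fv[:, nrn.id]
    return prof


def _circular_corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 10:
        return 0.0
    sa = np.sin(a - np.angle(np.mean(np.exp(1j * a))))
    sb = np.sin(b - np.angle(np.mean(np.exp(1j * b))))
    den = np.sqrt((sa**2).sum() * (sb**2).sum())
    return float((sa * sb).sum() / den) if den > 0 else 0.0


def classify_mode(
    mean_dynamics: np.ndarray,
    program: list | None = None,
    baseline_feature: np.ndarray | None = None,
    thresholds: dict | None = None,
    neurons: list | None = None,
) -> str:
    """Rule-based failure-mode label for one (mean) dynamics feature.

    Order of gates: seizure → silent → localization → tracking →
    selectivity; anything localized that neither tracks nor seizes is
    ``too_stable``; a delocalized but non-seizing, non-silent pattern is
    ``mixed``.
    """
    th = {**CLASSIFIER_THRESHOLDS, **(thresholds or {})}
    neurons = neurons or conn.enumerate_neurons()
    base = _feature_view(
        baseline_feature if baseline_feature is not None else _baseline_reference()
    )
    fv = _feature_view(mean_dynamics)
    prof = _glom_profile(fv, neurons)
    widths = [bm._fwhm_pct(p) for p in prof if p.max() > 0]
    med_width = float(np.median(widths)) if widths else 0.0
    # network-wide runaway takes precedence: a seizing circuit may also
    # carry one mute class (e.g. disinhibited runs with silenced Pintrs)
    if (
        fv.mean() > th["seizure_activity"] * base.mean()
        and med_width > th["seizure_width"]
    ):
        return "seizure"
    # class-mean activity relative to baseline
    for cls, sl in _CLASS_SLICES.items():
        b = base[:, sl].mean()
        if b > 0 and fv[:, sl].mean() < th["silent_frac"] * b:
            return "silent"
    if fv.mean() == 0:
        return "silent"
    localized = med_width <= th["localized_width"] and med_width > 0
    # tracking: first 100 points follow the bar azimuth
    d = DIAGNOSTIC
    step = d["subsample"] * 1e-4
    t_bar = d["window_bar"][0] + np.arange(100) * step
    bar_ep = (program or diagnostic_program())[0]
    bar_az = np.array([bar_ep.azimuth_at(t) for t in t_bar])
    cent = _pen_centroid_series(fv, neurons)
    tracks = _circular_corr(bar_az, cent[:100]) > th["track_corr"]
    # selectivity over the competitor window
    comp_az = (program or diagnostic_program())[1].azimuths
    th2 = cent[100:]
    ok = np.isfinite(th2)
    if ok.sum() >= 10:
        d1 = np.abs(bm._wrap(th2[ok] - comp_az[0]))
        d2 = np.abs(bm._wrap(th2[ok] - comp_az[1]))
        near1 = (d1 <= d2).mean()
        sel_index = max(near1, 1 - near1)
    else:
        sel_index = 0.0
    selective = sel_index > th["selectivity"]
    if localized and tracks and selective:
        return "proper_bump"
    if localized and tracks:
        return "no_selectivity"
    if localized:
        return "too_stable"
    return "mixed"


def cluster_modes(
    features: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    classify: bool = True,
) -> ModeCatalog:
    """k-means in the original 12,000-dim space + per-cluster mode labels.

    PCA (mean-centered, unscaled) supplies 2-D coordinates for plotting
    only; clustering never sees them.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < k:
        raise ValueError("need at least k feature vectors")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate features: all samples identical")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    means = np.vstack(
        [X[labels == c].mean(axis=0) if np.any(labels == c) else km.cluster_centers_[c]
         for c in range(k)]
    )
    pca_coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    classes = [classify_mode(m) for m in means] if classify else ["mixed"] * k
    return ModeCatalog(k=k, labels=labels, means=means,
                       mode_class=classes, pca_coords=pca_coords)


@lru_cache(maxsize=1)
def _cached_circuit():
    neurons = conn.enumerate_neurons()
    adjacency, labels = conn.infer_synapses(neurons)
    return neurons, adjacency, labels


def _matrix_for(params: conn.SynapseClassParams) -> np.ndarray:
    neurons, adjacency, labels = _cached_circuit()
    return conn.build_matrix(adjacency, labels, params, neurons).M


def _simulate_params(params: conn.SynapseClassParams, seed: int) -> np.ndarray:
    return diagnostic_features(run_diagnostic(_matrix_for(params), seed))


def sweep_class(
    class_name: str,
    multipliers: np.ndarray | None = None,
    replicates: int = 10,
    baseline: conn.SynapseClassParams | None = None,
    seed: int = 0,
):
    """Systematic variation of one synapse class from −9× to 10× baseline.

    Returns (multipliers, features[(n_mult, replicates, 12000)], labels).
    """
    baseline = baseline or conn.SynapseClassParams()
    field_name = conn._key_to_field(class_name)
    if multipliers is None:
        multipliers = np.linspace(-9, 10, 20)
    feats = np.empty((len(multipliers), replicates, 12000))
    labels = np.empty((len(multipliers), replicates), dtype=object)
    base = baseline.as_array()
    idx = list(conn.SynapseClassParams._FIELDS).index(field_name)
    for a, mult in enumerate(multipliers):
        vals = base.copy()
        vals[idx] = base[idx] * mult
        params = conn.SynapseClassParams.from_array(vals)
        for r in range(replicates):
            feats[a, r] = _simulate_params(params, seed + 1000 * a + r)
            labels[a, r] = classify_mode(feats[a, r])
    return np.asarray(multipliers), feats, labels


def bump_success_rate(
    n_configs: int,
    sigma_frac: float = 1.0,
    k: int = 400,
    seed: int = 0,
    baseline: conn.SynapseClassParams | None = None,
    n_init: int = 10,
):
    """Broad random search: fraction of dithered configs with proper bumps.

    Dithers at ``sigma_frac``, simulates the diagnostic program once per
    config, k-means clusters the features, classifies cluster means, and
    reports the fraction of configs falling in proper_bump clusters plus
    the per-class strength distributions of that successful pool.
    Returns (fraction, catalog, params_array[(n, 8)], success_mask).
    """
    if n_configs < k:
        raise ValueError("need n_configs ≥ k")
    baseline = baseline or conn.SynapseClassParams()
    if sigma_frac == 0:
        # degenerate: all configs are baseline; no clustering needed
        params = [baseline] * n_configs
        f = _simulate_params(baseline, seed)
        lab = classify_mode(f)
        frac = 1.0 if lab == "proper_bump" else 0.0
        mask = np.full(n_configs, lab == "proper_bump")
        return frac, None, np.vstack([p.as_array() for p in params]), mask
    params = dither_params(baseline, DitherSpec(sigma_frac, n_configs, seed))
    feats = np.vstack(
        [_simulate_params(p, seed + 7919 * i) for i, p in enumerate(params)]
    )
    catalog = cluster_modes(feats, k=k, seed=seed, n_init=n_init)
    classes = catalog.sample_classes()
    mask = classes == "proper_bump"
    frac = float(mask.mean())
    return frac, catalog, np.vstack([p.as_array() for p in params]), mask


_SUBTYPE_NAMES = ("E-PG", "E-PG_tip", "P-EN", "P-EG", "Pintr_D7", "Pintr_P6-8-9")


def inject_current(
    subtype: str,
    amplitudes: np.ndarray | None = None,
    replicates: int = 3,
    seed: int = 0,
):
    """Constant ectopic current into one anatomical subtype (±5 nA span).

    Emulates thermo-/optogenetic drive during the diagnostic program.
    Returns (amplitudes, features, labels) shaped like :func:`sweep_class`.
    """
    neurons = conn.enumerate_neurons()
    if subtype in ("E-PG", "P-EN", "P-EG"):
        # "E-PG" means the 16 non-tip cells, matching the anatomical subtypes
        ids = np.array(
            [n.id for n in neurons if n.neuron_class == subtype and n.subtype == subtype]
        )
    elif subtype in ("E-PG_tip", "Pintr_D7", "Pintr_P6-8-9"):
        ids = conn.subtype_indices(neurons, subtype)
    else:
        raise KeyError(f"unknown subtype {subtype!r}; one of {_SUBTYPE_NAMES}")
    if amplitudes is None:
        amplitudes = np.linspace(-5e-9, 5e-9, 11)
    M = conn.baseline_matrix().M
    feats = np.empty((len(amplitudes), replicates, 12000))
    labels = np.empty((len(amplitudes), replicates), dtype=object)
    for a, amp in enumerate(amplitudes):
        vec = np.zeros(60)
        vec[ids] = amp
        ect = lif.EctopicSchedule(amplitudes=vec)
        for r in range(replicates):
            res = run_diagnostic(M, seed + 1000 * a + r, ectopic=ect)
            feats[a, r] = diagnostic_features(res)
            labels[a, r] = classify_mode(feats[a, r])
    return np.asarray(amplitudes), feats, labels
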