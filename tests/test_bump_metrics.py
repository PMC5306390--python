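"""Bump quantification: convolution, centroid, width, drift, modes, speed."""

import numpy as np
import pytest

from pbring import bump_metrics as bm
from pbring import connectome as conn


def make_trace(t, centroid, valid=None):
    centroid = np.asarray(centroid, dtype=float)
    if valid is None:
        valid = np.isfinite(centroid)
    return bm.BumpTrace(t=np.asarray(t), centroid=centroid, valid=np.asarray(valid))


class TestConvolution:
    def test_empty_raster_is_zero(self):
        cr = bm.convolve_raster([[]] * 60, n_neurons=60, duration=1.0)
        assert cr.signal.shape == (60, 1000)
        assert np.all(cr.signal == 0)

    def test_single_spike_integrates_to_one(self):
        raster = [[] for _ in range(3)]
        raster[1] = [0.5]
        cr = bm.convolve_raster(raster, n_neurons=3, duration=1.0)
        assert cr.signal[1].sum() * cr.grid == pytest.approx(1.0, abs=1e-6)
        assert np.all(cr.signal >= 0)

    def test_two_close_spikes_double_the_peak(self):
        r1 = [[0.5]]
        r2 = [[0.5, 0.501]]
        a = bm.convolve_raster(r1, n_neurons=1, duration=1.0)
        b = bm.convolve_raster(r2, n_neurons=1, duration=1.0)
        # analytically: two unit Gaussians 1 ms apart, sd 24 ms -> peak
        # ratio 2*exp(-0.5*(0.5/24)^2) ~ 1.9996
        assert b.signal[0].max() / a.signal[0].max() == pytest.approx(2.0, rel=1e-3)

    def test_signal_zero_beyond_four_sd(self):
        raster = [[0.5]]
        cr = bm.convolve_raster(raster, n_neurons=1, duration=1.0)
        far = cr.t > 0.5 + 4 * cr.sd + 2 * cr.grid
        assert np.all(cr.signal[0][far] == 0)


class TestCentroid:
    def _raster_for_pens(self, neurons, pen_ids, duration=0.2, rate=200):
        raster = [[] for _ in range(60)]
        times = np.arange(0.0, duration, 1.0 / rate)
        for i in pen_ids:
            raster[i] = times.copy()
        return raster

    def test_single_pen_centroid_is_its_azimuth(self, neurons):
        nrn = next(n for n in neurons if n.neuron_class == "P-EN")
        (g,) = [c.index for c in nrn.dendrite_compartments if c.neuropil == "PB"]
        az = conn.wedge_azimuth(conn.wedge_of_glomerulus(nrn.hemisphere, g))
        cr = bm.convolve_raster(
            self._raster_for_pens(neurons, [nrn.id]), n_neurons=60, duration=0.2
        )
        tr = bm.bump_centroid(cr, neurons)
        mid = tr.valid & (tr.t > 0.05) & (tr.t < 0.15)
        assert np.allclose(tr.centroid[mid], az, atol=1e-6)

    def test_opposite_azimuths_are_degenerate(self, neurons):
        pens = {}
        for n in neurons:
            if n.neuron_class != "P-EN" or n.hemisphere != "R":
                continue
            (g,) = [c.index for c in n.dendrite_compartments if c.neuropil == "PB"]
            az = conn.wedge_azimuth(conn.wedge_of_glomerulus("R", g))
            pens[n.id] = az
        ids = list(pens)
        opp = [
            (a, b)
            for a in ids
            for b in ids
            if abs(abs(bm._wrap(pens[a] - pens[b])) - np.pi) < 1e-9
        ]
        a, b = opp[0]
        cr = bm.convolve_raster(
            self._raster_for_pens(None, [a, b]), n_neurons=60, duration=0.2
        )
        tr = bm.bump_centroid(cr, conn.enumerate_neurons())
        mid = (tr.t > 0.05) & (tr.t < 0.15)
        assert not np.any(tr.valid[mid])

    def test_low_signal_frames_invalid(self, neurons):
        raster = [[] for _ in range(60)]
        raster[20] = list(np.arange(0.0, 0.1, 0.005))  # activity only early
        cr = bm.convolve_raster(raster, n_neurons=60, duration=0.5)
        tr = bm.bump_centroid(cr, neurons)
        assert not np.any(tr.valid[cr.t > 0.3])


class TestWidth:
    def test_delta_profile_width(self, neurons):
        """One active P-EN -> single-glomerulus bump -> 12.5%."""
        raster = [[] for _ in range(60)]
        raster[20] = list(np.arange(0, 0.2, 0.005))
        cr = bm.convolve_raster(raster, n_neurons=60, duration=0.2)
        assert bm.bump_width(cr, neurons, 0.1) == pytest.approx(12.5, abs=0.5)

    def test_two_adjacent_glomeruli_width(self, neurons):
        """A tile-aligned bump spans two glomerulus bins -> 25%."""
        ids = []
        for n in neurons:
            if n.neuron_class != "P-EN":
                continue
            (g,) = [c.index for c in n.dendrite_compartments if c.neuropil == "PB"]
            if (n.hemisphere, g) in (("L", 5), ("R", 4)):
                ids.append(n.id)
        raster = [[] for _ in range(60)]
        for i in ids:
            raster[i] = list(np.arange(0, 0.2, 0.005))
        cr = bm.convolve_raster(raster, n_neurons=60, duration=0.2)
        assert bm.bump_width(cr, neurons, 0.1) == pytest.approx(25.0, abs=1.0)

    def test_uniform_profile_width(self, neurons):
        raster = [[] for _ in range(60)]
        for n in neurons:
            if n.neuron_class == "P-EN":
                raster[n.id] = list(np.arange(0, 0.2, 0.005))
        cr = bm.convolve_raster(raster, n_neurons=60, duration=0.2)
        assert bm.bump_width(cr, neurons, 0.1) == pytest.approx(100.0)

    def test_width_on_invalid_frame_raises(self, neurons):
        cr = bm.convolve_raster([[]] * 60, n_neurons=60, duration=0.2)
        with pytest.raises(ValueError):
            bm.bump_width(cr, neurons, 0.1)


class TestDriftAndSpeed:
    def test_constant_centroid_zero_drift(self):
        t = np.arange(0, 2, 0.001)
        tr = make_trace(t, np.full(t.size, 0.4))
        assert bm.drift_rate(tr) == 0.0

    def test_linear_drift_one_glomerulus_per_second(self):
        t = np.arange(0, 2, 0.001)
        # 1 glomerulus/s = 2*pi/8 rad/s
        tr = make_trace(t, bm._wrap(t * 2 * np.pi / 8))
        assert bm.drift_rate(tr) == pytest.approx(1.0, rel=1e-6)

    def test_speed_categories_recovered(self):
        """A synthetic trace alternating stay / slide / jump phases."""
        dt = 0.001
        seg = 500
        slide_frames = 30  # one wedge over 30 ms: an adjacent-position hop
        c = []
        pos = 0.0
        wedge = 2 * np.pi / 16
        for phase in ("stay", "slide", "stay", "jump", "stay"):
            if phase == "stay":
                c.extend([pos] * seg)
            elif phase == "slide":
                c.extend(pos + wedge * np.linspace(0, 1, slide_frames))
                pos += wedge
            else:
                pos += 3 * wedge
                c.extend([pos] * seg)
        t = np.arange(len(c)) * dt
        tr = make_trace(t, bm._wrap(np.array(c)))
        out = bm.speed_distribution(tr, window=0.02)
        s = out["summary"]
        assert s["stay"]["count"] > s["slide"]["count"] > 0
        assert s["jump"]["count"] > 0
        assert s["stay"]["mean_speed"] < s["slide"]["mean_speed"] < s["jump"]["mean_speed"]


class TestModes:
    def test_single_peak_histogram(self):
        h = np.zeros(96)
        h[40] = 100
        az, occ, spac = bm.position_modes(h)
        assert len(az) == 1 and occ[0] == 1.0

    def test_synthetic_grid_of_modes(self):
        """Fifteen peaks 22.5 degrees apart are all recovered with the
        correct spacing and none at the missing position."""
        edges = np.linspace(-np.pi, np.pi, 97)
        centers = 0.5 * (edges[:-1] + edges[1:])
        h = np.zeros(96)
        mode_az = bm._wrap(np.radians(np.arange(15) * 22.5 - 157.5))
        for a in mode_az:
            h[np.argmin(np.abs(bm._wrap(centers - a)))] += 100
        az, occ, spac = bm.position_modes(h, edges)
        assert len(az) == 15
        interior = spac[spac < 40]
        assert np.median(interior) == pytest.approx(22.5, abs=1.0)

    def test_prominence_floor_drops_noise(self):
        h = np.zeros(96)
        h[10] = 1000
        h[50] = 1000
        h[70] = 1  # below 0.1% of frames? 1/2001 < 0.001 -> dropped
        az, occ, _ = bm.position_modes(h, prominence_floor=0.001)
        assert len(az) == 2


class TestSelectivity:
    def test_fixed_at_cue(self):
        t = np.arange(0, 1, 0.001)
        tr = make_trace(t, np.full(t.size, 1.0))
        idx, sw = bm.selectivity_index(tr, (1.0, -1.0), 0.0, 1.0)
        assert idx == 1.0 and sw == 0

    def test_alternating_every_frame(self):
        t = np.arange(0, 1, 0.001)
        c = np.where(np.arange(t.size) % 2 == 0, 1.0, -1.0)
        tr = make_trace(t, c)
        idx, sw = bm.selectivity_index(tr, (1.0, -1.0), 0.0, 1.0)
        assert idx == pytest.approx(0.5)
        assert sw == 0  # debounce swallows single-frame flips

    def test_debounced_switch_counted(self):
        t = np.arange(0, 1, 0.001)
        c = np.where(t < 0.5, 1.0, -1.0)
        tr = make_trace(t, c)
        idx, sw = bm.selectivity_index(tr, (1.0, -1.0), 0.0, 1.0)
        assert sw == 1


class TestEquivariance:
    def test_rotated_input_rotates_centroid(self, baseline_M, neurons):
        """Feeding the bar one tile over rotates the centroid by 45 deg
        (noise disabled, identical upstream spike pattern)."""
        from pbring import stimuli as stim
        from pbring import lif_engine as lif

        base = stim.single_spike_input(2, 0.02, 0.6)  # E-PG L3, wedge 3, tile 1
        cents = []
        for ch in (2, 3):  # L3 (tile 1) vs L4 (tile 2): one tile apart
            tr = stim.single_spike_input(ch, 0.02, 0.6)
            I = stim.input_current(tr)
            res = lif.simulate(baseline_M, I, noise=False, record=False)
            cr = bm.convolve_raster(res, n_neurons=60, duration=0.6)
            trace = bm.bump_centroid(cr, neurons)
            sel = trace.valid & (trace.t > 0.3)
            cents.append(np.angle(np.mean(np.exp(1j * trace.centroid[sel]))))
        d = np.degrees(abs(bm._wrap(cents[1] - cents[0])))
        assert d == pytest.approx(45.0, abs=12.0)

    def test_mirrored_run_mirrors_centroid(self, baseline_M, neurons):
        from pbring import stimuli as stim
        from pbring import lif_engine as lif

        pi = conn.bilateral_symmetry_map(neurons)
        tr = stim.single_spike_input(4, 0.02, 0.5)
        I = stim.input_current(tr)
        angles = []
        for res in (
            lif.simulate(baseline_M, I, noise=False, record=False),
            lif.simulate(baseline_M, I[pi], noise=False, record=False),
        ):
            cr = bm.convolve_raster(res, n_neurons=60, duration=0.5)
            trace = bm.bump_centroid(cr, neurons)
            sel = trace.valid & (trace.t > 0.25)
            angles.append(np.angle(np.mean(np.exp(1j * trace.centroid[sel]))))
        # the mirror maps wedge w to 15 - w, i.e. azimuth theta to -theta
        assert abs(bm._wrap(angles[1] + angles[0])) < np.radians(12)
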