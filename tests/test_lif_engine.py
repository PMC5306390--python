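"""LIF engine: templates, Euler integration, reproducibility, symmetry."""

import numpy as np
import pytest

from pbring import connectome as conn
from pbring import stimuli as stim
from pbring import lif_engine as lif


@pytest.fixture(scope="module")
def params():
    return lif.NeuronParams()


class TestTemplates:
    def test_ap_endpoint_identities(self, params):
        ap = lif.ap_template(params)
        n = len(ap) - 1
        assert ap[0] == pytest.approx(params.V_thr, abs=1e-12)
        assert ap[n // 2] == pytest.approx(params.V_max, abs=1e-12)
        assert ap[n] == pytest.approx(params.V_min, abs=1e-12)
        assert len(ap) == int(round(params.t_AP / params.dt)) + 1

    def test_ap_rise_is_monotone_then_falls(self, params):
        ap = lif.ap_template(params)
        n = len(ap) - 1
        assert np.all(np.diff(ap[: n // 2 + 1]) > 0)
        assert np.all(np.diff(ap[n // 2 :]) < 0)

    def test_psc_endpoint_identities(self, params):
        psc = lif.psc_template(params)
        k2ms = int(round(0.002 / params.dt))
        assert psc[0] == pytest.approx(0.0, abs=1e-15)
        assert psc[k2ms] == pytest.approx(params.I_PSC)
        assert psc[-1] == pytest.approx(0.0, abs=1e-15)
        # total trace spans 2 ms + 7 half-lives = 37 ms
        assert len(psc) - 1 == int(round((0.002 + 7 * params.t_PSC) / params.dt))

    def test_psc_decay_value_one_half_life_in(self, params):
        # normalized decay at t = 2 ms + t_PSC: (2^-1 - 2^-7) / (1 - 2^-7)
        psc = lif.psc_template(params)
        k = int(round((0.002 + params.t_PSC) / params.dt))
        expected = params.I_PSC * (2**-1 - 2**-7) / (1 - 2**-7)
        assert psc[k] == pytest.approx(expected, rel=1e-9)

    def test_ap_template_rejects_coarse_dt(self, params):
        with pytest.raises(ValueError):
            lif.ap_template(params, dt=params.t_AP / 2)


class TestIntegration:
    def test_leak_relaxation_matches_closed_form(self, params):
        """M = 0, no input/noise: V relaxes to V_0 with tau = R_m C_m."""
        T = 2000
        v0 = params.V_thr - 1e-3
        res = lif.simulate(
            np.zeros((60, 60)), np.zeros((60, T)), noise=False, v_init=v0
        )
        t = np.arange(T) * params.dt
        exact = params.V_0 + (v0 - params.V_0) * np.exp(-t / params.tau_m)
        err = np.abs(res.V[0] - exact).max()
        assert err < 1e-3 * abs(v0 - params.V_0)

    def test_compiled_and_python_paths_identical(self, baseline_M):
        tr = stim.single_spike_input(4, 0.02, 0.2)
        I = stim.input_current(tr)
        a = lif.simulate(baseline_M, I, seed=3, compiled=True)
        b = lif.simulate(baseline_M, I, seed=3, compiled=False)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_seed_reproducibility(self, baseline_M):
        tr = stim.single_spike_input(4, 0.02, 0.2)
        I = stim.input_current(tr)
        a = lif.simulate(baseline_M, I, seed=5)
        b = lif.simulate(baseline_M, I, seed=5)
        c = lif.simulate(baseline_M, I, seed=6)
        assert np.array_equal(a.V, b.V)
        assert not np.array_equal(a.V, c.V)

    def test_euler_convergence_in_spike_times(self, baseline_M):
        """Halving dt moves each spike of a short baseline run by < 1 ms."""
        spikes = {}
        for dt in (1e-4, 5e-5):
            p = lif.NeuronParams(dt=dt)
            tr = stim.single_spike_input(4, 0.02, 0.5)
            I = stim.input_current(tr, p)
            res = lif.simulate(baseline_M, I, p, noise=False)
            spikes[dt] = res.spikes_of(4)
        # the saturated loop's period shifts by O(dt), so timing offsets
        # accumulate linearly; compare the early raster where the bound holds
        n = min(20, len(spikes[1e-4]), len(spikes[5e-5]))
        assert n >= 10
        assert np.all(np.abs(spikes[1e-4][:n] - spikes[5e-5][:n]) < 1e-3)

    def test_voltage_is_template_during_ap(self, params, baseline_M):
        tr = stim.single_spike_input(4, 0.02, 0.2)
        I = stim.input_current(tr)
        res = lif.simulate(baseline_M, I, noise=False)
        ap = lif.ap_template(params)
        k = int(round(res.spikes_of(4)[0] / params.dt))
        assert np.allclose(res.V[4, k : k + len(ap)], ap)

    def test_input_restricted_to_epg_rows(self, baseline_M):
        I = np.zeros((60, 100))
        I[30, 10] = 1e-9  # a P-EN row
        with pytest.raises(ValueError, match="E-PG rows"):
            lif.simulate(baseline_M, I, epg_rows=np.arange(18))

    def test_ectopic_schedule_window(self, params):
        amp = np.zeros(60)
        amp[0] = 2e-9
        ect = lif.EctopicSchedule(amplitudes=amp, t_start=0.01, t_end=0.02)
        arr = ect.render(60, 300, params.dt)
        assert arr[0, 150] == 2e-9 and arr[0, 50] == 0 and arr[0, 250] == 0
        with pytest.raises(ValueError):
            lif.EctopicSchedule(amplitudes=np.full(60, np.nan)).render(60, 10, 1e-4)


class TestCircuitProperties:
    def test_zero_connectivity_control(self):
        """Without synapses, E-PG output follows upstream rate monotonically
        and the downstream classes stay silent."""
        rates = []
        for peak in (20.0, 60.0, 120.0):
            prog = [stim.bar_epoch(0.0, 1.0, conn.tile_azimuth(2), peak_rate=peak)]
            tr = stim.render_program(prog, 1.0, seed=4)
            I = stim.input_current(tr)
            res = lif.simulate(np.zeros((60, 60)), I, seed=4, record=False)
            ch = conn.epg_channels_by_tile(conn.enumerate_neurons())[2]
            rates.append(np.mean([len(res.spikes_of(int(c))) for c in ch]))
            others = np.setdiff1d(np.arange(18, 60), [])
            assert all(len(res.spikes_of(int(i))) == 0 for i in range(18, 60))
        assert rates[0] < rates[1] < rates[2]

    def test_bilateral_equivariance(self, neurons, baseline_M):
        """Mirror the input, disable noise: the raster mirrors exactly."""
        pi = conn.bilateral_symmetry_map(neurons)
        tr = stim.single_spike_input(4, 0.02, 0.3)
        I = stim.input_current(tr)
        I_mirror = I[pi]  # I_mirror[pi[e]] == I[e] would be I[pi] inverse; pi is an involution
        a = lif.simulate(baseline_M, I, noise=False, record=False)
        b = lif.simulate(baseline_M, I_mirror, noise=False, record=False)
        ra = a.raster(60)
        rb = b.raster(60)
        for i in range(60):
            assert np.array_equal(ra[i], rb[pi[i]])

    def test_delta7_pool_synchrony(self, neurons, dark_run):
        """The Δ7 cells, which share identical afferents, fire in near
        coincidence: pairwise nearest-spike lags are far below the chance
        level of a quarter inter-spike interval."""
        import itertools

        raster = dark_run.raster(60)
        d7 = conn.subtype_indices(neurons, "Pintr_D7")

        def nearest_lag(a, b):
            a, b = a[a > 0.5], b[b > 0.5]
            assert len(a) > 10 and len(b) > 10
            idx = np.clip(np.searchsorted(b, a), 1, len(b) - 1)
            return np.median(np.minimum(np.abs(a - b[idx - 1]), np.abs(a - b[idx])))

        lags = [nearest_lag(raster[i], raster[j])
                for i, j in itertools.combinations(d7, 2)]
        isi = np.median(np.diff(raster[d7[0]]))
        assert np.median(lags) < isi / 4

    def test_nonfinite_voltage_raises(self):
        p = lif.NeuronParams()
        I = np.zeros((60, 100))
        I[0, 10] = np.nan  # corrupted input current
        with pytest.raises(FloatingPointError):
            with np.errstate(all="ignore"):
                lif.simulate(np.zeros((60, 60)), I, p, noise=False)


def test_neuron_params_validation():
    with pytest.raises(ValueError):
        lif.NeuronParams(V_thr=-0.08)  # below rest
    with pytest.raises(ValueError):
        lif.NeuronParams(dt=0.005)  # dt > t_AP
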