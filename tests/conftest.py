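import numpy as np
import pytest

from pbring import connectome as conn
from pbring import stimuli as stim
from pbring import lif_engine as lif
from pbring import bump_metrics as bm


@pytest.fixture(scope="session")
def neurons():
    return conn.enumerate_neurons()


@pytest.fixture(scope="session")
def adjacency(neurons):
    return conn.infer_synapses(neurons)


@pytest.fixture(scope="session")
def baseline_cm(neurons, adjacency):
    adj, lab = adjacency
    return conn.build_matrix(adj, lab, neurons=neurons)


@pytest.fixture(scope="session")
def baseline_M(baseline_cm):
    return baseline_cm.M


def simulate_dark(M, seed, duration=4.0, bar=None, record=False):
    """Dark run (5 Hz background only), optionally bar-ignited."""
    prog = []
    if bar is not None:
        prog = [stim.bar_epoch(0.0, bar, conn.tile_azimuth(seed % 8))]
    trains = stim.render_program(prog, duration, seed)
    I = stim.input_current(trains)
    return lif.simulate(M, I, duration=duration, seed=seed, record=record)


@pytest.fixture(scope="session")
def dark_run(baseline_M):
    """One 4 s baseline dark run shared across metric tests."""
    return simulate_dark(baseline_M, seed=11, duration=4.0)


@pytest.fixture(scope="session")
def dark_trace(dark_run, neurons):
    cr = bm.convolve_raster(dark_run, n_neurons=60, duration=4.0)
    return cr, bm.bump_centroid(cr, neurons)


@pytest.fixture(scope="session")
def dark_ensemble(baseline_M, neurons):
    """Centroid traces + widths from a small ensemble of 4 s dark runs."""
    traces, widths = [], []
    for seed in range(20):
        res = simulate_dark(baseline_M, seed=seed, duration=4.0)
        cr = bm.convolve_raster(res, n_neurons=60, duration=4.0)
        traces.append(bm.bump_centroid(cr, neurons))
        widths.append(bm.width_trace(cr, neurons))
    return traces, widths
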