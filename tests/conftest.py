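import numpy as np
import pytest

from featloop import synth
from featloop.data_model import NeuronRecord, SessionBundle, TrialRecord


@pytest.fixture(scope="session")
def small_cfg():
    return synth.SynthConfig(
        n_pc=240, n_sst=40, n_pv=20, n_trials_per_orientation=20, seed=1
    )


@pytest.fixture(scope="session")
def small_population(small_cfg):
    return synth.generate_population(small_cfg)


@pytest.fixture(scope="session")
def ensembled_population(small_cfg, small_population):
    neurons, gt = small_population
    specs = [(1, 0.0), (2, 45.0), (2, 90.0), (10, 90.0), (15, 0.0), (25, 135.0)]
    neurons, ensembles = synth.make_cotuned_ensembles(neurons, gt, specs, seed=1)
    return neurons, gt, ensembles


@pytest.fixture(scope="session")
def visual_session(small_cfg, ensembled_population):
    neurons, gt, _ = ensembled_population
    return synth.simulate_visual_trials(neurons, gt, small_cfg)


@pytest.fixture(scope="session")
def photostim_session(small_cfg, ensembled_population):
    neurons, gt, ensembles = ensembled_population
    kernels = {
        "PC": synth.pc_size_dependent_kernel,
        "SST": synth.sst_recruitment_kernel(),
        "PV": synth.pv_suppression_kernel(),
    }
    return synth.simulate_photostim_trials(
        neurons, gt, ensembles, kernels, small_cfg, n_trials_per_ensemble=10
    )


def tiny_bundle(n_trials=4, n_neurons=3, seed=0, with_traces=False):
    rng = np.random.default_rng(seed)
    neurons = [
        NeuronRecord(neuron_id=j, cell_type="PC", centroid=tuple(rng.uniform(0, 100, 3)))
        for j in range(n_neurons)
    ]
    trials = [
        TrialRecord(trial_id=i, vis_orientation=[0.0, 45.0, 90.0, 135.0][i % 4])
        for i in range(n_trials)
    ]
    traces = rng.normal(size=(n_trials, n_neurons, 10)) if with_traces else None
    return SessionBundle(
        responses=rng.normal(size=(n_trials, n_neurons)),
        neurons=neurons,
        trials=trials,
        traces=traces,
        frame_rate=6.0,
    )
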