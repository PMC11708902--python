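import numpy as np
import pytest

from neurocode import synthio
from neurocode.containers import Ensemble


@pytest.fixture
def small_ensemble():
    """Noisy 6-stimulus ensemble with near-orthogonal templates."""
    return synthio.make_noisy_ensemble(
        n_neurons=80, n_bins=10, true_corr=0.0, noise_sd=0.5,
        n_trials=10, n_sessions=2, n_stimuli=6, seed=7)


@pytest.fixture
def noise_free_ensemble():
    return synthio.make_noisy_ensemble(
        n_neurons=60, n_bins=8, true_corr=0.2, noise_sd=0.0,
        n_trials=6, n_stimuli=5, seed=11)


def make_rate_matched_pair(n_neurons=40, n_bins=10, noise_sd=0.05, seed=0):
    """Two stimuli related by a common time-bin permutation: identical
    per-neuron time averages (no spatial information), distinct
    spatiotemporal structure."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.5, 1.5, (n_neurons, n_bins))
    perm = rng.permutation(n_bins)
    templates = np.stack([base, base[:, perm]])
    n_trials = 10
    trials = np.repeat(templates, n_trials, axis=0)
    trials = trials + noise_sd * rng.standard_normal(trials.shape)
    return Ensemble(trials, np.repeat([0, 1], n_trials),
                    np.zeros(2 * n_trials, dtype=int), seed=seed)
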