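"""Nearest-neighbor population decoding across timescales.

Stimulus identity is decoded by correlating half-split trial averages:
for each stimulus the trials of every unit are split at random into a
train half and a test half, and each test-half average is assigned the
stimulus whose train-half average correlates best (Pearson).  Features
are either the full spatiotemporal response (N*K entries) or the
time-averaged spatial pattern (N entries).

Temporal information can be restricted to chosen timescales by
decomposing each neuron's response into discrete Fourier coefficients
for frequencies n/T (n = 0 .. K/2, the Nyquist limit) and decoding from
single bands or cumulative band prefixes.  The n = 0 (DC) band is stored
as the plain time average, so band-0 decoding is *identical* to spatial
decoding by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .containers import Ensemble

log = logging.getLogger(__name__)

__all__ = [
    "split_half", "nn_decode", "DecodeResult", "decode_ensemble",
    "fourier_features", "fourier_grid", "nyquist_bands",
    "decode_by_timescale",
]


def split_half(ensemble: Ensemble, seed: int | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-stimulus, per-unit random half split of trials.

    Returns ``(train_avg, test_avg)`` of shape ``(S, N, K)``: trial
    averages of disjoint, exhaustive halves, with the split drawn
    independently for every unit.  For odd trial counts the extra trial
    goes to the train half.
    """
    rng = np.random.default_rng(seed)
    stimuli = ensemble.stimuli
    S, N, K = len(stimuli), ensemble.n_neurons, ensemble.n_bins
    train = np.empty((S, N, K))
    test = np.empty((S, N, K))
    for si, s in enumerate(stimuli):
        trials = ensemble.trials_for(s)            # (R, N, K)
        R = trials.shape[0]
        if R < 2:
            raise ValueError(f"stimulus {s!r} has fewer than 2 trials")
        n_test = R // 2
        for n in range(N):
            perm = rng.permutation(R)
            test[si, n] = trials[perm[:n_test], n, :].mean(axis=0)
            train[si, n] = trials[perm[n_test:], n, :].mean(axis=0)
    return train, test


@dataclass
class DecodeResult:
    """Decoding outcome: accuracy, confusion counts, and provenance."""

    accuracy: float
    confusion: np.ndarray
    mode: str
    timescale_spec: str = "full"
    split_seed: int | None = None
    n_ties: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"accuracy": self.accuracy, "mode": self.mode,
                       "timescale_spec": self.timescale_spec,
                       "split_seed": self.split_seed,
                       "n_ties": self.n_ties}, f, indent=2)


def _featurize_avg(avg: np.ndarray, mode: str) -> np.ndarray:
    if mode == "spatial":
        return avg.mean(axis=2)
    if mode == "spatiotemporal":
        return avg.reshape(avg.shape[0], -1)
    raise ValueError("mode must be 'spatial' or 'spatiotemporal'")


def _corr_rows(test: np.ndarray, train: np.ndarray) -> np.ndarray:
    a = test - test.mean(axis=1, keepdims=True)
    b = train - train.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (a / na[:, None]) @ (b / nb[:, None]).T


def nn_decode(train_features: np.ndarray, test_features: np.ndarray,
              mode: str = "spatiotemporal",
              featurized: bool = False) -> DecodeResult:
    """Nearest-neighbor (template-matching) decoder.

    ``train_features`` / ``test_features`` are per-stimulus averages,
    either raw ``(S, N, K)`` tensors (featurized here according to
    ``mode``) or already-featurized ``(S, D)`` matrices
    (``featurized=True``).  Each test row is assigned the train stimulus
    with maximal Pearson correlation; exact ties go to the lowest
    stimulus index (counted and logged).
    """
    if not featurized:
        train_features = _featurize_avg(np.asarray(train_features), mode)
        test_features = _featurize_avg(np.asarray(test_features), mode)
    S = train_features.shape[0]
    if test_features.shape[0] != S:
        raise ValueError("train and test must cover the same stimulus set")
    c = _corr_rows(test_features, train_features)
    pred = np.argmax(c, axis=1)                    # argmax takes lowest index
    n_ties = int(sum((row == row[p]).sum() > 1 for row, p in zip(c, pred)))
    if n_ties:
        log.warning("%d decoding ties broken toward the lowest index", n_ties)
    confusion = np.zeros((S, S), dtype=int)
    for true, p in enumerate(pred):
        confusion[true, p] += 1
    acc = float(np.trace(confusion) / confusion.sum())
    return DecodeResult(accuracy=acc, confusion=confusion, mode=mode,
                        n_ties=n_ties)


def decode_ensemble(ensemble: Ensemble, mode: str = "spatiotemporal",
                    seed: int | None = None) -> DecodeResult:
    """Half-split nearest-neighbor decoding of an ensemble."""
    train, test = split_half(ensemble, seed)
    res = nn_decode(train, test, mode)
    res.split_seed = seed
    return res


# --------------------------------------------------------------------------
# Fourier timescale decomposition
# --------------------------------------------------------------------------

def fourier_grid(T_ms: float = 750.0, dt_ms: float | None = None,
                 n_bins: int | None = None) -> dict:
    """Consistent time/frequency grid for the response window.

    Given the window length ``T_ms`` and either the bin width or the bin
    count, returns ``{'dt_ms', 'n_bins', 'K', 'nyquist_hz'}`` where
    ``K = n_bins / 2 = T * f`` counts the resolvable frequencies up to
    the Nyquist frequency ``f = 1 / (2 dt)``.
    """
    if (dt_ms is None) == (n_bins is None):
        raise ValueError("give exactly one of dt_ms or n_bins")
    if n_bins is None:
        n_bins_f = T_ms / dt_ms
        n_bins = int(round(n_bins_f))
        if abs(n_bins_f - n_bins) > 1e-9:
            raise ValueError("bin width must divide the window evenly")
    dt_ms = T_ms / n_bins
    return {"dt_ms": dt_ms, "n_bins": n_bins, "K": n_bins // 2,
            "nyquist_hz": 1000.0 / (2.0 * dt_ms)}


def nyquist_bands(n_bins: int) -> int:
    """Highest usable band index: K/2 time bins resolve frequencies up to
    the Nyquist frequency 1/(2*dt)."""
    return n_bins // 2


def fourier_features(avg: np.ndarray, bands) -> np.ndarray:
    """Per-band Fourier features of trial-averaged responses ``(S, N, K)``.

    For band ``n >= 1`` the feature block holds the real and imaginary
    parts of ``C_n = sum_k v(k) exp(-2i pi k n / K)`` for every neuron
    (2N entries).  Band 0 is stored as the time average itself (N
    entries; the DC coefficient is real and proportional to it), which
    makes band-0 decoding coincide exactly with spatial decoding.
    Requested bands beyond the Nyquist limit are rejected.  Passing a
    list of bands concatenates the blocks (cumulative featurization).
    """
    avg = np.asarray(avg, dtype=float)
    S, N, K = avg.shape
    bands = np.atleast_1d(bands)
    n_max = nyquist_bands(K)
    if np.any(bands < 0) or np.any(bands > n_max):
        raise ValueError(f"bands must lie in [0, {n_max}] for K={K} bins")
    blocks = []
    for n in bands:
        if n == 0:
            blocks.append(avg.mean(axis=2))        # same code path as spatial
            continue
        phase = np.exp(-2j * np.pi * np.arange(K) * n / K)
        C = avg @ phase                            # (S, N) complex
        blocks.append(np.concatenate([C.real, C.imag], axis=1))
    return np.concatenate(blocks, axis=1)


def decode_by_timescale(ensemble: Ensemble, mode: str = "per_band",
                        n_max: int | None = None,
                        seeds=(0,)) -> dict:
    """Decoding accuracy as a function of timescale.

    ``mode='per_band'`` decodes from single Fourier bands n = 0..n_max;
    ``mode='cumulative'`` decodes from the concatenated bands 0..n for
    each n.  Accuracies are averaged over the half-split ``seeds``.
    Returns ``{'bands': ..., 'accuracy': ..., 'per_seed': ...}``.
    """
    if mode not in ("per_band", "cumulative"):
        raise ValueError("mode must be 'per_band' or 'cumulative'")
    K = ensemble.n_bins
    if n_max is None:
        n_max = nyquist_bands(K)
    if n_max > nyquist_bands(K):
        raise ValueError(f"n_max beyond the Nyquist band {nyquist_bands(K)}")
    bands = np.arange(n_max + 1)
    acc = np.zeros((len(seeds), len(bands)))
    for i, seed in enumerate(seeds):
        train, test = split_half(ensemble, seed)
        for j, n in enumerate(bands):
            sel = [n] if mode == "per_band" else list(range(n + 1))
            ftr = fourier_features(train, sel)
            fte = fourier_features(test, sel)
            acc[i, j] = nn_decode(ftr, fte, mode="fourier",
                                  featurized=True).accuracy
    return {"bands": bands, "accuracy": acc.mean(axis=0),
            "per_seed": acc, "seeds": list(seeds), "mode": mode}
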