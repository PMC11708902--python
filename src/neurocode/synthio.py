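"""Synthetic inputs for the population-coding pipeline.

Generators for optogenetic-style pulse-train stimuli, presentation
schedules, artificial Go/NoGo population patterns with independently
controlled similarity axes, noisy trial ensembles with known ground-truth
correlation, and raw fluorescence traces with slow calcium decay.

Every generator is a pure function of its parameters and seed: identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .containers import Ensemble

log = logging.getLogger(__name__)

__all__ = [
    "StimulusPattern",
    "ArtificialPatternPair",
    "make_opto_patterns",
    "OPTO_PROTOCOLS",
    "schedule_protocol",
    "make_pattern_pair",
    "pattern_metrics",
    "make_correlated_templates",
    "make_noisy_ensemble",
    "make_fluorescence",
]


# --------------------------------------------------------------------------
# Optogenetic-style pulse trains
# --------------------------------------------------------------------------

@dataclass
class StimulusPattern:
    """A binary light/drive waveform on one or more channels.

    ``pulses`` maps a channel name to a list of ``(onset_ms, offset_ms)``
    pairs.  Pulses are non-overlapping within a channel and lie within
    ``[0, duration_ms]``.
    """

    name: str
    duration_ms: float
    pulses: dict[str, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        for ch, pl in self.pulses.items():
            last_off = -1.0
            for on, off in pl:
                if not (0.0 <= on < off <= self.duration_ms + 1e-9):
                    raise ValueError(
                        f"pulse ({on}, {off}) on channel {ch!r} outside "
                        f"[0, {self.duration_ms}] or offset <= onset"
                    )
                if on < last_off - 1e-9:
                    raise ValueError(f"overlapping pulses on channel {ch!r}")
                last_off = off

    @property
    def channels(self) -> list[str]:
        return list(self.pulses)

    def total_on_ms(self, channel: str | None = None) -> float:
        chans = [channel] if channel is not None else self.channels
        return float(sum(off - on for ch in chans for on, off in self.pulses[ch]))

    def waveform(self, dt_ms: float, channel: str | None = None) -> np.ndarray:
        """Binary ON/OFF waveform sampled at ``dt_ms``."""
        n = int(round(self.duration_ms / dt_ms))
        t = (np.arange(n) + 0.5) * dt_ms
        chans = [channel] if channel is not None else self.channels
        w = np.zeros(n)
        for ch in chans:
            for on, off in self.pulses[ch]:
                w[(t >= on) & (t < off)] = 1.0
        return w

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {"name": self.name, "duration_ms": self.duration_ms,
                 "pulses": self.pulses}, f, indent=2)


def _train(n_pulses: int, on_tenths: int, off_tenths: int,
           start_tenths: int = 0) -> list[tuple[float, float]]:
    # build in integer tenths of ms so 49.8/16.6 accumulate without drift
    pulses = []
    t = Fraction(start_tenths, 10)
    on = Fraction(on_tenths, 10)
    off = Fraction(off_tenths, 10)
    for _ in range(n_pulses):
        pulses.append((float(t), float(t + on)))
        t += on + off
    return pulses


def _two_spot(first: str, second: str) -> dict[str, list[tuple[float, float]]]:
    # each spot: 250 ms at 20 Hz (25 ms ON / 25 ms OFF), onset delay 250 ms
    return {
        first: _train(5, 250, 250, start_tenths=0),
        second: _train(5, 250, 250, start_tenths=2500),
    }


OPTO_PROTOCOLS = ("15hz_high", "4hz_high", "4hz_low", "A", "B", "AB", "BA")


def make_opto_patterns(protocol_id: str) -> StimulusPattern:
    """Build one of the calibrated optogenetic stimulation patterns.

    Single-spot temporal-modulation protocols over 600 ms:

    - ``15hz_high`` : 9 pulses, 49.8 ms ON / 16.6 ms OFF
    - ``4hz_high``  : 3 pulses, 149.4 ms ON / 99.6 ms OFF  (same total ON
      time as ``15hz_high``, so the two differ only temporally)
    - ``4hz_low``   : 3 pulses, 16.6 ms ON / 233.2 ms OFF  (low rate)

    Two-spot relative-timing protocols (each spot driven at 20 Hz, 25 ms
    ON / 25 ms OFF):

    - ``A`` / ``B`` : a single spot for 500 ms (purely spatial contrast)
    - ``AB`` / ``BA``: both spots for 250 ms each, 250-ms onset delay, in
      the stated order (purely temporal contrast: the per-channel pulse
      multisets are identical).
    """
    if protocol_id not in OPTO_PROTOCOLS:
        raise ValueError(
            f"unknown protocol {protocol_id!r}; valid ids: {OPTO_PROTOCOLS}")
    # single-spot epochs are nominally 600 ms; the 4 Hz high-rate train's
    # third pulse ends at 647.4 ms, so each pattern's duration is the
    # full span of its pulse train
    if protocol_id == "15hz_high":
        return StimulusPattern("15hz_high", 600.0,
                               {"spot": _train(9, 498, 166)})
    if protocol_id == "4hz_high":
        return StimulusPattern("4hz_high", 647.4,
                               {"spot": _train(3, 1494, 996)})
    if protocol_id == "4hz_low":
        return StimulusPattern("4hz_low", 600.0,
                               {"spot": _train(3, 166, 2332)})
    if protocol_id == "A":
        return StimulusPattern("A", 500.0, {"A": _train(10, 250, 250)})
    if protocol_id == "B":
        return StimulusPattern("B", 500.0, {"B": _train(10, 250, 250)})
    if protocol_id == "AB":
        return StimulusPattern("AB", 500.0, _two_spot("A", "B"))
    return StimulusPattern("BA", 500.0, _two_spot("B", "A"))


# --------------------------------------------------------------------------
# Presentation schedules
# --------------------------------------------------------------------------

def schedule_protocol(n_sounds: int, n_reps: int, block_s: float,
                      pause_s: float, n_blocks: int,
                      seed: int | None = 0,
                      max_per_block: int | None = None
                      ) -> tuple[pd.DataFrame, float]:
    """Randomized presentation schedule split into fixed-length blocks.

    Each of ``n_sounds`` stimuli appears exactly ``n_reps`` times in a
    random order; presentations are dealt into ``n_blocks`` blocks of
    ``block_s`` seconds, each followed by a ``pause_s``-second pause
    (one pause per block).  ``max_per_block`` optionally caps the block
    capacity; the schedule is rejected when presentations do not fit.

    Returns ``(schedule, total_duration_s)`` where ``schedule`` has one
    row per presentation with columns ``presentation, sound, block``.
    """
    for name, v in [("n_sounds", n_sounds), ("n_reps", n_reps),
                    ("block_s", block_s), ("pause_s", pause_s),
                    ("n_blocks", n_blocks)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    n_pres = n_sounds * n_reps
    per_block = int(np.ceil(n_pres / n_blocks))
    if max_per_block is not None and per_block > max_per_block:
        raise ValueError(
            f"{n_pres} presentations do not fit in {n_blocks} blocks of "
            f"at most {max_per_block} presentations each")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.arange(n_sounds), n_reps))
    # deal as evenly as possible: first blocks take the extra presentation
    base, extra = divmod(n_pres, n_blocks)
    sizes = [base + (1 if b < extra else 0) for b in range(n_blocks)]
    blocks = np.repeat(np.arange(n_blocks), sizes)
    schedule = pd.DataFrame({
        "presentation": np.arange(n_pres),
        "sound": order,
        "block": blocks,
    })
    total = n_blocks * (block_s + pause_s)
    return schedule, float(total)


# --------------------------------------------------------------------------
# Artificial Go/NoGo pattern pairs
# --------------------------------------------------------------------------

@dataclass
class ArtificialPatternPair:
    """A Go/NoGo pair of nonnegative ``(neurons, time_bins)`` activity
    matrices plus the requested manipulation levels."""

    X_go: np.ndarray
    X_nogo: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X_go = np.asarray(self.X_go, dtype=float)
        self.X_nogo = np.asarray(self.X_nogo, dtype=float)
        if self.X_go.shape != self.X_nogo.shape:
            raise ValueError("pattern pair must share shape")
        if (self.X_go < 0).any() or (self.X_nogo < 0).any():
            raise ValueError("activity must be nonnegative")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.ravel(a) - np.mean(a)
    b = np.ravel(b) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def pattern_metrics(X1: np.ndarray, X2: np.ndarray) -> dict:
    """Realized similarity axes between two patterns.

    - ``spatial``: Pearson correlation of per-neuron time averages
    - ``spatiotemporal``: Pearson correlation of the flattened matrices
    - ``gad``: global activity difference |m1 - m2| / (m1 + m2)
    """
    from .rlmodel import gad  # single definition of GAD lives there
    return {
        "spatial": _pearson(X1.mean(axis=1), X2.mean(axis=1)),
        "spatiotemporal": _pearson(X1, X2),
        "gad": gad(float(X1.mean()), float(X2.mean())),
    }


def make_pattern_pair(n_neurons: int = 1000, n_bins: int = 25,
                      frac_shuffled: float = 0.0,
                      frac_resampled: float = 0.0,
                      activity_offset: float = 0.0,
                      seed: int | None = None,
                      uniform_range: tuple[float, float] = (0.0, 1.0),
                      gain_range: tuple[float, float] = (0.5, 2.0),
                      ) -> ArtificialPatternPair:
    """Artificial pattern pair with independently controlled similarity axes.

    The seed (Go) pattern draws each neuron's activity at each time bin
    uniformly and multiplies it by a per-neuron gain.  The NoGo pattern is
    derived from it by three independent manipulations:

    - shuffling the order of time bins in ``floor(frac_shuffled * N)``
      neurons (lowers spatiotemporal similarity; preserves per-neuron
      means, hence spatial similarity and overall rate);
    - resampling the activity level (new draws and new gain) in
      ``floor(frac_resampled * N)`` neurons (lowers spatial similarity);
    - adding ``activity_offset`` to every entry (sets the global activity
      difference).

    Negative activities after a negative offset are clipped at 0 (logged).
    """
    for name, frac in [("frac_shuffled", frac_shuffled),
                       ("frac_resampled", frac_resampled)]:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = uniform_range
    gains = rng.uniform(*gain_range, size=n_neurons)
    X_go = rng.uniform(lo, hi, size=(n_neurons, n_bins)) * gains[:, None]
    X_nogo = X_go.copy()

    n_shuf = int(np.floor(frac_shuffled * n_neurons))
    shuf_idx = rng.choice(n_neurons, size=n_shuf, replace=False)
    for i in shuf_idx:
        X_nogo[i] = X_nogo[i, rng.permutation(n_bins)]

    n_res = int(np.floor(frac_resampled * n_neurons))
    res_idx = rng.choice(n_neurons, size=n_res, replace=False)
    new_gains = rng.uniform(*gain_range, size=n_res)
    X_nogo[res_idx] = (rng.uniform(lo, hi, size=(n_res, n_bins))
                       * new_gains[:, None])

    X_nogo = X_nogo + activity_offset
    n_neg = int((X_nogo < 0).sum())
    if n_neg:
        log.warning("clipped %d negative activities at 0 after offset", n_neg)
        X_nogo = np.clip(X_nogo, 0.0, None)

    pair = ArtificialPatternPair(
        X_go, X_nogo,
        meta={"frac_shuffled": frac_shuffled, "frac_resampled": frac_resampled,
              "activity_offset": activity_offset, "seed": seed})
    pair.meta["realized"] = pattern_metrics(X_go, X_nogo)
    return pair


# --------------------------------------------------------------------------
# Noisy trial ensembles with known ground-truth correlation
# --------------------------------------------------------------------------

def make_correlated_templates(n_stimuli: int, n_neurons: int, n_bins: int,
                              true_corr: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Noise-free templates with exact pairwise Pearson correlation.

    Independent standard-normal draws are orthonormalized (Gram-Schmidt
    after centering) and mixed with the Cholesky factor of the
    equicorrelation matrix, so every pair of templates has correlation
    ``true_corr`` up to floating-point error (< 1e-6).  Templates are
    standardized to zero mean and unit SD, so downstream noise scales are
    in units of the signal SD.
    """
    if not -1.0 < true_corr < 1.0:
        raise ValueError("true_corr must lie in the open interval (-1, 1)")
    d = n_neurons * n_bins
    if n_stimuli > d:
        raise ValueError("need n_neurons * n_bins >= n_stimuli")
    raw = rng.standard_normal((n_stimuli, d))
    raw -= raw.mean(axis=1, keepdims=True)
    # centered Gram-Schmidt: orthogonal directions in the centered subspace
    basis = np.empty_like(raw)
    for i in range(n_stimuli):
        v = raw[i]
        for j in range(i):
            v = v - (v @ basis[j]) * basis[j]
        v -= v.mean()
        basis[i] = v / np.linalg.norm(v)
    corr = np.full((n_stimuli, n_stimuli), true_corr)
    np.fill_diagonal(corr, 1.0)
    mixed = np.linalg.cholesky(corr) @ basis
    mixed /= mixed.std(axis=1, keepdims=True)
    return mixed.reshape(n_stimuli, n_neurons, n_bins)


def make_noisy_ensemble(n_neurons: int = 2000, n_bins: int = 1,
                        true_corr: float = 0.5, noise_sd: float = 1.0,
                        n_trials: int = 15, n_sessions: int = 1,
                        n_stimuli: int = 2,
                        seed: int | None = None) -> Ensemble:
    """Trial ensemble around templates with known pairwise correlation.

    Each trial is ``template + independent zero-mean Gaussian noise`` of
    SD ``noise_sd`` (in units of the unit template SD).  Session labels
    partition the trials of each stimulus evenly.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials per stimulus")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    templates = make_correlated_templates(
        n_stimuli, n_neurons, n_bins, true_corr, rng)
    trials = np.repeat(templates, n_trials, axis=0)
    trials = trials + noise_sd * rng.standard_normal(trials.shape)
    stim = np.repeat(np.arange(n_stimuli), n_trials)
    per_stim_sessions = np.floor(
        np.arange(n_trials) * n_sessions / n_trials).astype(int)
    sessions = np.tile(per_stim_sessions, n_stimuli)
    true = np.full((n_stimuli, n_stimuli), true_corr)
    np.fill_diagonal(true, 1.0)
    return Ensemble(
        values=trials, stimulus_labels=stim, session_labels=sessions,
        truth={"templates": templates, "correlations": true}, seed=seed)


# --------------------------------------------------------------------------
# Raw fluorescence forward model
# --------------------------------------------------------------------------

def make_fluorescence(rate_trace: np.ndarray, dt_s: float,
                      tau_decay_s: float = 2.0, baseline: float = 1.0,
                      neuropil_gain: float = 0.7, noise_sd: float = 0.0,
                      seed: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Forward model for raw calcium fluorescence.

    ``F = rate * exp(-t/tau) + baseline + neuropil_gain * F_np + noise``;
    the neuropil trace ``F_np`` is slow filtered noise around its own
    baseline.  Inverted downstream by ``preprocess.neuropil_correct`` /
    ``preprocess.dff`` / ``preprocess.deconvolve``.
    """
    if tau_decay_s <= 0:
        raise ValueError("tau_decay_s must be positive")
    rate_trace = np.asarray(rate_trace, dtype=float)
    rng = np.random.default_rng(seed)
    t = np.arange(len(rate_trace)) * dt_s
    kernel = np.exp(-t / tau_decay_s) * dt_s
    calcium = np.convolve(rate_trace, kernel)[: len(rate_trace)]
    from scipy.ndimage import gaussian_filter1d
    if noise_sd > 0:
        slow = gaussian_filter1d(rng.standard_normal(len(rate_trace)),
                                 sigma=max(1.0, 1.0 / dt_s))
        F_np = baseline + 0.1 * noise_sd * slow
    else:
        F_np = np.full(len(rate_trace), baseline)
    F = (calcium + baseline + neuropil_gain * F_np
         + noise_sd * rng.standard_normal(len(rate_trace)))
    return F, F_np
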