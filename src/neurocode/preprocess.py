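"""Raw-trace preprocessing and response screening.

Turns raw fluorescence traces into deconvolved, filtered rate estimates,
screens neurons by inter-trial reproducibility, and provides the
cluster-based dimensionality reduction applied before model fitting.

The fluorescence chain inverts the forward model in
:mod:`neurocode.synthio`: neuropil subtraction, sliding-percentile
baseline for dF/F, then the linear deconvolution
``r(t) = f'(t) + f(t)/tau`` followed by Gaussian smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d, percentile_filter

from .containers import Ensemble

log = logging.getLogger(__name__)

__all__ = [
    "neuropil_correct", "dff", "deconvolve",
    "ReproReport", "reproducibility", "cluster_reduce",
]


def neuropil_correct(F: np.ndarray, F_np: np.ndarray,
                     gain: float = 0.7) -> np.ndarray:
    """Subtract a fraction (default 70%) of the neuropil signal."""
    F = np.asarray(F, dtype=float)
    F_np = np.asarray(F_np, dtype=float)
    if F.shape != F_np.shape:
        raise ValueError("fluorescence and neuropil traces must share shape")
    return F - gain * F_np


def dff(F: np.ndarray, dt_s: float, percentile: float = 3.0,
        window_s: float = 60.0, baseline_smooth_s: float = 1.0) -> np.ndarray:
    """Fractional fluorescence change ``f = (F - F0) / F0``.

    The baseline ``F0`` is the sliding-window 3rd percentile of a
    Gaussian-filtered copy of the trace.  Window length (60 s) and the
    1-s pre-filter SD are configurable defaults.  Constant traces map to
    exactly zero.
    """
    F = np.asarray(F, dtype=float)
    smooth = gaussian_filter1d(F, sigma=max(baseline_smooth_s / dt_s, 1e-9))
    size = max(3, int(round(window_s / dt_s)) | 1)  # odd window
    F0 = percentile_filter(smooth, percentile, size=size, mode="nearest")
    if np.any(F0 <= 0):
        bad = int(np.argmax(F0 <= 0))
        raise ValueError(
            f"nonpositive baseline F0 at sample {bad}; "
            "fluorescence must stay positive for dF/F")
    return (F - F0) / F0


def deconvolve(f: np.ndarray, dt_s: float, tau_s: float = 2.0,
               smooth_sd_ms: float = 31.0) -> np.ndarray:
    """Linear deconvolution ``r(t) = f'(t) + f(t)/tau``, then Gaussian
    smoothing (sigma 31 ms, kernel truncated at 4 sigma, unit sum).

    The derivative uses central differences (one-sided at the edges).
    The operator is linear to numerical precision.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    f = np.asarray(f, dtype=float)
    r = np.gradient(f, dt_s) + f / tau_s
    sigma = smooth_sd_ms / 1000.0 / dt_s
    if sigma > 0:
        r = gaussian_filter1d(r, sigma=sigma, truncate=4.0, mode="nearest")
    return r


# --------------------------------------------------------------------------
# Reproducibility screening
# --------------------------------------------------------------------------

@dataclass
class ReproReport:
    """Inter-trial reproducibility indices and the resulting keep mask."""

    per_neuron_index: np.ndarray
    per_stimulus_index: np.ndarray
    kept_mask: np.ndarray
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": np.arange(len(self.per_neuron_index)),
            "index": self.per_neuron_index,
            "kept": self.kept_mask,
        })


def _mean_pairwise_corr(rows: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered row pairs; rows with
    zero variance yield undefined pairs, which are dropped."""
    rows = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    ok = norms > 0
    if ok.sum() < 2:
        return np.nan
    z = rows[ok] / norms[ok, None]
    c = z @ z.T
    iu = np.triu_indices(len(z), k=1)
    return float(c[iu].mean())


def reproducibility(ensemble: Ensemble, threshold: float = 0.12) -> ReproReport:
    """Inter-trial reproducibility of single neurons and the population.

    Per neuron: the inter-trial correlation of that neuron's temporal
    response, averaged over all trial pairs and all stimuli (pairs with
    zero variance are undefined and excluded from the mean; a neuron with
    no defined pair gets index 0, logged).  Per stimulus: the mean
    pairwise inter-trial correlation of the full concatenated population
    sequence.  ``kept_mask`` keeps neurons with index >= ``threshold``.
    """
    stimuli = ensemble.stimuli
    n_neurons = ensemble.n_neurons
    per_neuron = np.full((len(stimuli), n_neurons), np.nan)
    per_stim = np.full(len(stimuli), np.nan)
    for si, s in enumerate(stimuli):
        trials = ensemble.trials_for(s)           # (R, N, K)
        if trials.shape[0] < 2:
            raise ValueError(f"stimulus {s!r} has fewer than 2 trials")
        for n in range(n_neurons):
            per_neuron[si, n] = _mean_pairwise_corr(trials[:, n, :])
        flat = trials.reshape(trials.shape[0], -1)
        per_stim[si] = _mean_pairwise_corr(flat)
    with np.errstate(invalid="ignore"):
        idx = np.nanmean(per_neuron, axis=0)
    n_undef = int(np.isnan(idx).sum())
    if n_undef:
        log.warning("%d neurons had no defined trial pair; index set to 0",
                    n_undef)
        idx = np.nan_to_num(idx, nan=0.0)
    return ReproReport(per_neuron_index=idx, per_stimulus_index=per_stim,
                       kept_mask=idx >= threshold, threshold=threshold)


# --------------------------------------------------------------------------
# Cluster-based dimensionality reduction
# --------------------------------------------------------------------------

def _raw_rsa_upper(avg: np.ndarray) -> np.ndarray:
    """Upper triangle of the raw spatiotemporal correlation matrix of
    trial-averaged responses ``(S, N, K)``."""
    flat = avg.reshape(avg.shape[0], -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    norms[norms == 0] = 1.0
    z = flat / norms[:, None]
    c = z @ z.T
    iu = np.triu_indices(len(z), k=1)
    return c[iu]


def _variance_explained(ref: np.ndarray, approx: np.ndarray) -> float:
    """Squared Pearson correlation between two RSA upper triangles."""
    ref = ref - ref.mean()
    approx = approx - approx.mean()
    denom = np.linalg.norm(ref) * np.linalg.norm(approx)
    if denom == 0:
        return 1.0
    return float((ref @ approx / denom) ** 2)


def cluster_reduce(ensemble: Ensemble, variance_target: float = 0.95
                   ) -> tuple[Ensemble, np.ndarray, int]:
    """Agglomerative (Ward) clustering of neurons on their full temporal
    response profiles, keeping the smallest cluster count whose
    cluster-mean RSA matrix explains >= ``variance_target`` of the
    variance of the full-population RSA matrix.

    Returns ``(reduced ensemble, cluster assignment, n_clusters)``.  The
    reduced ensemble replaces neurons by cluster means.  If even
    ``n_clusters == n_neurons`` misses the target (degenerate input), the
    full resolution is returned with a warning.
    """
    avg = ensemble.trial_average()                 # (S, N, K)
    n_neurons = ensemble.n_neurons
    profiles = np.transpose(avg, (1, 0, 2)).reshape(n_neurons, -1)
    ref_upper = _raw_rsa_upper(avg)
    if n_neurons == 1:
        return ensemble, np.zeros(1, dtype=int), 1
    Z = linkage(profiles, method="ward")

    def reduce_to(labels: np.ndarray, k: int) -> np.ndarray:
        out = np.empty((ensemble.n_trials, k, ensemble.n_bins))
        for c in range(k):
            out[:, c, :] = ensemble.values[:, labels == c, :].mean(axis=1)
        return out

    for k in range(1, n_neurons + 1):
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        k_eff = labels.max() + 1
        reduced_vals = reduce_to(labels, k_eff)
        red = Ensemble(values=reduced_vals,
                       stimulus_labels=ensemble.stimulus_labels,
                       session_labels=ensemble.session_labels,
                       dt_ms=ensemble.dt_ms, seed=ensemble.seed)
        ve = _variance_explained(ref_upper, _raw_rsa_upper(red.trial_average()))
        if ve >= variance_target:
            return red, labels, int(k_eff)
    log.warning("variance target %.3f unreachable; returning full resolution",
                variance_target)
    return ensemble, np.arange(n_neurons), n_neurons
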