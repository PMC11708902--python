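"""Noise-corrected representational similarity analysis.

Trial-to-trial variability attenuates the Pearson correlation between
trial-averaged population vectors.  When repeated trials are available,
the correlation of the underlying noise-free representations can be
estimated by dividing the mean cross-stimulus trial correlation by the
geometric mean of the within-stimulus trial correlations:

    rho_hat = m_cross / sqrt(m_self_s * m_self_s')

    m_cross  = mean over all trial pairs (r, r') of rho(v_s_r, v_s'_r')
    m_self_s = mean over trial pairs r != r' of rho(v_s_r, v_s_r')

The estimator is unbiased in the large-dimension limit but individual
estimates can fall outside [-1, 1]; they are reported as-is, never
clipped.  Stimuli whose within-stimulus trial correlation is below 0.01
are noise-dominated and excluded before building RSA matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import Ensemble

log = logging.getLogger(__name__)

__all__ = [
    "feature_vectors", "corrected_correlation", "self_consistency",
    "exclude_stimuli", "shuffle_trials", "RsaMatrix", "rsa", "rho_diff",
    "matrix_dissimilarity", "corrected_matrix_dissimilarity",
    "bootstrap_sessions",
]

MODES = ("spatial", "spatiotemporal")


def feature_vectors(trials: np.ndarray, mode: str) -> np.ndarray:
    """Featurize single trials ``(R, N, K)`` into row vectors.

    ``spatiotemporal``: concatenate every neuron's full time course
    (``N*K`` entries).  ``spatial``: time-average each neuron (``N``
    entries).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    trials = np.asarray(trials, dtype=float)
    if mode == "spatial":
        return trials.mean(axis=2)
    return trials.reshape(trials.shape[0], -1)


def _pairwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation between rows of ``a`` and ``b``.

    Zero-variance rows give NaN entries (undefined correlations)."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (a @ b.T) / np.outer(na, nb)
    c[na == 0, :] = np.nan
    c[:, nb == 0] = np.nan
    return c


def _nanmean_logged(values: np.ndarray, what: str) -> float:
    n_bad = int(np.isnan(values).sum())
    if n_bad:
        log.warning("%d undefined Pearson pairs dropped from %s", n_bad, what)
    if n_bad == values.size:
        return np.nan
    return float(np.nanmean(values))


def self_consistency(trials: np.ndarray, mode: str = "spatiotemporal") -> float:
    """Within-stimulus mean across-trial correlation,
    ``(1/(R(R-1))) sum_{r != r'} rho``."""
    feats = feature_vectors(trials, mode)
    c = _pairwise_corr(feats, feats)
    off = ~np.eye(len(feats), dtype=bool)
    return _nanmean_logged(c[off], "self-consistency")


def corrected_correlation(trials_s: np.ndarray, trials_s2: np.ndarray,
                          mode: str = "spatiotemporal") -> float:
    """Noise-corrected correlation between two stimuli's representations.

    ``trials_s`` and ``trials_s2`` are single-trial tensors ``(R, N, K)``
    (or pre-featurized 2-D arrays).  Requires >= 2 trials per stimulus.
    Returns NaN (flagged noise-dominated) when a within-stimulus mean
    correlation is <= 0; such stimuli should be removed beforehand with
    :func:`exclude_stimuli`.
    """
    trials_s = np.atleast_3d(np.asarray(trials_s, dtype=float))
    trials_s2 = np.atleast_3d(np.asarray(trials_s2, dtype=float))
    if trials_s.shape[0] < 2 or trials_s2.shape[0] < 2:
        raise ValueError("need at least 2 trials per stimulus")
    f1 = feature_vectors(trials_s, mode)
    f2 = feature_vectors(trials_s2, mode)
    m_cross = _nanmean_logged(_pairwise_corr(f1, f2), "cross mean")
    m_self_1 = self_consistency(trials_s, mode)
    m_self_2 = self_consistency(trials_s2, mode)
    if not (m_self_1 > 0 and m_self_2 > 0):
        log.warning("noise-dominated stimulus (within-trial correlation "
                    "<= 0); corrected estimate undefined")
        return np.nan
    return m_cross / np.sqrt(m_self_1 * m_self_2)


def exclude_stimuli(ensemble: Ensemble, threshold: float = 0.01,
                    mode: str = "spatiotemporal") -> np.ndarray:
    """Boolean keep-mask over ``ensemble.stimuli``: a stimulus is kept iff
    its within-stimulus mean across-trial correlation is >= ``threshold``
    (strictly below the threshold is excluded)."""
    keep = np.zeros(len(ensemble.stimuli), dtype=bool)
    for i, s in enumerate(ensemble.stimuli):
        sc = self_consistency(ensemble.trials_for(s), mode)
        keep[i] = not (np.isnan(sc) or sc < threshold)
    return keep


def shuffle_trials(ensemble: Ensemble, seed: int | None = None) -> Ensemble:
    """Shuffle trial identity independently for each neuron within each
    stimulus.  Destroys within-trial noise correlations across neurons
    while preserving every neuron's marginal trial set exactly (and hence
    the trial average, bit-identically)."""
    rng = np.random.default_rng(seed)
    values = ensemble.values.copy()
    for s in ensemble.stimuli:
        idx = np.flatnonzero(ensemble.stimulus_labels == s)
        for n in range(ensemble.n_neurons):
            values[idx, n, :] = values[idx[rng.permutation(len(idx))], n, :]
    return replace(ensemble, values=values)


@dataclass
class RsaMatrix:
    """Stimulus-pair similarity matrix.

    ``values`` is S x S and symmetric with unit diagonal (corrected
    self-similarity is 1 by convention).  ``stimuli`` names the rows.
    """

    values: np.ndarray
    stimuli: np.ndarray
    mode: str
    corrected: bool = True
    boot_sd: np.ndarray | None = None
    n_boot: int = 0

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.values), k=1)
        return self.values[iu]

    def mean_offdiagonal(self) -> float:
        return float(np.nanmean(self.upper()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.stimuli,
                            columns=self.stimuli)


def rsa(ensemble: Ensemble, mode: str = "spatiotemporal",
        corrected: bool = True, apply_exclusion: bool = True,
        exclusion_threshold: float = 0.01) -> RsaMatrix:
    """Representational similarity matrix over all stimulus pairs.

    ``corrected=True`` uses the noise-corrected estimator on single
    trials; ``corrected=False`` correlates trial averages (the raw,
    attenuated similarity).  Noise-dominated stimuli are dropped first
    when ``apply_exclusion`` is set.
    """
    if apply_exclusion:
        keep = exclude_stimuli(ensemble, exclusion_threshold, mode)
        ensemble = ensemble.select_stimuli(ensemble.stimuli[keep])
    stimuli = ensemble.stimuli
    S = len(stimuli)
    trials = [ensemble.trials_for(s) for s in stimuli]
    m = np.eye(S)
    if corrected:
        for i in range(S):
            for j in range(i + 1, S):
                m[i, j] = m[j, i] = corrected_correlation(
                    trials[i], trials[j], mode)
    else:
        feats = feature_vectors(
            np.stack([t.mean(axis=0) for t in trials]), mode)
        c = _pairwise_corr(feats, feats)
        iu = np.triu_indices(S, k=1)
        m[iu] = c[iu]
        m[(iu[1], iu[0])] = c[iu]
    return RsaMatrix(values=m, stimuli=stimuli, mode=mode, corrected=corrected)


def rho_diff(rho_timeavg: float, rho_seq: float) -> float:
    """Normalized spatial-vs-spatiotemporal correlation contrast,
    ``(rho_t-av - rho_seq) / (1 - 0.5 (rho_t-av - rho_seq))``."""
    if not (np.isfinite(rho_timeavg) and np.isfinite(rho_seq)):
        raise ValueError("inputs must be finite")
    d = rho_timeavg - rho_seq
    denom = 1.0 - 0.5 * d
    if denom == 0:
        log.warning("rho_diff denominator is zero; contrast undefined")
        return np.nan
    return d / denom


def matrix_dissimilarity(m1: RsaMatrix, m2: RsaMatrix) -> float:
    """Raw structural dissimilarity between two RSA matrices:
    ``1 - Pearson correlation of the upper-triangle entries`` (in [0, 2]).
    Degenerate (constant) matrices give NaN (flagged)."""
    u1, u2 = m1.upper(), m2.upper()
    if len(u1) != len(u2):
        raise ValueError("matrices must cover the same stimulus set")
    ok = ~(np.isnan(u1) | np.isnan(u2))
    u1, u2 = u1[ok] - u1[ok].mean(), u2[ok] - u2[ok].mean()
    denom = np.linalg.norm(u1) * np.linalg.norm(u2)
    if denom == 0:
        log.warning("degenerate (constant) RSA matrix; dissimilarity undefined")
        return np.nan
    return float(1.0 - u1 @ u2 / denom)


def _split_half_rsa(ensemble: Ensemble, mode: str, rng: np.random.Generator
                    ) -> tuple[RsaMatrix, RsaMatrix]:
    """RSA matrices (uncorrected, trial-averaged) on disjoint trial halves."""
    half_a_idx, half_b_idx = [], []
    for s in ensemble.stimuli:
        idx = np.flatnonzero(ensemble.stimulus_labels == s)
        perm = rng.permutation(len(idx))
        half = len(idx) // 2
        half_a_idx.append(idx[perm[:half]])
        half_b_idx.append(idx[perm[half:]])
    out = []
    for part in (half_a_idx, half_b_idx):
        sel = np.concatenate(part)
        sub = replace(ensemble, values=ensemble.values[sel],
                      stimulus_labels=ensemble.stimulus_labels[sel],
                      session_labels=ensemble.session_labels[sel])
        out.append(rsa(sub, mode, corrected=False, apply_exclusion=False))
    return out[0], out[1]


def corrected_matrix_dissimilarity(ensemble: Ensemble,
                                   mode1: str = "spatiotemporal",
                                   mode2: str = "spatial",
                                   ensemble2: Ensemble | None = None,
                                   n_splits: int = 10,
                                   seed: int | None = None) -> float:
    """Noise-corrected dissimilarity between two RSA structures.

    Compares the RSA matrix of ``ensemble`` under ``mode1`` with that of
    ``ensemble2`` (default: the same ensemble) under ``mode2``, with the
    trial-level attenuation correction mirrored at the matrix level: RSA
    matrices are computed on disjoint trial halves; the across-source
    correlation of upper triangles (cross) is divided by the geometric
    mean of the across-half, within-source correlations (self), and the
    corrected dissimilarity is ``1 - cross / sqrt(self1 * self2)``,
    averaged over ``n_splits`` random splits.
    """
    if ensemble2 is None:
        ensemble2 = ensemble
    if len(ensemble.stimuli) != len(ensemble2.stimuli):
        raise ValueError("ensembles must cover the same stimulus set")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_splits):
        a1, b1 = _split_half_rsa(ensemble, mode1, rng)
        a2, b2 = _split_half_rsa(ensemble2, mode2, rng)
        sim = lambda m, mm: 1.0 - matrix_dissimilarity(m, mm)  # noqa: E731
        cross = 0.5 * (sim(a1, b2) + sim(b1, a2))
        self1 = sim(a1, b1)
        self2 = sim(a2, b2)
        if self1 > 0 and self2 > 0:
            out.append(1.0 - cross / np.sqrt(self1 * self2))
    if not out:
        log.warning("all splits noise-dominated; corrected matrix "
                    "dissimilarity undefined")
        return np.nan
    return float(np.mean(out))


def bootstrap_sessions(ensemble: Ensemble, statistic, n_boot: int = 100,
                       seed: int | None = None
                       ) -> tuple[float, float, float]:
    """Session bootstrap of an ensemble statistic.

    ``statistic`` maps an Ensemble to a scalar.  Sessions are resampled
    with replacement ``n_boot`` times; returns ``(estimate, SD, p)`` with
    a two-sided p-value for the statistic differing from zero, floored at
    ``1 / n_boot``.
    """
    sessions = ensemble.sessions
    if len(sessions) < 2:
        raise ValueError("session bootstrap requires at least 2 sessions")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(ensemble))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        resampled = rng.choice(sessions, size=len(sessions), replace=True)
        parts = [ensemble.select_sessions([s]) for s in resampled]
        merged = Ensemble(
            values=np.concatenate([p.values for p in parts]),
            stimulus_labels=np.concatenate(
                [p.stimulus_labels for p in parts]),
            session_labels=np.concatenate(
                [np.full(p.n_trials, i) for i, p in enumerate(parts)]),
            dt_ms=ensemble.dt_ms)
        boots[b] = statistic(merged)
    sd = float(np.std(boots))
    frac_le = np.mean(boots <= 0.0)
    frac_ge = np.mean(boots >= 0.0)
    p = max(2.0 * min(frac_le, frac_ge), 1.0 / n_boot)
    return estimate, sd, float(min(p, 1.0))
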