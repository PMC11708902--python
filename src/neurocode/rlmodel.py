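"""Reinforcement-learning model of Go/NoGo discrimination.

A minimal feedforward decision circuit learns to associate population
input patterns with a lick/no-lick decision.  A Go unit receives the
input through plastic excitatory weights ``w_E`` and an inhibitory unit
relays the same input with weights ``w_I``; the Go unit's binary output
at each time step is

    y(t) = theta( w_E . X(t) - w_I . X(t) - xi ),

with theta the Heaviside step (theta(0) = 0) and xi a Gaussian decision
noise drawn once per trial.  A Go response is emitted when the mean of
y(t) over the 0.5-s response window exceeds 0.2.

Learning is gated by an eligibility trace: the pre/post coincidence
X(t) y(t) is integrated over the response window and gated by a
seconds-long dopamine-gating kernel D evaluated at the coincidence-to-
reward lag.  Weights then move by an asymmetric
reward-prediction-error rule,

    e      = R - sigma * (w_E - w_I) . ElTr
    dw_E   = lambda * f(e) * ElTr,   dw_I = -dw_E
    f(u)   = u for u < 0,  nu * u for u >= 0   (nu > 1),

with R = +1 for reward and -1 otherwise, and weights clipped at zero.
Because X enters only through its per-bin drive and its coincidence with
y, the rule is blind to per-neuron temporal order: patterns differing
only by mean-preserving time-bin shuffles are not discriminable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "EligibilityKernel", "ModelState", "gad",
    "run_trial", "eligibility_trace", "update_weights", "train",
    "LearningOutcome", "equalize_global_activity", "learning_surface",
]

@dataclass
class EligibilityKernel:
    """Discretized nonnegative dopamine-gating kernel over lag (s).

    Default: gamma-shaped profile peaking at ``peak_s`` = 1 s with
    support [0, ``support_s`` = 2 s], normalized to unit integral — a
    documented stand-in for the measured striatal plasticity-gating
    window (reward must arrive within a few seconds of the pre/post
    coincidence for the synapse tag to be read out).
    """

    dt_s: float = 0.02
    peak_s: float = 1.0
    support_s: float = 2.0
    shape: float = 4.0

    def __post_init__(self) -> None:
        u = np.arange(0.0, self.support_s + self.dt_s / 2, self.dt_s)
        scale = self.peak_s / (self.shape - 1.0)
        d = u ** (self.shape - 1.0) * np.exp(-u / scale)
        total = d.sum() * self.dt_s
        self.lags_s = u
        self.values = d / total

    def __call__(self, lag_s) -> np.ndarray:
        """Kernel value at arbitrary lags (linear interpolation, zero
        outside the support)."""
        return np.interp(lag_s, self.lags_s, self.values, left=0.0, right=0.0)


@dataclass
class ModelState:
    """Weights and hyperparameters of the decision circuit.

    ``lam`` is the learning rate, ``nu`` the asymmetry ratio (>1:
    unexpected rewards teach faster than omitted ones), ``sigma`` scales
    the reward prediction, ``xi_sd`` the per-trial decision noise, and
    ``threshold`` the Go criterion on the mean output (0.2).
    """

    n_inputs: int
    lam: float = 0.002
    nu: float = 3.0
    sigma: float = 0.5
    xi_sd: float = 0.5
    threshold: float = 0.2
    T_eltr_s: float = 0.5
    reward_delay_s: float = 1.0
    w_init: float = 0.01
    multiplicative: bool = False
    kernel: EligibilityKernel = field(default_factory=EligibilityKernel)
    w_E: np.ndarray = None
    w_I: np.ndarray = None

    def __post_init__(self) -> None:
        if self.w_E is None:
            self.w_E = np.full(self.n_inputs, self.w_init)
        if self.w_I is None:
            self.w_I = np.full(self.n_inputs, self.w_init)
        self.w_E = np.asarray(self.w_E, dtype=float)
        self.w_I = np.asarray(self.w_I, dtype=float)
        if (self.w_E < 0).any() or (self.w_I < 0).any():
            raise ValueError("weights must be nonnegative")

    def copy(self) -> "ModelState":
        return replace(self, w_E=self.w_E.copy(), w_I=self.w_I.copy())


def gad(v1: float, v2: float) -> float:
    """Global activity difference ``|v1 - v2| / (v1 + v2)``: symmetric,
    scale-invariant, in [0, 1]."""
    if v1 + v2 <= 0:
        log.warning("GAD undefined for zero total activity")
        return np.nan
    return abs(v1 - v2) / (v1 + v2)


def _response(state: ModelState, X: np.ndarray, xi: float) -> np.ndarray:
    """Binary Go-unit output per time bin; theta(0) = 0."""
    drive = (state.w_E - state.w_I) @ X - xi
    return (drive > 0).astype(float)


def eligibility_trace(X: np.ndarray, y: np.ndarray,
                      kernel: EligibilityKernel, dt_s: float,
                      reward_lag_s: float = 1.0) -> np.ndarray:
    """Per-input eligibility at reward time.

    ``ElTr_i = D(lag) * sum_k X_i(k) y(k) dt`` — the pre/post coincidence
    integrated over the response window, gated by the kernel evaluated at
    the lag between the window midpoint and reward delivery (reward
    arrives ``reward_lag_s`` after the end of the window).

    The gating kernel varies over seconds while the response window is
    half a second, so within a trial it acts as a single gain on the
    integrated coincidence: the seconds-long trace averages out the
    precise timing of pre/post coincidences inside the window, which is
    what makes the rule blind to per-neuron temporal order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K = X.shape[1]
    T = K * dt_s
    lag = T / 2.0 + reward_lag_s
    gain = float(kernel(lag))
    return gain * (X @ y) * dt_s


def update_weights(state: ModelState, X_ElTr: np.ndarray, R_outcome: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """One application of the asymmetric reward-prediction-error rule.

    Returns the new ``(w_E, w_I)``, clipped at zero.  With
    ``multiplicative=True`` the per-synapse step is additionally scaled
    by the current weight (optional variant, off by default).
    """
    e = R_outcome - state.sigma * float((state.w_E - state.w_I) @ X_ElTr)
    f_e = state.nu * e if e >= 0 else e
    step = state.lam * f_e * X_ElTr
    if state.multiplicative:
        w_scale_E = state.w_E / max(state.w_E.mean(), 1e-12)
        w_scale_I = state.w_I / max(state.w_I.mean(), 1e-12)
    else:
        w_scale_E = w_scale_I = 1.0
    w_E = np.clip(state.w_E + step * w_scale_E, 0.0, None)
    w_I = np.clip(state.w_I - step * w_scale_I, 0.0, None)
    return w_E, w_I


def run_trial(state: ModelState, X: np.ndarray, is_go: bool,
              rng: np.random.Generator, learn: bool = True) -> dict:
    """Run one trial in place: response, decision, outcome, weight update.

    ``X`` is the nonnegative ``(n_inputs, K)`` input over the 0.5-s
    response window.  Decision is Go iff the time-averaged output exceeds
    the threshold.  Reward outcome: R = +1 for a hit (Go response to the
    Go pattern), R = -1 otherwise.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input pattern must be finite")
    dt_s = state.T_eltr_s / X.shape[1]
    xi = rng.normal(0.0, state.xi_sd) if state.xi_sd > 0 else 0.0
    y = _response(state, X, xi)
    go = bool(y.mean() > state.threshold)
    correct = go if is_go else not go
    R = 1.0 if (is_go and go) else -1.0
    if learn:
        tr = eligibility_trace(X, y, state.kernel, dt_s,
                               state.reward_delay_s)
        state.w_E, state.w_I = update_weights(state, tr, R)
    return {"go": go, "correct": correct, "R": R, "xi": xi,
            "mean_y": float(y.mean())}


@dataclass
class LearningOutcome:
    """Learning curve (accuracy per 150-trial block, averaged over
    repeats), trials to the 80% criterion (sentinel ``max_trials + 1``
    when never reached), and the final weights of the last repeat."""

    curve: np.ndarray
    trials_to_criterion: int
    final_w_E: np.ndarray
    final_w_I: np.ndarray
    n_repeats: int
    max_trials: int
    block: int = 150

    @property
    def learned(self) -> bool:
        return self.trials_to_criterion <= self.max_trials


def train(go_pattern: np.ndarray, nogo_pattern: np.ndarray,
          state: ModelState | None = None, max_trials: int = 10_000,
          criterion: float = 0.8, n_repeats: int = 3, block: int = 150,
          seed: int | None = None, **state_kwargs) -> LearningOutcome:
    """Train the model to discriminate a Go/NoGo pattern pair.

    Trials alternate between the two patterns in randomized order (equal
    numbers per block).  The learning curve is the fraction of correct
    responses per ``block`` trials, averaged over ``n_repeats``
    independent simulations; trials-to-criterion is the end of the first
    block whose average accuracy reaches ``criterion``.
    """
    go_pattern = np.asarray(go_pattern, dtype=float)
    nogo_pattern = np.asarray(nogo_pattern, dtype=float)
    if go_pattern.shape != nogo_pattern.shape:
        raise ValueError("patterns must share shape")
    n_blocks = max_trials // block
    curves = np.zeros((n_repeats, n_blocks))
    rng_master = np.random.default_rng(seed)
    for rep in range(n_repeats):
        rng = np.random.default_rng(rng_master.integers(2**31))
        st = (ModelState(n_inputs=go_pattern.shape[0], **state_kwargs)
              if state is None else state.copy())
        for b in range(n_blocks):
            is_go_seq = rng.permutation(
                np.arange(block) % 2 == 0)
            n_correct = 0
            for is_go in is_go_seq:
                X = go_pattern if is_go else nogo_pattern
                rec = run_trial(st, X, bool(is_go), rng)
                n_correct += rec["correct"]
            curves[rep, b] = n_correct / block
    mean_curve = curves.mean(axis=0)
    reached = np.flatnonzero(mean_curve >= criterion)
    ttc = int((reached[0] + 1) * block) if len(reached) else max_trials + 1
    return LearningOutcome(curve=mean_curve, trials_to_criterion=ttc,
                           final_w_E=st.w_E, final_w_I=st.w_I,
                           n_repeats=n_repeats, max_trials=max_trials,
                           block=block)


def equalize_global_activity(X1: np.ndarray, X2: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Remove the global activity difference between two patterns by
    shifting each to the common mean (clipped at zero)."""
    m = 0.5 * (X1.mean() + X2.mean())
    return (np.clip(X1 - X1.mean() + m, 0.0, None),
            np.clip(X2 - X2.mean() + m, 0.0, None))


def learning_surface(frac_shuffled_grid, frac_resampled_grid,
                     activity_offset_grid=(0.0,), n_seeds: int = 3,
                     n_neurons: int = 1000, n_bins: int = 25,
                     max_trials: int = 10_000, seed: int = 0,
                     **train_kwargs) -> list[dict]:
    """Trials-to-criterion over a grid of pattern manipulations.

    For every combination of time-bin shuffling fraction (spatiotemporal
    axis), activity-resampling fraction (spatial axis), and global
    activity offset (GAD axis), generates ``n_seeds`` pattern pairs,
    trains the model on each, and records the realized similarity
    metrics next to the requested levels.
    """
    from .synthio import make_pattern_pair
    rng = np.random.default_rng(seed)
    rows = []
    for fs in frac_shuffled_grid:
        for fr in frac_resampled_grid:
            for off in activity_offset_grid:
                for _ in range(n_seeds):
                    pair_seed = int(rng.integers(2**31))
                    pair = make_pattern_pair(
                        n_neurons, n_bins, frac_shuffled=fs,
                        frac_resampled=fr, activity_offset=off,
                        seed=pair_seed)
                    out = train(pair.X_go, pair.X_nogo,
                                max_trials=max_trials,
                                seed=int(rng.integers(2**31)),
                                **train_kwargs)
                    rows.append({
                        "frac_shuffled": fs, "frac_resampled": fr,
                        "activity_offset": off, "pair_seed": pair_seed,
                        "trials_to_criterion": out.trials_to_criterion,
                        "learned": out.learned,
                        **{f"realized_{k}": v
                           for k, v in pair.meta["realized"].items()},
                    })
    return rows
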