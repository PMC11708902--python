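"""Trial-structured population response container.

The universal currency of the pipeline is a tensor of shape
``(trials, neurons, time_bins)`` together with per-trial stimulus and
session labels.  Synthetic generators attach the noise-free ground truth
they were built from so downstream estimators can be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

SCHEMA_VERSION = 1


@dataclass
class Ensemble:
    """Trial-structured population activity for a set of labeled stimuli.

    Parameters
    ----------
    values
        Array of shape ``(n_trials_total, n_neurons, n_bins)``; rate-like
        units, baseline-subtracted.
    stimulus_labels
        Integer (or string) label per trial.
    session_labels
        Recording-session tag per trial; used by the session bootstrap.
    dt_ms
        Time-bin width in milliseconds.
    truth
        Optional ground truth: ``templates`` with shape
        ``(n_stimuli, n_neurons, n_bins)`` and ``correlations`` with the
        true pairwise Pearson correlations of the noise-free templates.
    seed
        RNG seed the ensemble was generated from, if synthetic.
    """

    values: np.ndarray
    stimulus_labels: np.ndarray
    session_labels: np.ndarray
    dt_ms: float = 1.0
    truth: dict | None = None
    seed: int | None = None
    window_ms: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (trials, neurons, time_bins)")
        self.stimulus_labels = np.asarray(self.stimulus_labels)
        self.session_labels = np.asarray(self.session_labels)
        n = self.values.shape[0]
        if len(self.stimulus_labels) != n or len(self.session_labels) != n:
            raise ValueError("label length must match the trial axis")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def stimuli(self) -> np.ndarray:
        """Unique stimulus labels, sorted."""
        return np.unique(self.stimulus_labels)

    @property
    def sessions(self) -> np.ndarray:
        return np.unique(self.session_labels)

    def trials_for(self, stimulus) -> np.ndarray:
        """All trials of one stimulus, shape ``(R, n_neurons, n_bins)``."""
        return self.values[self.stimulus_labels == stimulus]

    def trial_average(self) -> np.ndarray:
        """Per-stimulus trial-averaged responses, ``(S, n_neurons, n_bins)``."""
        return np.stack([self.trials_for(s).mean(axis=0) for s in self.stimuli])

    def select_stimuli(self, keep) -> "Ensemble":
        keep = np.asarray(keep)
        mask = np.isin(self.stimulus_labels, keep)
        return replace(
            self,
            values=self.values[mask],
            stimulus_labels=self.stimulus_labels[mask],
            session_labels=self.session_labels[mask],
        )

    def select_sessions(self, sessions) -> "Ensemble":
        sessions = np.asarray(sessions)
        mask = np.isin(self.session_labels, sessions)
        return replace(
            self,
            values=self.values[mask],
            stimulus_labels=self.stimulus_labels[mask],
            session_labels=self.session_labels[mask],
        )

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        """Write the ensemble to HDF5 (datasets /tensor, /stimulus_labels,
        /session_labels, optional /truth)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("tensor", data=self.values)
            f.create_dataset(
                "stimulus_labels", data=np.asarray(self.stimulus_labels, dtype="S")
            )
            f.create_dataset(
                "session_labels", data=np.asarray(self.session_labels, dtype="S")
            )
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["window_ms"] = list(self.window_ms)
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            if self.truth is not None:
                g = f.create_group("truth")
                for k, v in self.truth.items():
                    g.create_dataset(k, data=np.asarray(v))

    @classmethod
    def load(cls, path) -> "Ensemble":
        with h5py.File(path, "r") as f:
            truth = None
            if "truth" in f:
                truth = {k: f["truth"][k][()] for k in f["truth"]}
            labels = f["stimulus_labels"][()].astype(str)
            # labels written as bytes; restore ints when they round-trip
            try:
                labels = labels.astype(int)
            except ValueError:
                pass
            sessions = f["session_labels"][()].astype(str)
            try:
                sessions = sessions.astype(int)
            except ValueError:
                pass
            return cls(
                values=f["tensor"][()],
                stimulus_labels=labels,
                session_labels=sessions,
                dt_ms=float(f.attrs.get("dt_ms", 1.0)),
                truth=truth,
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
                window_ms=tuple(f.attrs.get("window_ms", (0.0, 0.0))),
            )
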