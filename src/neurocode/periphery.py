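"""Auditory-nerve population layout.

Tonotopic placement of inner hair cells (IHCs) along the basilar
membrane, fibers-per-IHC allocation, and the spontaneous-rate /
calcium-clearance mapping for auditory nerve fibers (ANFs).  The
transduction cascade itself (stapes to spike trains) is out of scope;
this module only builds the population layout those models run on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnfLayout", "x_from_cf", "cf_from_x", "fibers_per_ihc",
    "sr_from_tau", "tau_from_sr", "build_layout",
]


def x_from_cf(cf_khz):
    """Basilar-membrane position (% length from apex) for a characteristic
    frequency in kHz: ``x = -56.5 + 82.5 * log10(CF)``."""
    cf_khz = np.asarray(cf_khz, dtype=float)
    if np.any(cf_khz <= 0):
        raise ValueError("characteristic frequency must be positive (kHz)")
    return -56.5 + 82.5 * np.log10(cf_khz)


def cf_from_x(x_percent):
    """Inverse tonotopic map: CF in kHz at position x (% from apex)."""
    return 10.0 ** ((np.asarray(x_percent, dtype=float) + 56.5) / 82.5)


def fibers_per_ihc(x_percent, rounded: bool = True):
    """ANF count per IHC at position x: ``N = -0.0038 x^2 + 0.375 x + 7.9``.

    ``rounded=True`` returns the nearest-integer allocation used to build
    discrete layouts; ``rounded=False`` returns the raw quadratic.
    """
    x = np.asarray(x_percent, dtype=float)
    n = -0.0038 * x**2 + 0.375 * x + 7.9
    if rounded:
        return np.round(n).astype(int)
    return n


def sr_from_tau(tau_ca_ms):
    """Spontaneous rate (spikes/s) from the calcium-clearance time constant
    (ms): ``SR = 91.1 * tau^2.66``."""
    tau = np.asarray(tau_ca_ms, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_ca must be positive (ms)")
    return 91.1 * tau**2.66


def tau_from_sr(sr_spikes_s):
    """Closed-form inverse of :func:`sr_from_tau`."""
    sr = np.asarray(sr_spikes_s, dtype=float)
    if np.any(sr <= 0):
        raise ValueError("spontaneous rate must be positive")
    return (sr / 91.1) ** (1.0 / 2.66)


@dataclass
class AnfLayout:
    """Discrete ANF population layout.

    ``cfs`` (kHz), ``ihc_positions`` (% from apex) and ``fibers_per_ihc``
    are per-IHC arrays; ``fiber_ihc``, ``taus`` (ms) and ``srs``
    (spikes/s) are per-fiber arrays.
    """

    cfs: np.ndarray
    ihc_positions: np.ndarray
    fibers_per_ihc: np.ndarray
    fiber_ihc: np.ndarray
    taus: np.ndarray
    srs: np.ndarray
    seed: int | None = None

    @property
    def n_ihcs(self) -> int:
        return len(self.cfs)

    @property
    def n_fibers(self) -> int:
        return int(self.fibers_per_ihc.sum())

    def ihc_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ihc": np.arange(self.n_ihcs),
            "x_percent": self.ihc_positions,
            "cf_khz": self.cfs,
            "n_fibers": self.fibers_per_ihc,
        })

    def fiber_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fiber": np.arange(len(self.fiber_ihc)),
            "ihc": self.fiber_ihc,
            "tau_ca_ms": self.taus,
            "sr_spikes_s": self.srs,
        })


def build_layout(cf_lo_khz: float = 5.0, n_ihcs: int = 40,
                 per_octave: int = 12,
                 sr_range: tuple[float, float] = (0.5, 95.0),
                 seed: int | None = None) -> AnfLayout:
    """Build the default 40-IHC / 590-fiber tonotopic layout.

    CFs are geometrically spaced at ``per_octave`` IHCs per octave from
    ``cf_lo_khz`` (ratio ``2**(1/per_octave)``), which makes the position
    grid arithmetic with spacing ``82.5 * log10(2) / per_octave`` (~2.07%
    for 12 per octave).  Per-fiber spontaneous rates are sampled
    log-uniformly within ``sr_range`` (the distribution is a documented
    default, not a constraint of the layout) and mapped back to calcium
    time constants with the closed-form inverse.
    """
    rng = np.random.default_rng(seed)
    cfs = cf_lo_khz * 2.0 ** (np.arange(n_ihcs) / per_octave)
    x = x_from_cf(cfs)
    counts = fibers_per_ihc(x, rounded=True)
    fiber_ihc = np.repeat(np.arange(n_ihcs), counts)
    lo, hi = sr_range
    srs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(fiber_ihc)))
    taus = tau_from_sr(srs)
    return AnfLayout(cfs=cfs, ihc_positions=x, fibers_per_ihc=counts,
                     fiber_ihc=fiber_ihc, taus=taus, srs=srs, seed=seed)
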