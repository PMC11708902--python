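"""Auditory-nerve layout: tonotopy, fiber allocation, spontaneous rates.

Builds the default 40-inner-hair-cell layout (5 kHz anchor, 12 IHCs per
octave) and prints the constants it implies.
"""

import numpy as np

from neurocode import periphery

layout = periphery.build_layout(seed=7)
print(f"IHCs: {layout.n_ihcs}")
print(f"CF range: {layout.cfs[0]:.1f} - {layout.cfs[-1]:.1f} kHz")
print(f"apex position: {layout.ihc_positions[0]:.2f}% "
      f"(rounds to {round(float(layout.ihc_positions[0]), 1)})")
print(f"tonotopic increment: {np.diff(layout.ihc_positions).mean():.3f}% "
      "per IHC")
print(f"total auditory nerve fibers: {layout.n_fibers}")
print(f"fibers per IHC: {layout.fibers_per_ihc.min()} (apex) to "
      f"{layout.fibers_per_ihc.max()} (mid-array)")
print(f"spontaneous rates: {layout.srs.min():.2f} - {layout.srs.max():.1f} "
      "spikes/s")
tau = periphery.tau_from_sr(20.0)
print(f"a 20 spikes/s fiber needs tau_Ca = {float(tau):.3f} ms "
      f"(round trip: {float(periphery.sr_from_tau(tau)):.1f} spikes/s)")
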