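"""Population decoding by coding scheme and timescale.

Decodes stimulus identity from half-split trial averages using either
the spatial (time-averaged) or the spatiotemporal featurization, then
restricts the decoder to single Fourier bands and cumulative band
prefixes.  The example uses two stimuli related by a time-bin
permutation — they carry no spatial information at all — plus four
ordinary stimuli.
"""

import numpy as np

from neurocode import decode, synthio
from neurocode.containers import Ensemble

rng = np.random.default_rng(0)
# 4 distinct stimuli + a rate-matched pair (same time-averaged rates,
# different temporal order)
tmpl = rng.uniform(0.5, 1.5, (4, 80, 12))
pairA = rng.uniform(0.5, 1.5, (80, 12))
pairB = pairA[:, rng.permutation(12)]
templates = np.concatenate([tmpl, pairA[None], pairB[None]])
trials = np.repeat(templates, 12, axis=0)
trials += 0.3 * rng.standard_normal(trials.shape)
ens = Ensemble(trials, np.repeat(np.arange(6), 12), np.zeros(72, int))

seeds = range(5)
for mode in ("spatial", "spatiotemporal"):
    acc = np.mean([decode.decode_ensemble(ens, mode, s).accuracy
                   for s in seeds])
    print(f"{mode:>15} decoding accuracy: {acc:.3f}")

res = decode.decode_by_timescale(ens, "cumulative", seeds=seeds)
print("\ncumulative Fourier decoding (band 0 = spatial/rate code):")
for band, acc in zip(res["bands"], res["accuracy"]):
    print(f"  bands 0..{band}: accuracy {acc:.3f}")

print("\nThe spatial decoder confuses the rate-matched pair (accuracy")
print("caps near 5/6 = 0.83); adding temporal bands recovers it.")
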