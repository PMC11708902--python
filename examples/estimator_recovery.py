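"""Noise-corrected correlation: recovering a known representation similarity.

Builds trial ensembles whose noise-free templates have Pearson
correlation exactly 0.5, corrupts them with increasing trial noise, and
compares the raw trial-average correlation (attenuated by noise) with
the noise-corrected estimator (unbiased at every noise level).
"""

import numpy as np

from neurocode import popcode, synthio

print(f"{'noise SD':>9} {'raw':>8} {'corrected':>10}   (truth = 0.5)")
for noise_sd in (0.0, 0.5, 1.0, 2.0):
    raw, corrected = [], []
    for s in range(50):
        ens = synthio.make_noisy_ensemble(
            n_neurons=2000, n_bins=1, true_corr=0.5, noise_sd=noise_sd,
            n_trials=15, seed=1000 * int(noise_sd * 10) + s)
        raw.append(popcode.rsa(ens, corrected=False,
                               apply_exclusion=False).values[0, 1])
        corrected.append(popcode.corrected_correlation(
            ens.trials_for(0), ens.trials_for(1)))
    print(f"{noise_sd:9.1f} {np.mean(raw):8.3f} {np.mean(corrected):10.3f}")

print("\nThe raw similarity shrinks as noise grows (attenuation); the")
print("corrected estimator stays at the true value of 0.5 throughout.")
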