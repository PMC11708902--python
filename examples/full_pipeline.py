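"""One-config end-to-end run: generate -> screen -> RSA -> decode -> learn.

Runs the whole synthetic analysis flow with a small configuration and
prints the headline numbers from the report bundle it writes.
"""

import tempfile

from neurocode import pipeline

cfg = pipeline.default_config()
cfg["ensemble"].update(n_neurons=150, n_bins=8, n_stimuli=6, n_trials=10,
                       noise_sd=0.8, true_corr=0.4)
cfg["rlmodel"].update(n_neurons=300, max_trials=3000, n_repeats=1)

with tempfile.TemporaryDirectory() as out:
    report = pipeline.run_all(cfg, out)

print(f"config hash: {report['config_hash']}")
print(f"kept neurons: {report['n_kept_neurons']}")
est = report["estimator"]
print(f"true template correlation {est['true_corr']:.2f}: "
      f"raw estimate {est['raw']:.3f}, corrected {est['corrected']:.3f}")
td = report["decode"]["time_domain"]
print(f"decoding accuracy: spatial {td['spatial']:.2f}, "
      f"spatiotemporal {td['spatiotemporal']:.2f}")
rl = report["rlmodel"]
print(f"RL model trials-to-criterion: {rl['trials_to_criterion']} "
      f"(spatial corr {rl['realized']['spatial']:.2f})")
print(f"ANF layout: {report['periphery']['n_fibers']} fibers / "
      f"{report['periphery']['n_ihcs']} IHCs")
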