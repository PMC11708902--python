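"""Relative-timing to rate conversion in a two-neuron E/I circuit.

An excitatory neuron driven by input A receives delayed inhibition from
a partner neuron driven by input B.  When the two 225-ms pulse trains
overlap in time, the A-then-B and B-then-A orders produce different
excitatory spike counts (a temporal cue becomes a rate cue); with a
250-ms onset delay the circuit is order-blind.
"""

from neurocode import eimodel

params = eimodel.LifParams(noise_sd=0.0)
res = eimodel.order_experiment(params, [0.0, 30.0, 80.0, 130.0, 250.0, 350.0],
                               n_seeds=1, n_boot=10, seed=0)
print(f"{'lag (ms)':>9} {'E spikes A->B':>14} {'E spikes B->A':>14} "
      f"{'|diff|':>7}")
for lag, ab, ba, d in zip(res["lags_ms"], res["counts_ab"],
                          res["counts_ba"], res["mean_abs_diff"]):
    print(f"{lag:9.0f} {ab:14.0f} {ba:14.0f} {d:7.1f}")

print("\nOverlapping trains (lag < 225 ms) yield order-dependent spike")
print("counts; at the 250-ms delay used experimentally the counts match,")
print("so no unintended spatial cue is created.")
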