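"""Build a multi-frequency multilayer network from trial-epoched signals.

Generates synthetic epochs in which channels 0-3 share a theta (6 Hz)
oscillation whose phase modulates their gamma (40 Hz) amplitude, while
channels 4-7 form a second, independent module.  The network has one layer
per band: intra-layer weights are phase-locking values (PLV, across-trial
phase consistency) and inter-layer weights are direct phase-amplitude
coupling (dPAC), all in [0, 1].
"""

import numpy as np

import multifreq as mf
from multifreq.synthetic import theta_gamma_study

epochs, bands, truth = theta_gamma_study(seed=0, coupled=True, n_trials=40)
net = mf.build_network(epochs, bands)

theta = net.intra_block(0)
inter = net.inter_block(0, 1)
iu = np.triu_indices(4, 1)
print(f"layers: {net.layers}, {net.n_total} layer-nodes")
print(f"theta PLV within module A : {theta[:4, :4][iu].mean():.3f}")
print(f"theta PLV across modules  : {theta[:4, 4:].mean():.3f}")
print(f"theta->gamma dPAC within A: {inter[:4, :4].mean():.3f}")
print(f"theta->gamma dPAC across  : {inter[:4, 4:].mean():.3f}")
print()
print("Within-module synchrony is strong and across-module synchrony sits at")
print("the across-trial noise floor; the elevated within-module dPAC is the")
print("planted cross-frequency coupling that will bind theta and gamma nodes")
print("into one community during detection.")

mf.write_network(net, "/tmp/multifreq_example_net.tsv")
print("\nnetwork written to /tmp/multifreq_example_net.tsv (+ manifest)")
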