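"""Maximize multilayer modularity on a planted-partition network.

The quality function compares each block's observed weight against a
configuration null model that preserves every node's layer-wise strengths;
the resolution gamma_r scales the null term and the inter-layer scale
omega weighs cross-layer edges.
"""

import numpy as np

import multifreq as mf

net, truth = mf.make_planted_network(mf.PlantedNetworkSpec(), seed=7)
params = mf.QualityParams(gamma_r=1.0, omega=1.0)

result = mf.maximize(net, params, seed=0)
print(f"4-layer planted network, {net.n_total} layer-nodes")
print(f"detected {result.partition.n_communities} communities, Q = {result.quality:.2f}")
print(f"NMI vs planted partition = {mf.nmi(result.partition, truth):.2f}")

all_one = mf.Partition(net, np.zeros(net.n_total, dtype=int))
print(f"Q(all-in-one, gamma_r = 1) = "
      f"{mf.multilayer_modularity(net, all_one, params):.2e}  (zero by construction)")
print()
print("NMI = 1 means the planted two cross-layer communities are recovered")
print("exactly; the all-in-one partition scores zero because observed and")
print("expected weights telescope at unit resolution.")
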