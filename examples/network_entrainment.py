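"""A 20% pathological minority entrains a mixed network once connected.

100 neurons (80 tonic-spiking at K_bath = 9.5 mM, 20 seizure-like at
17.0 mM) evolve independently for 5 s; the network is then switched to a
fully connected graph with exponential synapses (w = 0.5). After the
switch the population locks to the slow pathological rhythm: pairwise
spike-train synchrony rises.
"""

import numpy as np

from hybridbrain import (NetworkConfig, build_network, simulate_network,
                         synchrony_index)

config = NetworkConfig(N=100, f=0.8, K_bath_healthy=9.5, K_bath_path=17.0,
                       connectivity="none", seed=0)
net = build_network(config)
result = simulate_network(net, T=10_000.0, dt=0.0125, record_every=160,
                          switch_schedule=[(5000.0, True)])

pre = synchrony_index(result.raster, 100, 2000.0, 5000.0)
post = synchrony_index(result.raster, 100, 7000.0, 10_000.0)
n_pre = len(result.raster.in_window(2000.0, 5000.0))
n_post = len(result.raster.in_window(7000.0, 10_000.0))

print(f"spikes  2-5 s (unconnected): {n_pre}")
print(f"spikes 7-10 s   (connected): {n_post}")
print(f"synchrony index before the switch: {pre:.3f}")
print(f"synchrony index after the switch:  {post:.3f}")
print("\nThe synchrony index is the variance of the population-mean binned "
      "rate over\nthe mean single-cell variance (1 = locked). The rise "
      "after 5 s shows the\nnetwork settling into the common rhythm paced "
      "by the pathological cells.")
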