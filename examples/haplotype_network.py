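"""Temporal statistical-parsimony haplotype network.

Collapses the fixture into haplotypes, builds a minimum-spanning network,
reports the parsimony probability of every link (the chance the connection
involves no hidden homoplasious change), and layers the network by time
period to quantify haplotype loss.
"""

from condorabc import (build_network, collapse_haplotypes, layer_by_period,
                       make_condor_like_fixture)

samples = make_condor_like_fixture(seed=0)
table = collapse_haplotypes(samples)
net = build_network(table)

print(f"{table.n_H} haplotypes, {len(net.edges)} network links")
print(net.edge_frame().to_string(index=False))
print()

layered = layer_by_period(net)
for period in layered.periods:
    present = layered.presence[period]
    print(f"{period}: {len(present)} haplotypes "
          f"({sum(present.values())} samples) -> {sorted(present)}")
print(f"haplotype loss between periods: {layered.loss_percent:.0f}% "
      f"(lost: {', '.join(layered.lost_haplotypes)})")
print()
print("Link probabilities above 0.95 mean each connection is accepted under "
      "statistical parsimony; 1-step links on a 310 bp alignment sit near "
      "99.8%.")
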