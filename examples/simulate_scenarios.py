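"""Serial-sample coalescent simulation under the four demographic scenarios.

Simulates condor-like heterochronous datasets (35 museum-era + 38 modern
sequences, 310 bp, HKY mutation) under each scenario and compares the
resulting diversity.  A recent crash (scenario 2) leaves most coalescences
in the small epoch near the present, inflating rare deep splits relative to
the constant-size history.
"""

import numpy as np

from condorabc import (ScenarioParams, condor_design, condor_mutation_model,
                       mean_pairwise_differences, segregating_sites,
                       simulate_dataset)

model = condor_mutation_model(mu=1e-6, kappa=10.0)
design = condor_design()

scenarios = {
    "1 constant":          ScenarioParams(1, nef1=500),
    "2 recent bottleneck": ScenarioParams(2, nef1=50, nef2=20000, t1=200),
    "3 ancient bottleneck": ScenarioParams(3, nef1=500, nef3=50, t2=50000),
    "4 boom and busts":    ScenarioParams(4, nef1=100, nef2=20000, nef4=500,
                                          t1=200, te=10000, t2=200000),
}

rng = np.random.default_rng(0)
print(f"{'scenario':<22}{'mean K':>8}{'mean S':>8}   (50 replicates each)")
for name, params in scenarios.items():
    ks, ss = [], []
    for _ in range(50):
        ds = simulate_dataset(params, model, design,
                              seed=rng.integers(2**31))
        mat = ds.matrix()
        ks.append(mean_pairwise_differences(mat)[0])
        ss.append(segregating_sites(mat))
    print(f"{name:<22}{np.mean(ks):8.3f}{np.mean(ss):8.2f}")

print("\nK is the mean number of pairwise differences; S the count of "
      "segregating sites.  Histories with a large ancestral size retain "
      "deep lineages and show elevated S relative to the constant-size "
      "history with the same present-day size.")
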