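"""Exact pairwise coalescent-time distribution under the birth-death model.

Builds a supercritical birth-death process (lambda=0.5, mu=0.25, T=10),
evaluates the closed-form CDF of the time since the common ancestor of two
randomly sampled survivors, and cross-checks it against 4000 brute-force
full-tree simulations.
"""

import numpy as np

from bdcoal import BDParams, F_bd, sample_pair_coalescence, simulate_tree

params = BDParams(birth_rate=0.5, death_rate=0.25, origin_time=10.0)

print(f"R0 = {params.R0:.1f}, net growth r = {params.growth_rate}, "
      f"generation time rho = {params.generation_time}")

for tau in (2.0, 5.0, 8.0, 10.0):
    print(f"P(pair coalesced within {tau:4.1f} time units) = "
          f"{F_bd(tau, params):.4f}")

n = 4000
taus = np.array([
    sample_pair_coalescence(simulate_tree(params, rng_seed=k), rng_seed=10**6 + k)
    for k in range(n)
])
grid = np.sort(taus)
ks = np.max(np.abs(np.arange(1, n + 1) / n - F_bd(grid, params)))
print(f"\ntree-oracle check: KS distance over {n} simulated pairs = {ks:.4f}")
print("(values near 1/sqrt(n) ~ 0.016 mean the closed form matches the process)")
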