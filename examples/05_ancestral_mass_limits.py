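"""Ancestral coalescence mass of the deterministic coalescent versus mu.

Tabulates, in the large-N0 limit, the probability that a pair coalesces
before the origin of the matched birth-death process: e^-2 ~= 0.135 for
mu = 0, decreasing to 0 as mu approaches lambda.
"""

from bdcoal import limit_table

table = limit_table(birth_rate=0.5, n_mu=11)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nThe ancestral_mass column is the probability the exponential-growth")
print("coalescent assigns to coalescence at tau > T, where the birth-death")
print("process had a single individual; it never vanishes for R0 > 1.")
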