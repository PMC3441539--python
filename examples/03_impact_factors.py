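"""Sweep the factors that control the mean rejoining time.

Reproduces the model's impact-factor experiments on a 20-fragment
fixed-length population: the mean rejoining time rises with nuclear volume
(both recruitment and joining are second-order reactions), falls with the
residue release rate when short fragments are present, and jumps sharply
when the fragment length drops below the critical length L_c = 42 bp.
"""

from nhejsim import SimParams, parameter_sweep

params = SimParams()

print("volume sweep (20 fragments of 100 bp, 300 replicates/point):")
table = parameter_sweep(params, 20, 100, "V", [0.5, 1, 2, 4], 300, 11)
print(table[["value", "mean", "min", "max", "se"]].to_string(index=False))

print("\nrelease-rate sweep with short fragments (30 bp < L_c):")
table = parameter_sweep(params, 20, 30, "k_r", [0.05, 0.1, 0.2], 300, 12)
print(table[["value", "mean", "se"]].to_string(index=False))

print("\nfragment-length sweep across the critical length L_c = 42 bp:")
table = parameter_sweep(
    params, 20, 100, "fixed_length_n", [30, 41, 42, 60, 200], 300, 13
)
print(table[["value", "mean", "se"]].to_string(index=False))
print("\nBelow L_c every join needs a residue release before the product can "
      "recruit again, so halving k_r roughly doubles the time, and the mean "
      "jumps by roughly an order of magnitude between 42 and 41 bp.")
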