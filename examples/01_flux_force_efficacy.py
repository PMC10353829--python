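"""Flux-force efficacy: how much enzyme a given driving force wastes.

The FFE, (e^x - 1)/(e^x + 1) with x = dG/(RT), is the net-forward fraction
of catalytic events at a dissipation of dG kJ/mol.  Near equilibrium almost
half the enzyme works backwards; a few kJ/mol buys most of the benefit.
"""

from bioenopt import flux_force_efficacy, forward_fraction

T = 308.15  # 35 C, the warm fermentation case

print(f"{'dG (kJ/mol)':>12} {'FFE (%)':>8} {'forward sites (%)':>18}")
for dg in (0.0, 0.276, 0.5, 1.1, 1.5, 3.0, 6.0, 12.0):
    ffe = 100 * flux_force_efficacy(dg, T)
    fwd = 100 * forward_fraction(dg, T)
    print(f"{dg:12.3f} {ffe:8.1f} {fwd:18.1f}")

print()
print("A bottleneck running at 1.5 kJ/mol uses only ~64% of its enzyme for")
print("net forward flux; at 0.276 kJ/mol (25 C) the efficacy drops to ~6%,")
print("i.e. nearly half of all catalytic events are wasted going backwards.")
print(f"(at 25 C: FFE(0.276) = {100 * flux_force_efficacy(0.276, 298.15):.1f}%)")
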