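"""Junctional-conductance fitting and the derived genotype comparison.

Forward-generates amplitude-distance profiles from the network model at the
three genotype conductances (wild type, connexin30 T5M knock-in, connexin30
null), re-fits g_j as the model's only free parameter, and derives the
percent reductions and the open-channel count per cell pair.
"""

from gjlock import NetworkParams, build_lattice, solve_steady_state, amplitude_profile
from gjlock.calibfit import fit_gj, n_open, percent_reduction

lattice = build_lattice(45, 15)
genotypes = {"wild type": 206.0, "Cx30 T5M/T5M": 177.0, "Cx30 -/-": 19.0}

recovered = {}
for name, g_true in genotypes.items():
    profile = amplitude_profile(
        solve_steady_state(lattice, NetworkParams(g_j_ns=g_true)), lattice
    )
    fit = fit_gj(profile, lattice)
    recovered[name] = fit.g_j_ns
    print(f"{name:>14}: generated at {g_true:6.1f} nS -> fitted "
          f"g_j = {fit.g_j_ns:6.1f} nS (rss {fit.rss:.2e})")

g_wt = recovered["wild type"]
print(f"\nreduction vs wild type: "
      f"T5M {percent_reduction(g_wt, recovered['Cx30 T5M/T5M']):.0f}%, "
      f"null {percent_reduction(g_wt, recovered['Cx30 -/-']):.0f}%")
for gamma in (115.0, 137.5, 160.0):
    est = n_open(g_wt, gamma)
    print(f"unitary conductance {gamma:5.1f} pS -> "
          f"~{est.n_open_rounded} open channels per cell pair")
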