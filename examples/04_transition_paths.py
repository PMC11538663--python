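"""Minimum action paths: the most probable routes of the conversion.

The Freidlin-Wentzell action S = 1/2 int |phi_dot - F(phi)|^2 dt scores
how much noise a transition path requires; its minimizer is the most
probable escape route.  Here we compute the E->A and M->A paths of the
pentastable condition and show the pseudotime expression profile along
E->M: ZEB1 rises from the epithelial to the mesenchymal end while
miR200 collapses.
"""
from caclandscape import (find_attractors, load_cac_network,
                          minimize_action, pseudotime_profiles)

net = load_cac_network(TGFB=4.3, MEKI=0.02, ROSI=1.5)
aset = find_attractors(net, n_starts=200, seed=7, include_unstable=False)
E, M, A = (aset.by_phenotype(l) for l in ("E", "M", "A"))

for name, src, dst in [("E->A", E, A), ("A->E", A, E), ("M->A", M, A)]:
    p = minimize_action(net, src, dst, N=61, T_values=(5.0, 10.0, 20.0))
    print(f"S({name}) = {p.action:8.4f}   (horizon T={p.T}, "
          f"converged={p.converged})")

p_em = minimize_action(net, E, M, N=61, T_values=(5.0, 10.0, 20.0))
prof = pseudotime_profiles(p_em, net, nodes=["ZEB1", "miR200", "SNAIL1"])
print("\nE->M pseudotime profile (every 10th point):")
print(prof.iloc[::10].round(3).to_string(index=False))
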