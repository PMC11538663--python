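"""Trace the TGF-beta bifurcation diagram of the CAC circuit.

Scanning TGF-beta at fixed MEKi/Rosi reveals the threshold structure of
the conversion: the mesenchymal branch is born near 3.2, the P2 and A
branches near 3.9 and 4.1, the P1 branch near 4.3, and above ~7.5 only
the mesenchymal state survives.  A coarse grid (step 0.1) keeps this
example quick; halve the step for threshold reporting at +-0.05.
"""
import numpy as np

from caclandscape import bifurcation_scan, load_cac_network

net = load_cac_network(MEKI=0.02, ROSI=1.5)
values = np.arange(2.5, 8.01, 0.1)
diag = bifurcation_scan(net, "TGFB", values, n_fresh_starts=12,
                        n_starts_first=80, seed=3)

print("TGFB   #stable  phenotypes")
for v, aset in list(zip(diag.values, diag.attractor_sets))[::5]:
    print(f"{v:5.2f}  {aset.n_stable:7d}  {','.join(sorted(aset.labels()))}")
print("\nfolds (stable-branch count changes):")
for loc, before, after in diag.folds:
    print(f"  TGFB = {loc:.2f}: {before} -> {after} stable states")
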