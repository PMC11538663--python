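"""Find the stable cell states of the CAC circuit under a drug condition.

With moderate TGF-beta plus MEK inhibitor and rosiglitazone the circuit
is pentastable: epithelial (E), mesenchymal (M), two partial-EMT
intermediates (P1, P2) and the adipose state (A).  Each printed row is
one attractor with its marker levels; the phenotype label comes from the
marker rules (A has the top PPARgamma/C/EBPalpha, E the highest P53).
"""
import pandas as pd

from caclandscape import find_attractors, load_cac_network

net = load_cac_network(TGFB=4.3, MEKI=0.02, ROSI=1.5)
aset = find_attractors(net, n_starts=200, seed=7)

markers = ["P53", "miR145", "ZEB1", "SNAIL1", "MEK", "ERK", "RKIP",
           "PPARG", "CEBPA"]
rows = []
for p in aset.stable_points:
    rows.append({"phenotype": p.phenotype,
                 **{m: round(float(p.state[net.index(m)]), 3)
                    for m in markers}})
print(pd.DataFrame(rows).sort_values("phenotype").to_string(index=False))
print(f"\n{aset.n_stable} stable states; saddles found: "
      f"{len(aset.points) - aset.n_stable}")
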