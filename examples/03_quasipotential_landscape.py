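"""Build the quasi-potential landscape U = -ln Pss of the CAC circuit.

Each stable state contributes a product-form Gaussian (mean at the
attractor, variances from the linearized fluctuation relation).  The
mixture is projected two ways: onto the first two principal components,
where all five attractors of the pentastable condition appear as
separate local minima, and onto the (miR145, PPARgamma) gene pair,
which merges the three ZEB1-high states (they differ on RKIP/ERK and
C/EBPalpha rather than on these two axes) -- a reminder that the basin
count of a 2-D projection depends on the chosen coordinates.
"""
import numpy as np

from caclandscape import (build_landscape, count_minima, find_attractors,
                          load_cac_network, project_landscape)

net = load_cac_network(TGFB=4.3, MEKI=0.02, ROSI=1.5)
aset = find_attractors(net, n_starts=200, seed=7, include_unstable=False)
L = build_landscape(net, aset, D=0.01, weights="equal")

_, U_pc = project_landscape(L, "pca", grid_size=150, n_samples=40000, seed=0)
print(f"PC1/PC2 projection: {count_minima(U_pc)} local minima "
      f"(one per attractor)")

grids, U = project_landscape(L, ("miR145", "PPARG"), grid_size=200)
print(f"(miR145, PPARG) projection: {count_minima(U)} local minima "
      f"(ZEB1-high states overlap on this plane)")
for mom, w in L.components:
    i, j = net.index("miR145"), net.index("PPARG")
    print(f"  {mom.attractor.phenotype}: miR145={mom.mean[i]:.3f} "
          f"PPARG={mom.mean[j]:.3f}  weight={w:.3f}  "
          f"sigma=({mom.var[i]:.4f}, {mom.var[j]:.4f})")
print(f"gene-pair grid {U.shape}, U range "
      f"[{U.min():.2f}, {np.percentile(U, 99):.2f}]")
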