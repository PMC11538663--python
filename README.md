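# caclandscape

Quasi-potential landscape analysis and landscape control for
Hill-regulation gene networks, built around a model of induced
cancer–adipose conversion (CAC): the reprogramming of epithelial (E) and
mesenchymal (M) tumor cells into post-mitotic adipocytes (A) through
partial-EMT intermediates (P1, P2) by a combination of TGF-β, a MEK
inhibitor, and rosiglitazone.

## Who this is for

Computational/systems biologists who want to treat a cell-fate decision
circuit as a dynamical system end to end: enumerate its attractors,
trace bifurcations against a drug dose, construct the Waddington-style
quasi-potential, compute the most probable transition routes between
cell states, and rank drug targets by how much they re-shape the
landscape.

## The model

Each gene/protein/miRNA node follows

```
dX/dt = g_X · G − k_X · K · X,      Hs(Y; S, λ, n) = 1 + (λ−1) Yⁿ/(Sⁿ+Yⁿ)
```

where `G` and `K` are products of shifted-Hill factors `Hs` over the
incoming regulations (λ>1 activation, λ<1 inhibition) and drugs are
clamped input nodes. Stochasticity is additive noise with diffusion
coefficient `D`; the stationary density is approximated
self-consistently as a weighted mixture of per-attractor product-form
Gaussians (means at the attractors, variances `σ_i = −D/A_ii` from the
linearized fluctuation relation), and the landscape is `U = −ln P_ss`.
Transitions are scored by the Freidlin–Wentzell action
`S_T[φ] = ½∫₀ᵀ |φ̇ − F(φ)|² dt`, minimized over endpoint-pinned paths
(MAPs). Landscape control minimizes
`ΔS_A = Σ_src (S_src→A − S_A→src)` over the model's 189 free parameters
to find interventions that channel cells into the adipose basin.

The packaged CAC network (15 dynamical nodes, 3 drug inputs, 52
regulations) is a **synthetic reconstruction**: the wiring follows the
published circuit, and a calibration script
(`scripts/calibrate_network.py`) fits designated thresholds to the
published bifurcation structure. See `docs/methods.md` for what that
does and does not pin down.

## Worked example

```python
from caclandscape import find_attractors, load_cac_network, minimize_action

net = load_cac_network(TGFB=4.3, MEKI=0.02, ROSI=1.5)
aset = find_attractors(net, n_starts=200, seed=7)
print(sorted(aset.labels()))

E, A = aset.by_phenotype("E"), aset.by_phenotype("A")
path = minimize_action(net, E, A, N=61, T_values=(5.0, 10.0, 20.0))
print(round(path.action, 4), path.T)
```

prints

```
['A', 'E', 'M', 'P1', 'P2']
0.2448 20.0
```

The first line is the pentastable regime at moderate TGF-β with MEKi
and rosiglitazone: epithelial, mesenchymal, both partial-EMT
intermediates, and the adipose state coexist. The second line is the
minimized Freidlin–Wentzell action of the most probable E→A conversion
route at the optimal horizon — small actions mean transitions the noise
can realize often (actions are meaningful relative to each other and to
`2D`, not in absolute units). The scripts in `examples/` walk through
each capability the same way: attractors and phenotype labels,
bifurcation scans, landscape projections, transition paths, landscape
control, Langevin occupancies, and synthetic expression data.

A thin CLI mirrors the library:

```
caclandscape attractors --config cac --tgfb 4.3 --meki 0.02 --rosi 1.5
caclandscape bifurcate --param TGFB --from 0 --to 10 --step 0.05
caclandscape map --from E --to A --tgfb 4.3 --meki 0.02 --rosi 1.5
```

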