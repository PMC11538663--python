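# Methods

## Model

Every node of the regulatory circuit evolves as

    dX/dt = g_X · G − k_X · K · X

with basal synthesis rate `g_X` (concentration/time), degradation rate
`k_X` (1/time), and regulation terms `G` and `K` that are products of
shifted Hill factors over the incoming edges acting on the synthesis or
the degradation side respectively:

    Hs(Y; S, λ, n) = 1 + (λ − 1) · Yⁿ / (Sⁿ + Yⁿ).

`Hs` equals 1 at `Y = 0` and approaches `λ` at saturation, so `λ > 1` is
activation and `λ < 1` inhibition; `S` is the half-effect threshold and
`n` the Hill cooperativity. Drug species (TGF-β, a MEK inhibitor,
rosiglitazone) are *input nodes*: they regulate targets through the same
Hill factors but are clamped at configured concentrations and carry no
dynamics and no noise. All concentrations and rates are dimensionless
model units of order one; the TGF-β axis spans 0–10 so that the reported
threshold values are directly comparable.

Stochasticity is additive Langevin noise, `dx = F(x) dt + √(2 D dt) η`,
with a constant isotropic diffusion coefficient `D`
(concentration²/time). The modeling tradition this package follows treats `D`
as a free smallness parameter; we default to `D = 0.01` relative to the
O(1) expression scales, exposed everywhere as an argument.

## The packaged CAC network (synthetic reconstruction)

`caclandscape/data/cac_network_synthetic.yaml` encodes the
cancer–adipose conversion circuit: 15 dynamical nodes (SNAIL1, ZEB1,
miR-200, miR-145, miR-34, P53, MDM2, LIN28, LET7, BACH1, RKIP, MEK, ERK,
PPARγ, C/EBPα), 3 drug inputs, and 52 active regulations. The topology
follows the published circuit description — the p53/microRNA–EMT-TF
core, the RKIP/LIN28/let-7/BACH1 metastasis module, the MAPK cascade
with ERK self-activation *and* self-inhibition, and the PPARγ–C/EBPα
positive feedback — but the kinetic constants are **not** the published
ones (those tables are not redistributable). Instead,
`scripts/calibrate_network.py` constructs the network with hand-chosen
order-one parameters and then calibrates five designated threshold
parameters (secant iteration on continuation-measured fold locations)
against the published TGF-β bifurcation structure:

| fold (TGF-β scan at MEKi = 0.02, Rosi = 1.5) | target | achieved |
|---|---|---|
| mesenchymal (M) branch born | 3.2 | 3.19 |
| P2 branch born | 3.9 | 3.91 |
| adipose (A) branch born | 4.1 | 4.09 |
| P1 branch born | 4.3 | 4.31 |
| last non-M branch dies (M-only regime) | 7.5 | 7.46 |

and verifies the drug-condition attractor counts (monostable E without
drugs; E+M with TGF-β alone; E+M+P1 adding MEKi; the five-state regime
adding Rosi; monostable M at high TGF-β) and the combination-drug
interventions (below). Upper branch edges that the calibration does not
drive: the A branch dies at ≈ 4.44, the E branch persists to ≈ 5.0 and
P2 to ≈ 5.2 — the qualitative ordering matches the published narrative
but these three numbers are emergent rather than fitted.

The scan baseline (MEKi = 0.02, Rosi = 1.5) is our choice: it makes the
five-state scan window and the five-state drug condition one consistent
parameterization. The optional TGF-β autoregulation variant is a config
flag (`tgfb_autoregulation`) that promotes TGF-β to a dynamical node
with a tagged self-activation edge; it is off by default and untested
beyond loading.

Because the kinetics are reconstructed, agreement with the printed
thresholds demonstrates that the *pipeline* (multistart attractor
search, continuation, fold detection, phenotype rules) reproduces the
published analysis on a faithfully structured model — it is not an
independent re-estimate of the published parameter values.

## Attractor search and bifurcation scans

Stable states are found by a multistart protocol: Latin-hypercube
initial conditions over `[0, 2·scale]` per coordinate (the scale is the
invariant-box bound `g/k · max G / min K`), forward LSODA integration in
chunks until the flow is nearly stationary, then Newton polishing of the
root on the dynamical coordinates. Points closer than a relative L∞
merge tolerance of 1e−3 are deduplicated, keeping the smaller residual.
Stability is the sign of the largest real part of the Jacobian spectrum
(analytic Jacobian throughout). Saddles are sought by Newton iteration
from midpoints of stable-state pairs and flagged.

Bifurcation scans combine Newton continuation of the previous grid
point's attractors with a fresh multistart batch per point (newborn
branches have small basins near their fold, so pure continuation would
miss births and pure multistart would be slow). Folds are reported as
midpoints of the grid cells where the stable count changes; at the
default step 0.05 this brackets each fold to ±0.025 plus any detection
lag of the newborn branch's basin.

## Phenotype rules

Labels follow the marker logic of the circuit: **A** — PPARγ and C/EBPα
above their high cutoffs (checked first, so interventions that force
ZEB1 high while saturating PPARγ still classify as adipose); **P2** —
ZEB1-high background with elevated C/EBPα; **M** — ZEB1 and ERK high;
**P1** — ZEB1 high with ERK shut off (RKIP re-expressed); **E** — P53
and miR-145 high; otherwise unclassified. Default mode uses absolute
cutoffs calibrated to the packaged model's scales (robust for the
monostable and bistable sets that drug scans routinely produce); a
z-score mode (cutoffs on per-marker z-scores across the stable set) is
available for parameterizations on other scales. When both
intermediates are present, P2 is the one with higher PPARγ; a lone
intermediate is distinguished by ERK.

## Mean-field quasi-potential

Around each stable attractor the stationary density is approximated as
a product of per-coordinate Gaussians: means at the attractor, and
variances from the diagonal restriction of the fluctuation (Lyapunov)
relation `0 = σAᵀ + Aσ + 2D·I`, i.e. `σ_i = −D / A_ii`. If some
diagonal Jacobian entry is non-negative at a stable point (possible
with strong rotational coupling) the diagonal of the full Lyapunov
solution is used and flagged. The steady state is the weighted mixture
over attractors and `U = −ln P_ss`.

Mixture weights are a modeling choice the underlying approximation does
not fix; three policies are provided:

* `occupancy` (default): long-run basin occupancy estimated by the
  Langevin ensemble. At very small `D` transitions are rare, so this
  reflects finite-horizon occupancy from the ensemble's initial
  distribution rather than the true stationary weights.
* `equal`: convenient for symmetric systems and quick looks.
* `action`: stationary distribution of the master equation with rates
  `∝ exp(−S_ij / 2D)` built from the pairwise minimized actions — the
  Freidlin–Wentzell small-noise weights. ln-weight differences scale as
  1/D, which is the scaling property the tests check on the tilted
  double well.

Projections onto named coordinate pairs are exact marginals of the
product-form mixture; the principal-component projection samples the
mixture, fits/uses a 2-column basis, and applies a Gaussian KDE before
taking −ln. The default grid is 200×200 spanning 1.2× the attractor
extent (plus 4σ Gaussian tails). On the packaged CAC model the five
attractors of the pentastable condition all separate on the PC1/PC2
projection; single gene-pair projections can merge states that differ
mainly on other axes (in this reconstruction M, P1 and P2 nearly
coincide on the (miR145, PPARγ) plane because the intermediates are
distinguished by RKIP/ERK and C/EBPα rather than by PPARγ level).

## Transition paths

The Freidlin–Wentzell action of a discretized path uses a
segment-midpoint scheme, `S = (h/2) Σ |v_i − F(m_i)|²` with
`v_i = (φ_{i+1} − φ_i)/h`, whose gradient with respect to the interior
points is analytic through the Jacobian. Minimum action paths pin both
endpoints, start from linear interpolation (optionally through an
intermediate attractor), and run L-BFGS-B with non-negativity bounds
for concentration systems. Because transitions between attractors favor
long horizons while the action functional is defined at fixed `T`, the
horizon is swept geometrically (5, 10, 20, 40, 80 by default), each
sweep warm-starting from the previous optimum, stopping when
lengthening the horizon improves the action by less than 1e−4
relative; the minimizing `T` is kept and recorded on the path. Default
discretization is N = 101 points (N = 201 for the oracle tests; the
tests check that doubling N moves the double-well action by < 0.5%).

For 1-D and separable gradient systems `F = −V′` the minimized uphill
action is `2·[V(saddle) − V(start)]`; this closed form anchors the
entire test suite (double-well action 0.5, tilted-well asymmetries,
symmetric toggle equality).

## Landscape control

The control objective sums forward-minus-reverse transition actions
toward the adipose state, `ΔS_A = Σ_src (S_src→A − S_A→src)` over the
sources E, M, P1, P2; minimizing it deepens the A basin. Source states
absent at an iterate contribute 0 — a vanished tumor state is the
desired outcome and must not penalize the objective; a vanished target
A is penalized heavily so the optimizer never accepts it. The search
runs bound-constrained L-BFGS-B with finite-difference gradients
(objective evaluations are expensive but low-dimensional gradients are
informative even near the attractor-birth discontinuities, where the
best evaluated point is retained) in 7 jittered restarts
(restart 0 exactly at baseline), each with a configurable evaluation
budget; bounds default to [base/10, base×10] with Hill exponents
additionally confined to [1, 6]. Sensitivities are the across-restart
average of `(p_opt − p_base)/p_base`, ranked by magnitude with the sign
retained; Hill exponents and fold changes stay in the search but are
flagged non-druggable in all reports. The exact objective recomputes
MAPs per iterate; a `exact_actions=False` surrogate scores straight-line
paths with the same quadrature (no inner optimization), trading
accuracy for an order of magnitude in speed.

The full CAC search space enumerates 189 free parameters: 2 rates × 15
nodes + 3 (λ, S, n) × 52 regulations + 3 drug levels. The reported
combination interventions act on it directly:
500× (g_ZEB1, Rosi) from the drug-free baseline collapses the attractor
set to a single adipose state, while 500× (g_SNAIL1, Rosi) collapses it
to a single mesenchymal state with no adipose attractor — in the model
because saturating SNAIL1 crushes the PPARγ/C/EBPα and RKIP switches
through its inhibitory edges, while saturating ZEB1 does not.

## Langevin oracle

Euler–Maruyama with reflecting boundary at zero for concentration
coordinates (inputs are clamped and receive no noise), default
`dt = 0.01`; the tests verify that the noise-free limit reproduces the
ODE solution and that stationary statistics match closed forms within
sampling error. Basin occupancy assigns post-burn-in samples (default
burn-in 20%) to the nearest attractor in rescaled state space
(per-coordinate spread of the attractor means, floored at 5% of the
system scale); samples farther than a cutoff from every attractor are
reported as a transient fraction rather than forced into a basin.
Blow-ups abort with a diagnostic instead of returning garbage.

## Synthetic data

The toy factory provides systems with closed-form facts used as test
oracles: the OU process (variance `D/k`), the symmetric and tilted
double wells (minima ±1, barrier 1/4), the two-gene toggle switch, and
the fold normal form `dx/dt = r + x²`. The toggle's default parameters
(g = 4, k = 1, λ = 0.1, S = 2, n = 4) place its wells ≈3.3 units apart
with transition action ≈1.5, so at the default `D = 0.01` it sits deep
in the small-noise regime the mean-field comparisons assume; weaker
parameterizations drift into visibly anharmonic tails. The expression generator
emulates cluster-structured bulk transcriptomics: per-gene state means
taken from model attractors and i.i.d. multiplicative log-normal noise
(`exp(ln μ + ε)`, `ε ~ N(0, sd²)`, default sd 0.3 — a realistic bulk
RNA-seq dispersion on the log scale). Zero noise reproduces the means
exactly; non-positive means are offset by a logged pseudocount.
Model-vs-data comparisons z-score each gene across states on both sides
before differencing/correlating; gene-name mapping between model nodes
and data symbols is an explicit dictionary argument.

What the generator does *not* emulate: count noise and library-size
variation, gene-gene correlation within a state beyond the shared mean,
batch effects, or any read-level structure. Passing clustering and
comparison tests therefore shows the analysis logic is correct on data
with the assumed mean/noise structure, not that it is robust to real
RNA-seq artifacts.

## Problem sizes and numerical defaults

The shipped analyses use multistart sizes of 150–300 starts per
condition (attractor counts saturate well below 100 starts on this
model), bifurcation grids of 201 points at step 0.05 with 20–24 fresh
starts per point, Langevin ensembles of 200–500 trajectories, and
N = 41–201 path points depending on whether the path feeds an
optimizer loop or a reported number. Determinism: every stochastic
component takes an explicit seed; the CLI derives per-stage seeds from
a single manifest seed by hashing.

## Known limitations

* The packaged kinetics are calibrated reconstructions; quantities not
  pinned by calibration (absolute expression levels, exact upper branch
  edges, action magnitudes) should not be read as predictions of the
  published model.
* The mean-field Gaussian mixture ignores covariances and basin
  anharmonicity; it is accurate near attractors at small `D` and is
  cross-checked against Langevin histograms only there.
* Occupancy-based weights are finite-horizon estimates at small `D`.
* ΔS_A optimization over all 189 parameters with exact per-iterate MAPs
  is computationally heavy; the surrogate objective or a druggable-only
  parameter subset is recommended for exploration.
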