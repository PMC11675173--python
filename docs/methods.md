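# Methods

This note documents the models implemented in `thalroute`, the
parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and the places where the design was
genuinely open.

## Connectome model and preprocessing

A subject's connectome is a dense symmetric matrix of nonnegative
integer streamline counts over labelled gray-matter parcels (the
packaged fixture ships the 90-region AAL ordering; any label set can be
supplied). The FA matrix, when present, is a parallel matrix sharing the
weight sparsity pattern; it is used exclusively as a statistical
covariate — edge existence is always decided by the streamline count.

* **Edge threshold** (`threshold_edges`, default 3): edges carried by
  fewer than 3 streamlines are treated as false-positive tracts and
  zeroed in both weights and FA. Idempotent; survivors keep their
  weight.
* **Hubs** (`identify_hubs`, default 20): degree strictly greater than
  20 after thresholding. Hubs are computed per subject by default — the
  hub-attached subnetwork therefore differs across subjects — but a
  fixed group-level hub list can be supplied (CLI `--hubs FILE`).
* **Hub-attached reading network**: induced subgraph over hubs ∪ the
  13-region left reading list. Weights are copied, never re-thresholded.
* **Mean FA covariate**: arithmetic mean over existing undirected edges,
  each counted once. Two scopes exist because the correlation analyses
  and the regression models condition on slightly different quantities:
  `"subnetwork"` (all edges of the hub-attached network; used for the
  partial correlations) and `"pivot-incident"` (edges touching the
  thalamus; the thalamocortical covariate of regression Model 1).

## Efficiency metrics

CC and LE are computed in binary and weighted modes; the weighted mode
is the default since streamline-count networks are weighted, but the
variant is recorded in every output because the choice is a genuine
degree of freedom:

* CC binary: 2·(closed triangles)/(k(k−1)); weighted: Onnela
  geometric-mean triangle intensity over max-normalized weights
  (delegated to networkx), which reduces to the binary value on uniform
  weights.
* LE: mean of inverse shortest-path lengths over the node's neighbour
  pairs, paths restricted to the neighbour-induced subgraph with the
  central node excluded (otherwise every pair has a trivial 2-step
  detour through it). Weighted path lengths use reciprocal
  max-normalized weights. Degree < 2 gives 0 by convention.

## Weight-to-length transform

Streamline counts are similarities; routing and geodesics need lengths.
Default `reciprocal` (d = 1/w), with `neglog`
(d = −log(w/w_max) + ε, ε = 1e-3) available. Both are strictly
decreasing in w; the transform name travels with the length matrix
because downstream costs depend on it. Geodesics are exact Dijkstra
(scipy); unreachable pairs are infinite.

## The routing model

Transition probabilities toward target t:
`P ∝ exp(−(λ(d_ij + g_jt) + d_ij))`, normalized over the neighbours j of
i. The exponent is implemented exactly in this form — d_ij
appears both λ-scaled and unscaled — because any algebraic
"simplification" changes the probabilities. Numerical notes:

* Rows are computed with a log-sum-exp shift (subtract the row-max
  exponent before exponentiation), so large λ cannot underflow a whole
  row; the softmax itself is shift-invariant.
* Neighbours with no finite geodesic to the target receive zero mass;
  nodes with no route at all are excluded from the transient set and
  listed on the model (`excluded`), since thresholded subject networks
  can fragment.
* The target row is absorbing.

**Transmission cost** is the expected walked distance of the absorbing
walk: with Q the transient block and b_i = Σ_j P_ij d_ij the expected
length of one step (the absorbing step included), the per-source costs
solve (I − Q)x = b. The solve is a direct LU factorization per
(target, λ) — never an explicit inverse — with a residual check at
1e-10, which matters for near-deterministic rows at large λ. One solve
yields all sources for a target, so full spectra cost one factorization
per (target, λ).

**Informational cost** is Σ over transient nodes of expected visits ×
KL(P row ‖ null row) in bits, computed by the same linear solve with
b = per-row KL. The null routing strategy is the λ = 0 walk
(P ∝ exp(−d_ij)) — the unbiased end of the spectrum — with a
uniform-over-neighbours null available by flag. A support violation
(biased row with mass where the null has none) is an error rather than
an infinity.

**λ grid.** The two published cost-averaging windows (ln λ ∈ [−5.1, 0.15]
for transmission, [−0.14, 2.76] for informational cost) do not fit
inside the published grid endpoints (−2.2 to 1.45), so the default grid is
ln λ ∈ [−5.1, 2.76] with 30 equally spaced points — the smallest
equally-spaced 30-point grid representing both windows — and the
[−2.2, 1.45] grid remains available as a preset. Neither convention is
guessed to be "intended"; both are explicit.

**Pivot aggregation.** `C_thal = Σ_r cost(r→thal) + Σ_r cost(thal→r)`
over reading regions r, per λ and per cost kind, as a sum (a per-region
mean is available by flag). Costs are directional by construction and
the asymmetry is preserved.

**Monte-Carlo oracle.** `simulate_walks` samples absorbing walks
(vectorised across walks) and reports the empirical mean distance, the
mean sampled log₂ probability ratio versus the null, and a
Rao–Blackwellized variant that accumulates the per-visit expected KL of
the occupied row. The last has the same expectation as the analytic
informational cost but far lower variance, so it is the quantity used
when 1%-level agreement is asserted. The walker shares nothing with the
linear-solve path beyond the transition matrix itself.

## Null networks and normalization

Randomized counterparts preserve the degree sequence exactly
(double-edge swaps, 10 per edge, with back-off on small dense graphs
where the requested swap count is infeasible), the edge-weight multiset
exactly (the original weights are reassigned to the new topology), and
node strengths approximately: weights are first rank-matched to the sum
of endpoint strengths, then refined by randomized exchange passes that
accept only swaps reducing total absolute strength error. On 90-node
synthetic connectomes the median relative strength deviation is ~1%
(the contract asserts ≤ 10%).

`‖C‖(λ)` divides the empirical pair-averaged cost by the ensemble mean
(mean, not median, by default — configurable) of the same quantity.
The efficient window is the set of grid points with `‖C‖ < 1`, strict,
so a ratio of exactly 1 is outside the window. Ensemble size defaults
to 500 per subject with smaller sizes used for desk-scale runs; the
size is always recorded. Windows may be data-driven (from the ratios)
or the fixed intervals above; which was used is recorded in the run
config.

## Statistics

* **Partial correlation**: residualize x and y on [intercept |
  covariates] by least squares, correlate the residuals; p from the t
  distribution with n − k − 2 degrees of freedom. Rank-deficient
  covariates raise an error naming the collinear columns.
* **Covariate sets**: age-standardized scores (SWE, PDE, passage
  comprehension) use {sex, mean FA, handedness}; RAN, which is a raw
  items-per-second rate, additionally includes age. A reduced age-only
  RAN set is selectable. Constant covariate columns (e.g. an
  all-right-handed cohort) are dropped with a warning.
* **Family-wise error**: Freedman–Lane max-statistic permutations. Score
  residuals (after covariate projection) are permuted with one shared
  seeded index permutation per iteration, re-residualized on the
  covariates, and the familywise max |partial r| forms the null;
  corrected p = (1 + #{max ≥ |r_obs|})/(1 + n_perm), floored at the
  single-test parametric p so corrected ≥ uncorrected always holds.
  Two-sided throughout; sex/handedness coded 0/1.
* **Hierarchical regression**: nested OLS (statsmodels) per block;
  ΔR² tested with F = (ΔR²/q)/((1 − R²_k)/(n − p_k − 1)). Blocks must
  not overlap; a rank-deficient cumulative design is an error.

## Synthetic cohorts

The generator emulates only the statistical structure the pipeline
consumes:

* **Topology**: a distance-free hub-core + peripheral-modules graph — a
  spanning ring (connectivity), a hub clique attached to the periphery
  until each planted hub clears degree 26, module-internal extra edges
  up to the target density (periphery capped at degree 18, so planted
  hubs are exactly the nodes passing the degree-20 rule), and
  sub-threshold weight-1–2 "false positive" edges that vanish at
  thresholding. Named regions (the reading list) are guaranteed ≥ 2 hub
  attachments so hub-attached subnetworks stay connected.
* **Weights**: integers uniform in [3, 60] on structural edges.
* **Subjects**: multiplicative log-normal weight jitter (σ = 0.25,
  rounded, never crossing the streamline threshold in either direction,
  so all subjects share one thresholded topology); per-edge FA around a
  subject-level mean drawn from N(0.45, 0.05) truncated to [0.3, 0.6].
* **Phenotypes**: age ~ U(9, 14), sex ~ Bernoulli(0.5), handedness
  ~ Bernoulli(0.95 right); standard scores with cohort-realistic means
  and SDs (≈ 93/21, 93/20, 90/13; RAN 1.87/0.48 items/s).
* **Planting**: the target score is
  `mean + sd·(ρ·z_metric + √(1−ρ²)·ε)` where z_metric standardizes the
  metric actually computed by the pipeline (not a latent proxy), so the
  planted population correlation is exactly ρ and recovery tests
  exercise the estimator used on real data. Default cohort: n = 64,
  90 nodes, 6 hubs, density 0.10, ρ = 0.4 on the hub-attached
  transmission cost vs the decoding score.

Not emulated: geometric embedding and distance-dependent connection
probabilities, realistic fiber geometry, test–retest noise,
subject-varying thresholded topology, or any diffusion-signal physics.
Passing tests therefore demonstrate the correctness and calibration of
the estimators under the generative model, not tractography validity on
real MRI.

## Problem sizes used in the shipped checks

Unit and pipeline tests run at deliberately small scales chosen as the
smallest sizes that exercise every code path: 8–12-node graphs against
brute-force oracles, 100,000-walk Monte-Carlo comparisons on 10-node
graphs, 40–50-member null ensembles on 90-node connectomes, 200
replicate 64-subject cohorts for the family-wise error calibration, and
an 8-subject / 30-node / 20-null / 200-permutation smoke run for
byte-level determinism of the CLI pipeline. The acceptance script runs
one 64-subject, 90-node cohort end to end.

## Known limitations

* Strength preservation in null networks is approximate by design
  (exact joint preservation of degrees, strengths and weights is
  infeasible in general); the achieved deviation is measured and
  asserted, not assumed.
* The informational cost of an unreachable pair is infinite and excluded
  from averaged curves with a logged count; fragmented subnetworks
  therefore contribute fewer pairs.
* The permutation scheme assumes exchangeable residuals under the null
  (Freedman–Lane); heavy-tailed score distributions are handled only as
  well as that assumption allows.
* Weighted CC/LE conventions vary across the literature; the shipped
  defaults (Onnela CC, reciprocal-length LE, max normalization) are
  recorded in every output so results are attributable to a convention.
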