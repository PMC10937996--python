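# Methods

## Model

The package operates on a pair `(A, x)`: a simple, undirected, connected
protein-interaction network with 0/1 adjacency `A`, and a strictly positive
expression vector `x` aligned to its nodes (normalised transcript
abundance, unitless). The mass-action weighting `W(x)_ij = a_ij x_i x_j`
models interaction propensity as the product of endpoint abundances. All
downstream quantities derive from this single construction:

* random walk `p_ij = a_ij x_j / Σ_k a_ik x_k` (scale-free in `x`);
* stationary distribution `π_i ∝ x_i (A x)_i`, exact for connected
  undirected graphs (verified in tests against power iteration to 1e-10);
* network entropy `S_R = Σ_i π_i S_i` with local entropies
  `S_i = −Σ_k p_ik log p_ik` (natural log, `0 log 0 = 0`);
* Forman-Ricci edge curvature with node weights `W_i = 1/deg(i)` and edge
  distances `d_ij = 1/(x_i x_j)`:
  `R_F(i,j) = W_i + W_j − √d_ij [W_i Σ_{k∈N(i)∖j} d_ik^{−1/2} + W_j Σ_{k∈N(j)∖i} d_kj^{−1/2}]`,
  which at product-form distances simplifies to sums of `√(x_k/x_j)` ratio
  terms. Both forms are implemented; their equivalence on product-form
  inputs is a standing test oracle.

The `1/deg` node weights bound each curvature bracket independently of
degree (for bounded expression ratios `|nodal curvature| ≤ 2(1 + √r_max)`),
so nodal curvature carries no mechanical degree dependence; local entropy,
by contrast, is bounded by `log deg(i)`. Total curvature
`Ric(x) = Σ_i π_i · mean of incident edge curvatures` deliberately mirrors
the structure of `S_R` so the two are comparable without sharing a degree
artefact.

Matching an expression table onto the network follows the standard
protocol: genes are translated to proteins (identity mapping when no table
is given), several genes mapping to one protein are averaged, unmatched
nodes are dropped, and the largest connected component of the matched
subgraph is retained. Zero or negative matched expression is a hard error;
an explicit `pseudocount` can be added, but never silently.

## k-star closed forms

For a star with `k` leaves, hub `i`, unit weights except one leaf `j` with
weight `eps`, all quantities are closed-form. The hub's stationary mass is
exactly 1/2 for every `(k, eps)`. Entropy
`S_R(eps)` is maximised at `eps = 1` for every `k`; total curvature is
maximised at `eps = 1` only for `k = 2`. For every `k ≥ 3` there is a
non-empty range of `eps > 1` on which the two measures move in opposite
directions, and the range widens with `k` — the two-regime result the toy
model exists to exhibit. Regime boundaries are computed from
central-difference derivatives on a dense grid (`eps` 0.01–10, step 0.001),
not from sampled correlations, to keep the boundary crisp.

One term in the published leaf nodal-curvature expression is inconsistent
with direct evaluation of the edge-curvature definition (a leaf has a
single incident edge, so its nodal curvature is that edge's value,
`1 + (1/k)(3 − k − √eps)`). The closed forms here use the directly derived
term; the general pipeline on constructed stars is the authority, and
closed forms match it to better than 1e-10 across the full grid.

## Normalised discrete Ricci flow

The flow `d_{t+Δt} = d_t + Δt (R_F^t − R̄ic) d_t` starts from the start
state's distances `d_0 = 1/(x_i^0 x_j^0)` and targets the end state's edge
curvature field `R̄ic`. Design choices:

* **Curvature inside the flow** is recomputed from the current distance
  field via the general weighted form each iteration, with node weights
  `1/deg` held fixed: after one step the distances leave the product
  manifold, and time-varying node weights would leave the update
  under-determined.
* **Step size.** The default grid is 0.001–0.1 in steps of 0.001; the
  selected `Δt` is the largest candidate whose first step keeps all
  distances strictly positive. The closed-form bound
  `Δt* = min 1/(R̄ic − R_F⁰)` over edges where the target exceeds the
  initial curvature is reported alongside; any `Δt < Δt*` provably keeps
  the first step positive, and the runner enforces positivity at every
  later step (raising with the offending edge and the bound otherwise).
* **Iteration count** defaults to 150 with no early stopping: the run
  length is chosen large enough that the curvature residual
  `max_e |R_F^t − R̄ic|` is flat at the end, and the diagnostic residual
  series (reported per iteration, with the final field's residual appended)
  lets callers judge convergence themselves. Residuals may be transiently
  non-monotone; tests assert final < initial, not monotonicity.
* **Gauge.** Forman curvature of a distance field is invariant under global
  rescaling of `d`. The flow therefore converges to the end state's
  curvature field, not to its weights: the limit's weight field `1/d_∞`
  matches `W(x^diff)` only up to a global scale set by the flow's own
  history. Predicted weighted networks `W_p = 1/d_t` are meaningful for
  ordering and shape comparisons, not for absolute weight recovery; node
  expression is never reconstructed from `d` (only `W = 1/d` is defined).

## Trajectory evaluation

A measured intermediate sample (a weighted network) is assigned the
trajectory iteration minimising Euclidean distance over unique undirected
edges (ties break to the earliest iteration; halving relative to the full
symmetric matrix is monotone and cannot change an argmin). The ordering
statistic is the two-sided Pearson correlation between closest-pass
iteration and true sample time, computed over intermediate time points; a
variant including the final point (which lands at the last iteration by
construction) is available behind a flag, since conventions differ on
whether to include it. The null model is the straight line in weight space
between the endpoint weighted networks, sampled at the same number of
points. Cohort statistics (entropy-curvature Pearson correlation, Fisher-z
comparison of two independent correlations) use the standard t- and
z-based two-sided tests with significance conventionally at 5%.

## Synthetic data

Three generators make every stage testable without downloads; all are
deterministic under their seed.

* **Stars** `(k, eps)` as above, node order `(l1..l_{k−1}, i, j)`.
* **Random PINs**: largest connected component of an Erdős–Rényi graph
  `G(n, mean_degree/(n−1))` with i.i.d. log-normal expression (log-sd 1).
  Default evaluation sizes are n = 25–100 nodes, mean degree 4 — large
  enough that curvature fields are heterogeneous, small enough that the
  full suite runs in seconds.
* **Time courses** between two states on a shared topology, in two labelled
  flavours: truths sampled from the flow's own trajectory at requested
  iteration fractions (for self-consistency: exact recovery at zero noise
  is asserted), and truths from an elementwise log-linear (geometric)
  interpolation of the weights, which is independent of the flow (for
  non-circular ordering checks). Optional multiplicative log-normal noise
  (log-sd `noise_sigma`, default evaluations use 1%) emulates measurement
  error on edge weights.

What these fixtures do *not* emulate: single-cell count noise (dropout,
library size), correlated expression changes along real lineages, and the
scale of real interactomes (~10⁴ nodes, ~1.5×10⁵ edges). Passing tests
demonstrate correctness of the mathematics and robustness of orderings at
desk scale, not biological validity on any particular data set. Note that
because a per-edge-monotone geometric path projects monotonically onto the
straight-line null, the null orders such synthetic courses essentially
correctly; the flow's advantage over the null appears on curved courses
such as its own noisy trajectory, mirroring the situation where a measured
course is evaluated under both candidate trajectories.

## Numerical choices

* Natural logarithms throughout; normalised entropy is base-invariant.
* Spectral radius for the maximal entropy rate via dense symmetric
  eigensolver below 200 nodes, Lanczos (`eigsh`) above.
* Stationary distribution via the closed form, never by iteration;
  `πP = π` is a test assertion (1e-10), not a solver.
* Edge fields store one value per undirected edge in canonical `(i < j)`
  lexicographic order; symmetry is structural.
* Degenerate inputs: graphs below 3 matched nodes are rejected; a 2-node
  network has entropy rate and maximal rate both 0 (deterministic walk);
  empty `E*` yields `Δt* = +∞` and step selection falls back to the grid
  maximum.

## Limitations

* Ollivier-Ricci curvature and triangle/2-cell-augmented Forman variants
  are out of scope, as are directed or signed networks.
* The flow assumes identical topology for start and end states; topology
  mismatch is a structural error, not something the package reconciles.
* Correlation-based ordering statistics with very few intermediate points
  (3–4) have low power; p-values are reported but the recovery tests rely
  on exact index matching where possible.
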