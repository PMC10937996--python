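# netricci

Differential-geometry tools for biological network rewiring: network
entropy, Forman-Ricci curvature and normalised discrete Ricci flow on
protein-interaction networks (PINs) weighted by gene expression.

Cellular differentiation rewires intra-cellular signalling. A practical way
to study this genome-wide is to weight an undirected PIN `G = (V, E)` with a
transcriptomic profile `x > 0` by mass action, `W(x)_ij = a_ij x_i x_j`,
and analyse the induced random walk `p_ij = a_ij x_j / Σ_k a_ik x_k`.
`netricci` computes, on this construction:

* **Network entropy** — the entropy rate `S_R = Σ_i π_i S_i` of the walk,
  with `S_i = −Σ_k p_ik log p_ik` and `π` the closed-form stationary
  distribution `π_i ∝ x_i Σ_j a_ij x_j`; optionally normalised by the
  topology's maximal entropy rate `log λ_max(A)`. Higher in stem-like and
  malignant states.
* **Forman-Ricci curvature** — on each edge, with node weights `1/deg` and
  edge distances `d_ij = 1/(x_i x_j)`,
  `R_F(i,j) = deg(i)⁻¹[1 − Σ_{k∈N(i)∖j} √(x_k/x_j)] + deg(j)⁻¹[1 − Σ_{k∈N(j)∖i} √(x_k/x_i)]`,
  aggregated to nodal means and a stationary-weighted total `Ric(x)`.
  Entropy and total curvature correlate positively in promiscuous
  ("stem-like") signalling regimes but can anticorrelate in committed ones
  — the package includes the closed-form k-star model that exhibits both
  regimes.
* **Normalised discrete Ricci flow** — iterates
  `d_{t+Δt} = d_t + Δt (R_F^t − R̄ic) d_t` from a start state's distances
  toward the curvature field `R̄ic` of an end state, producing a network
  rewiring trajectory whose points are predicted weighted networks
  `W_p = 1/d_t`. Step size is selected as the largest candidate in a grid
  that keeps first-step distances positive (the theoretical bound is
  `Δt* = min 1/(R̄ic − R_F⁰)` over edges where the gap is positive).
* **Trajectory evaluation** — closest-pass ordering of measured
  intermediate samples along a trajectory (Euclidean distance over edges),
  Pearson ordering statistics, a straight-line null trajectory, and
  Fisher-z comparison of correlations between cohorts.

## Worked example

```python
>>> import numpy as np
>>> from netricci import (StarParams, make_star, entropy_rate,
...                       compute_curvature, run_flow)
>>> stem = make_star(StarParams(k=5, eps=1.0))   # balanced star: max entropy
>>> diff = make_star(StarParams(k=5, eps=4.0))   # committed toward one leaf
>>> round(entropy_rate(stem), 4), round(entropy_rate(diff), 4)
(0.8047, 0.6931)
>>> round(compute_curvature(stem).total, 4), round(compute_curvature(diff).total, 4)
(0.4, 0.41)
>>> traj = run_flow(stem, diff)
>>> traj.dt_used, round(traj.residuals[0], 4), round(traj.residuals[-1], 6)
(0.1, 0.4, 0.00058)
```

As the star commits to its favoured leaf (`eps: 1 → 4`) entropy falls from
its maximum `(log 5)/2` while total curvature *rises* slightly — a k=5 star
at `eps > 1` sits in the anticorrelated "one for many" regime, which is
exactly why the two measures are complementary rather than interchangeable.
150 iterations of the flow shrink the worst-edge curvature residual from
0.4 to 5.8e-4, i.e. the rewired network's curvature field has converged
onto the end state's.

The same works from the shell on real files (edge list / GraphML / SIF
networks; TSV/CSV/MTX expression):

```sh
netricci entropy   --network pin.tsv --expr samples.tsv --out entropy.tsv
netricci curvature --network pin.tsv --expr samples.tsv --out curvature.tsv
netricci flow      --network pin.tsv --expr-start t0.tsv --expr-end tT.tsv --out flowdir/
netricci evaluate  --trajectory flowdir/ --truth t1.tsv --truth t2.tsv \
                   --times 12,24 --out ordering.json
```

## Layout

| module | contents |
| --- | --- |
| `netricci.network` | I/O, gene→protein matching, `MatchedNetwork`, `EdgeField`, walk operators |
| `netricci.entropy` | local entropies, entropy rate, topological maximum |
| `netricci.curvature` | edge / nodal / total Forman-Ricci curvature (two code paths) |
| `netricci.flow` | normalised discrete Ricci flow, step-size selection, diagnostics |
| `netricci.trajectory` | linear null, closest-pass ordering, cohort statistics |
| `netricci.kstar` | k-star closed forms and regime scans |
| `netricci.synthetic` | star / random-PIN / time-course generators |
| `netricci.cli` | `netricci` subcommands incl. `pipeline` |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
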