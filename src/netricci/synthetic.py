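"""Synthetic fixtures: star networks, random sparse PINs, and time courses.

Everything downstream is testable without external data through three
generators:

* :func:`make_star` — the analytically tractable k-star with one perturbed
  leaf weight, matching the closed forms in :mod:`netricci.kstar`;
* :func:`make_random_pin` — the largest connected component of a sparse
  Erdos-Renyi graph with log-normal expression, a stand-in for an
  expression-weighted interactome at desk scale;
* :func:`make_timecourse` — time-ordered "measured" weighted networks
  between two expression states with known ground-truth ordering, either
  sampled from the Ricci flow itself (for self-consistency checks) or from
  an independent elementwise log-linear (geometric) interpolation of the
  weights (for non-circular ordering tests), with optional multiplicative
  log-normal noise.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .flow import FlowConfig, run_flow
from .kstar import StarParams
from .network import EdgeField, MatchedNetwork, ValidationError, weighted_adjacency

__all__ = ["make_star", "make_random_pin", "make_timecourse", "Timecourse"]


def make_star(p: StarParams) -> MatchedNetwork:
    """Construct the k-star as a MatchedNetwork.

    Node order is (l1, ..., l_{k-1}, i, j): ordinary leaves first, then the
    hub i, then the distinguished leaf j with expression eps.
    """
    k, eps = p.k, p.eps
    ids = tuple(f"l{t}" for t in range(1, k)) + ("i", "j")
    n = k + 1
    hub = k - 1
    rows, cols = [], []
    for leaf in range(n):
        if leaf == hub:
            continue
        rows += [hub, leaf]
        cols += [leaf, hub]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    x = np.ones(n)
    x[-1] = eps
    return MatchedNetwork(ids, adj, x)


def make_random_pin(
    n: int, mean_degree: float, seed: int, sigma: float = 1.0
) -> MatchedNetwork:
    """Largest connected component of G(n, p) with log-normal expression.

    ``p = mean_degree / (n - 1)``; expression is drawn i.i.d. log-normal
    (log-scale sd ``sigma``), emulating strictly positive normalised counts.
    The returned network may have fewer than ``n`` nodes when the random
    graph is disconnected.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    graph = nx.gnp_random_graph(n, mean_degree / (n - 1), seed=int(seed))
    lcc = max(nx.connected_components(graph), key=len)
    if len(lcc) < 3:
        raise ValidationError(
            f"largest component has {len(lcc)} nodes; increase n or mean_degree"
        )
    keep = sorted(lcc)
    ids = tuple(f"g{v}" for v in keep)
    adj = sp.csr_matrix(
        nx.to_scipy_sparse_array(graph.subgraph(keep), nodelist=keep, dtype=float)
    )
    adj.data[:] = 1.0
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=0.0, sigma=sigma, size=n)[keep]
    return MatchedNetwork(ids, adj, x)


@dataclass(frozen=True)
class Timecourse:
    """Ground-truthed synthetic time course between two expression states.

    ``truths`` are weighted networks (EdgeFields) at the requested time
    fractions, ``true_times`` the fractions themselves, and for flow-sampled
    courses ``iterations`` the exact flow iterations the truths came from.
    """

    truths: list
    true_times: np.ndarray
    iterations: np.ndarray | None
    kind: str


def make_timecourse(
    net_start: MatchedNetwork,
    net_end: MatchedNetwork,
    sample_times,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    kind: str = "flow",
    config: FlowConfig | None = None,
) -> Timecourse:
    """Synthesize intermediate weighted-network measurements.

    ``sample_times`` are fractions strictly inside (0, 1) of the full course.
    ``kind="flow"`` samples the normalised Ricci flow trajectory between the
    states at the corresponding iterations; ``kind="geometric"`` samples the
    elementwise log-linear path W(s) = W0^(1-s) * WT^s, which is independent
    of the flow.  Multiplicative log-normal noise of log-scale sd
    ``noise_sigma`` is applied per edge when requested.
    """
    times = np.asarray(sample_times, dtype=float)
    if np.any(times <= 0) or np.any(times >= 1):
        raise ValidationError("sample_times must lie strictly inside (0, 1)")
    if kind not in ("flow", "geometric"):
        raise ValidationError("kind must be 'flow' or 'geometric'")

    if kind == "flow":
        config = config or FlowConfig()
        traj = run_flow(net_start, net_end, config)
        iters = np.maximum(1, np.rint(times * config.n_iter).astype(int))
        truths = [traj.predicted_weights(int(r)) for r in iters]
    else:
        W0 = weighted_adjacency(net_start)
        WT = weighted_adjacency(net_end)
        if not W0.same_edges(WT):
            raise ValidationError("states must share the same edge set")
        logW0, logWT = np.log(W0.values), np.log(WT.values)
        truths = [
            W0.with_values(np.exp((1.0 - s) * logW0 + s * logWT)) for s in times
        ]
        iters = None

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        truths = [
            w.with_values(
                w.values * rng.lognormal(0.0, noise_sigma, size=w.n_edges)
            )
            for w in truths
        ]
    return Timecourse(truths=truths, true_times=times, iterations=iters, kind=kind)
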