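"""Closed-form entropy and curvature for the k-star toy network.

The k-star has a hub i joined to k leaves; every node carries unit
expression except one distinguished leaf j with x_j = eps > 0.  The model is
small enough that the random walk, its stationary distribution, the network
entropy and the total Forman-Ricci curvature all have closed forms in
(k, eps), which makes it the canonical oracle for the general pipeline and
the setting in which the entropy/curvature two-regime result is proved:

* entropy S_R(eps) peaks at eps = 1 for every k;
* total curvature R_F(eps) peaks at eps = 1 only for k = 2;
* for every k >= 3 there is a non-empty range of eps > 1 on which S_R falls
  while R_F rises ("one for many" signalling), so the two measures
  anticorrelate there, and the range widens with k.

Lowering eps below 1 spreads signalling over the k-1 ordinary leaves at the
cost of j ("many for one"); both measures then fall together.

Note on the leaf nodal curvature: a leaf l has a single incident edge, so
its nodal curvature is R_F(i,l) = 1 + (1/k)(3 - k - sqrt(eps)); the general
pipeline is the authority for this term and the closed forms below match it
to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ValidationError

__all__ = [
    "StarParams",
    "star_transition_probs",
    "star_stationary",
    "star_local_entropy",
    "star_entropy",
    "star_nodal_curvature",
    "star_total_curvature",
    "regime_scan",
    "anticorrelated_range",
]


@dataclass(frozen=True)
class StarParams:
    """k leaves around one hub; the distinguished leaf j has weight eps."""

    k: int
    eps: float

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 2:
            raise ValidationError("k must be an integer >= 2")
        if not self.eps > 0:
            raise ValidationError("eps must be positive")


def star_transition_probs(p: StarParams) -> dict:
    """Hub/leaf transition probabilities of the weighted random walk."""
    k, eps = p.k, p.eps
    return {
        "hub_to_j": eps / (k + eps - 1),
        "hub_to_leaf": 1.0 / (k + eps - 1),
        "leaf_to_hub": 1.0,
    }


def star_stationary(p: StarParams) -> dict:
    """Stationary probabilities: the hub holds 1/2 regardless of (k, eps)."""
    k, eps = p.k, p.eps
    return {
        "hub": 0.5,
        "leaf": 1.0 / (2.0 * (k + eps - 1)),
        "j": eps / (2.0 * (k + eps - 1)),
    }


def star_local_entropy(p: StarParams) -> dict:
    """Local entropies: leaves are deterministic (0 nats), only the hub mixes."""
    k, eps = p.k, p.eps
    a = eps / (k + eps - 1)
    b = (k - 1.0) / (k + eps - 1)
    return {"hub": float(-a * np.log(a) - b * np.log(1.0 / (k + eps - 1))),
            "leaf": 0.0}


def star_entropy(p: StarParams | None = None, k: int | None = None,
                 eps=None) -> float | np.ndarray:
    """Network entropy rate of the k-star (nats).

    Accepts either ``StarParams`` or ``(k, eps)`` with eps possibly an array,
    for vectorised regime scans.  At eps = 1 this reduces to (1/2) log k.
    """
    if p is not None:
        k, eps = p.k, p.eps
    eps = np.asarray(eps, dtype=float)
    a = eps / (k + eps - 1)
    b = (k - 1.0) / (k + eps - 1)
    out = -0.5 * (a * np.log(a) + b * np.log(1.0 / (k + eps - 1)))
    return float(out) if out.ndim == 0 else out


def star_nodal_curvature(p: StarParams) -> dict:
    """Nodal Forman-Ricci curvatures of hub, ordinary leaf, and leaf j."""
    k, eps = p.k, p.eps
    se = np.sqrt(eps)
    hub = (1.0 / k) * (
        k
        + (1.0 / k) * (1.0 - (k - 1.0) / se)
        + ((k - 1.0) / k) * (3.0 - k - se)
    )
    j = 1.0 + (1.0 / k) * (1.0 - (k - 1.0) / se)
    leaf = 1.0 + (1.0 / k) * (3.0 - k - se)
    return {"hub": float(hub), "leaf": float(leaf), "j": float(j)}


def star_total_curvature(p: StarParams | None = None, k: int | None = None,
                         eps=None) -> float | np.ndarray:
    """Total Forman-Ricci curvature of the k-star.

    Stationary-weighted sum of the three nodal values; dominated by -sqrt(eps)
    terms as eps grows, hence unbounded below.  Vectorised over eps.
    """
    if p is not None:
        k, eps = p.k, p.eps
    eps = np.asarray(eps, dtype=float)
    se = np.sqrt(eps)
    hub = (1.0 / k) * (
        k
        + (1.0 / k) * (1.0 - (k - 1.0) / se)
        + ((k - 1.0) / k) * (3.0 - k - se)
    )
    nodal_j = 1.0 + (1.0 / k) * (1.0 - (k - 1.0) / se)
    nodal_leaf = 1.0 + (1.0 / k) * (3.0 - k - se)
    denom = 2.0 * (k + eps - 1.0)
    out = 0.5 * hub + (eps / denom) * nodal_j + ((k - 1.0) / denom) * nodal_leaf
    return float(out) if out.ndim == 0 else out


DEFAULT_EPS_GRID = np.round(np.arange(10, 10001) * 1e-3, 3)  # 0.01 .. 10


def anticorrelated_range(k: int, eps_grid: np.ndarray = DEFAULT_EPS_GRID):
    """The eps > 1 interval on which entropy and curvature move oppositely.

    Signs are taken from central-difference derivatives on the grid.  Returns
    ``(lo, hi, width)`` or ``None`` when no such interval exists (k = 2).
    """
    eps = np.asarray(eps_grid, dtype=float)
    dS = np.gradient(star_entropy(k=k, eps=eps), eps)
    dR = np.gradient(star_total_curvature(k=k, eps=eps), eps)
    mask = (eps > 1.0) & (dS * dR < 0)
    if not mask.any():
        return None
    lo, hi = float(eps[mask].min()), float(eps[mask].max())
    return lo, hi, hi - lo


def regime_scan(
    k_range=range(2, 21), eps_grid: np.ndarray = DEFAULT_EPS_GRID
) -> pd.DataFrame:
    """Dense (k, eps) scan of entropy, curvature and their co-movement sign.

    ``agree`` is +1 where the derivative signs of S_R and R_F coincide
    (correlated regime), -1 where they oppose (anticorrelated regime).
    """
    frames = []
    eps = np.asarray(eps_grid, dtype=float)
    for k in k_range:
        S = star_entropy(k=k, eps=eps)
        R = star_total_curvature(k=k, eps=eps)
        dS = np.gradient(S, eps)
        dR = np.gradient(R, eps)
        frames.append(
            pd.DataFrame(
                {
                    "k": k,
                    "eps": eps,
                    "S_R": S,
                    "R_F": R,
                    "dS_deps": dS,
                    "dR_deps": dR,
                    "agree": np.sign(dS * dR).astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
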