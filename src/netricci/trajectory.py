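"""Trajectory evaluation: null linear paths, closest-pass ordering, cohort
correlation statistics.

A rewiring trajectory is a sequence of predicted weighted networks (one
:class:`~netricci.network.EdgeField` per iteration).  To validate a
trajectory against measured intermediate samples, each true weighted network
is assigned the trajectory iteration that passes closest to it in Euclidean
distance over unique undirected edges; a trajectory that respects the
biology passes the true samples in time order, which is quantified by the
Pearson correlation between closest-pass iteration and true sample time.

The null model is the straight line in weight space between the start and
end weighted networks, sampled at equally spaced points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .network import EdgeField, ValidationError

__all__ = [
    "OrderingResult",
    "linear_trajectory",
    "edge_distance",
    "closest_pass_ordering",
    "correlate_entropy_curvature",
    "fisher_z_compare",
]


@dataclass(frozen=True)
class OrderingResult:
    """Closest-pass iterations per true sample and the ordering statistic.

    ``closest_pass[k]`` is the 1-based trajectory iteration nearest to the
    k-th truth; ``pearson_r``/``p_value`` test the association between
    closest-pass iteration and true sample time (two-sided, significance
    conventionally at the 5% level).
    """

    closest_pass: np.ndarray
    min_distance: np.ndarray
    true_times: np.ndarray
    pearson_r: float
    p_value: float


def linear_trajectory(
    W0: EdgeField, WT: EdgeField, n_points: int = 150
) -> list[EdgeField]:
    """Equally spaced points on the straight line from W0 to WT.

    Returns fields for t = 1..n_points; the last point equals WT exactly.
    """
    if not W0.same_edges(WT):
        raise ValidationError("endpoint fields must share the same edge index")
    delta = (WT.values - W0.values) / n_points
    out = [W0.with_values(W0.values + t * delta) for t in range(1, n_points)]
    out.append(WT.with_values(WT.values.copy()))
    return out


def edge_distance(Wa: EdgeField, Wb: EdgeField) -> float:
    """Euclidean distance over unique undirected edges (each counted once).

    Equals the Frobenius distance between the symmetric weight matrices
    divided by sqrt(2); the halving is monotone, so orderings by distance
    are unaffected by the convention.
    """
    if not Wa.same_edges(Wb):
        raise ValidationError("fields must share the same edge index")
    return float(np.linalg.norm(Wa.values - Wb.values))


def closest_pass_ordering(
    trajectory: Sequence[EdgeField],
    truths: Sequence[EdgeField],
    true_times: Sequence[float],
) -> OrderingResult:
    """Assign each true sample its nearest trajectory iteration and
    correlate the assignments with true sample time.

    ``trajectory[r-1]`` is the prediction at iteration r (1-based).  Argmin
    ties break toward the earliest iteration.  At least three truths are
    required for the Pearson test.
    """
    if len(trajectory) == 0:
        raise ValidationError("trajectory must be non-empty")
    true_times = np.asarray(true_times, dtype=float)
    if len(truths) != true_times.size:
        raise ValidationError("one time per truth required")
    if len(truths) < 3:
        raise ValidationError("need >= 3 evaluated time points for a correlation")
    dists = np.empty((len(truths), len(trajectory)))
    for a, truth in enumerate(truths):
        for r, pred in enumerate(trajectory):
            dists[a, r] = edge_distance(pred, truth)
    closest = dists.argmin(axis=1) + 1  # np.argmin takes the first minimum
    mins = dists[np.arange(len(truths)), closest - 1]
    if np.ptp(closest) == 0 or np.ptp(true_times) == 0:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(closest.astype(float), true_times)
    return OrderingResult(
        closest_pass=closest,
        min_distance=mins,
        true_times=true_times,
        pearson_r=float(r),
        p_value=float(p),
    )


def correlate_entropy_curvature(samples: Sequence[tuple]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) across (entropy, curvature) pairs."""
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("need >= 3 (entropy, curvature) pairs")
    r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(r), float(p)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p-value for the difference of two independent Pearson
    correlations via Fisher's z-transformation.

    z_k = atanh(r_k); the difference is compared against a normal with
    standard error sqrt(1/(n1-3) + 1/(n2-3)).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValidationError("correlations must satisfy |r| < 1")
        if n <= 3:
            raise ValidationError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(2.0 * stats.norm.sf(abs(z)))
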