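"""Mutual-information edge scores and the silhouette coefficient.

An edge's score compares two partitions of the samples: each gene's
expression vector, discretized on the shared bin grid, assigns every
sample to a module (its bin).  With modules ``U_1..U_|U|`` and
``V_1..V_|V|`` over ``N`` samples the mutual information is

    MI(U, V) = sum_i sum_j (|U_i n V_j| / N) * ln( N |U_i n V_j| / (|U_i| |V_j|) )

in nats, with empty intersections contributing zero.  The normalized
score divides by a mean of the two partition entropies so that 0 means
no association and 1 a perfect one; the arithmetic mean is the default
normalization, with geometric/min/max available.  A partition with zero
entropy (a constant gene) carries no information, so its NMI is defined
as 0.

The edge score defaults to the NMI over all samples.  An alternative
mode assigns samples to detected blobs, scores each subpopulation
separately and averages — retained because on real data the two modes
select nearly the same network, making the simpler all-samples score
the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .binning import OUT_OF_RANGE, BinGrid, bin_values
from .blob_detection import BlobSet, blob_radius_factor

__all__ = [
    "MIResult",
    "mutual_information",
    "entropy",
    "normalized_mi",
    "mi_result",
    "discretize_for_mi",
    "edge_nmi",
    "silhouette",
]

NMI_NORMS = ("arithmetic", "geometric", "min", "max")


@dataclass(frozen=True)
class MIResult:
    """Raw MI (nats), the two partition entropies, and the NMI."""

    mi_raw: float
    h_u: float
    h_v: float
    nmi: float


def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    nu, nv = ui.max() + 1, vi.max() + 1
    return np.bincount(ui * nv + vi, minlength=nu * nv).reshape(nu, nv)


def mutual_information(u, v) -> float:
    """MI between two module assignments, in nats.

    ``u`` and ``v`` are equal-length label vectors (any hashable dtype);
    labels only name modules, so any relabeling gives the same MI.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape or u.ndim != 1 or u.size == 0:
        raise ValueError(
            f"label vectors must be equal-length non-empty 1-D, got shapes "
            f"{u.shape} and {v.shape}"
        )
    nij = _contingency(u, v)
    n = nij.sum()
    ni = nij.sum(axis=1, keepdims=True)
    nj = nij.sum(axis=0, keepdims=True)
    nz = nij > 0
    p = nij[nz] / n
    log_term = np.log(n * nij[nz] / (ni @ np.ones_like(nj))[nz] /
                      (np.ones_like(ni) @ nj)[nz])
    return float(max(0.0, np.sum(p * log_term)))


def entropy(labels) -> float:
    """Shannon entropy of a module assignment, in nats."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mi_result(u, v, norm: str = "arithmetic") -> MIResult:
    """MI, entropies and NMI in one pass."""
    if norm not in NMI_NORMS:
        raise ValueError(f"norm must be one of {NMI_NORMS}, got {norm!r}")
    mi = mutual_information(u, v)
    h_u, h_v = entropy(u), entropy(v)
    if h_u == 0.0 or h_v == 0.0:
        return MIResult(mi_raw=0.0, h_u=h_u, h_v=h_v, nmi=0.0)
    if norm == "arithmetic":
        denom = 0.5 * (h_u + h_v)
    elif norm == "geometric":
        denom = math.sqrt(h_u * h_v)
    elif norm == "min":
        denom = min(h_u, h_v)
    else:
        denom = max(h_u, h_v)
    return MIResult(mi_raw=mi, h_u=h_u, h_v=h_v,
                    nmi=float(min(1.0, mi / denom)))


def normalized_mi(u, v, norm: str = "arithmetic") -> float:
    """NMI in [0, 1]; 0 when either partition has zero entropy."""
    return mi_result(u, v, norm=norm).nmi


def discretize_for_mi(expr: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Module labels (bin indices) for one gene's samples.

    Out-of-range or missing samples get the sentinel label
    ``OUT_OF_RANGE`` and must be excluded pairwise with the partner
    gene before scoring (see :func:`edge_nmi`).
    """
    return bin_values(np.asarray(expr, dtype=float), grid)


def edge_nmi(expr_a, expr_b, grid: BinGrid, mode: str = "all_samples",
             blobs: BlobSet | None = None, norm: str = "arithmetic",
             per_blob_min_samples: int = 10) -> float:
    """NMI score of one gene pair.

    all_samples
        NMI of the two bin-discretized vectors over every
        pairwise-complete, in-range sample.
    per_blob
        Each sample is assigned to the first detected blob (strongest
        response first; nearest center on ties) whose disk of radius
        ``sqrt(2)*sigma`` (``sigma`` for DoH) contains its binned
        coordinate.  Blobs holding fewer than ``per_blob_min_samples``
        samples are skipped; the score is the unweighted mean of the
        per-blob NMIs, falling back to all_samples when no blob
        qualifies.
    """
    expr_a = np.asarray(expr_a, dtype=float)
    expr_b = np.asarray(expr_b, dtype=float)
    if expr_a.size == 0 or expr_a.shape != expr_b.shape:
        raise ValueError("expression vectors must be equal-length and non-empty")
    la = discretize_for_mi(expr_a, grid)
    lb = discretize_for_mi(expr_b, grid)
    ok = (la != OUT_OF_RANGE) & (lb != OUT_OF_RANGE)
    if not ok.any():
        raise ValueError("no pairwise-complete in-range samples")
    la, lb = la[ok], lb[ok]
    if mode == "all_samples":
        return normalized_mi(la, lb, norm=norm)
    if mode != "per_blob":
        raise ValueError(f"unknown scoring mode {mode!r}")
    if blobs is None:
        raise ValueError("per_blob scoring requires a BlobSet")

    rf = blob_radius_factor(blobs.method)
    ordered = sorted(
        blobs.blobs, key=lambda b: (-b.response, b.row, b.col, b.sigma)
    )
    assignment = np.full(la.shape, -1, dtype=int)
    for i in range(la.size):
        r, c = float(lb[i]), float(la[i])  # row = gene_b bin, col = gene_a bin
        containing = [
            (bi, math.hypot(r - b.row, c - b.col))
            for bi, b in enumerate(ordered)
            if math.hypot(r - b.row, c - b.col) <= rf * b.sigma
        ]
        if containing:
            # first blob in response order; equal responses already sorted
            # deterministically, nearest center decides among those
            top = containing[0][0]
            tied = [t for t in containing
                    if ordered[t[0]].response == ordered[top].response]
            assignment[i] = min(tied, key=lambda t: t[1])[0]
    scores = []
    for bi in range(len(ordered)):
        members = assignment == bi
        if members.sum() < per_blob_min_samples:
            continue
        scores.append(normalized_mi(la[members], lb[members], norm=norm))
    if not scores:
        warnings.warn(
            "no blob held enough samples for per-blob scoring; "
            "falling back to all-samples NMI", stacklevel=2,
        )
        return normalized_mi(la, lb, norm=norm)
    return float(np.mean(scores))


def silhouette(points, labels) -> float:
    """Mean silhouette coefficient S of a clustered point set.

    Per point, ``s = (b - a) / max(a, b)`` with ``a`` the mean Euclidean
    distance to the point's own cluster (excluding itself) and ``b``
    the smallest mean distance to any other cluster; points in
    singleton clusters score 0.  S is the mean over points and lies in
    [-1, 1].
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1 and points.shape[1] > 1 and np.asarray(labels).size > 1:
        points = points.T
    labels = np.asarray(labels)
    if labels.size != points.shape[0]:
        raise ValueError("labels and points disagree in length")
    classes, inv = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    dist = squareform(pdist(points)) if points.shape[0] > 1 else np.zeros((1, 1))
    scores = np.zeros(labels.size)
    for i in range(labels.size):
        own = inv == inv[i]
        n_own = own.sum()
        if n_own == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(
            dist[i, inv == k].mean()
            for k in range(classes.size) if k != inv[i]
        )
        scores[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(scores.mean())
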