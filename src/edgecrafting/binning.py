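"""Discretization of bigenic expression data into 2-D count images.

Every gene pair ("edge") in a gene expression matrix defines a cloud of
points in the plane: each sample contributes the coordinate
``(expression of gene A, expression of gene B)``.  This module converts
that cloud into a square integer count image on a grid that is shared by
the whole matrix, so that images of different edges are directly
comparable and so that the same discretization also drives the mutual
information score.

The grid spans ``[0, domain_bound]`` where ``domain_bound`` is the
global expression maximum rounded up to the next integer; a resolution
``r`` (expression units per bin) must divide that integer exactly.  For
a matrix whose maximum is 18.89, resolutions 1, 0.5 and 0.25 give
19 x 19, 38 x 38 and 76 x 76 images respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinGrid",
    "EdgeImage",
    "OUT_OF_RANGE",
    "compute_bin_grid",
    "bin_value",
    "bin_values",
    "bin_edge",
    "normalize_image",
]

#: Sentinel returned by :func:`bin_value` for values outside the grid domain.
OUT_OF_RANGE = -1


@dataclass(frozen=True)
class BinGrid:
    """Shared 1-D discretization used for both image axes and MI binning.

    Parameters
    ----------
    domain_bound : int
        Upper edge of the grid (integer ceiling of the global expression
        maximum). The lower edge is always 0: only non-negative
        expression levels are considered.
    resolution : float
        Width of one bin in expression units. Must divide
        ``domain_bound`` exactly.
    n_bins : int
        Bins per dimension, ``domain_bound / resolution``.
    """

    domain_bound: int
    resolution: float
    n_bins: int

    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"grid needs at least 2 bins, got {self.n_bins}")
        if not math.isclose(self.n_bins * self.resolution, self.domain_bound,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                f"n_bins ({self.n_bins}) * resolution ({self.resolution}) "
                f"!= domain_bound ({self.domain_bound})"
            )


@dataclass
class EdgeImage:
    """Square count image of one gene pair.

    ``counts[i, j]`` is the number of samples whose gene-B expression
    falls in row bin ``i`` and gene-A expression in column bin ``j``;
    row/column 0 is the lowest-expression bin.
    """

    counts: np.ndarray
    n_samples_used: int
    n_samples_dropped: int

    def __post_init__(self) -> None:
        total = int(self.counts.sum())
        if total != self.n_samples_used:
            raise ValueError(
                f"count mass {total} != n_samples_used {self.n_samples_used}"
            )


def compute_bin_grid(global_max: float, resolution: float) -> BinGrid:
    """Build the shared grid from the matrix-wide expression maximum.

    The domain bound is ``ceil(global_max)``; ``resolution`` must divide
    it exactly, otherwise a :class:`ValueError` suggests the nearest
    valid resolution.

    >>> compute_bin_grid(18.89, 0.5).n_bins
    38
    """
    if global_max <= 0:
        raise ValueError(f"global_max must be positive, got {global_max}")
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    domain_bound = int(math.ceil(global_max - 1e-12))
    ratio = domain_bound / resolution
    n_bins = round(ratio)
    if not math.isclose(ratio, n_bins, rel_tol=0, abs_tol=1e-9) or n_bins < 2:
        nearest = domain_bound / max(round(ratio), 2)
        raise ValueError(
            f"resolution {resolution} does not divide the domain bound "
            f"{domain_bound} into an integer number of bins; nearest valid "
            f"resolution is {nearest:g}"
        )
    return BinGrid(domain_bound=domain_bound, resolution=resolution,
                   n_bins=int(n_bins))


def bin_value(v: float, grid: BinGrid) -> int:
    """Map one expression value to its bin index.

    Bins are half-open ``[k*r, (k+1)*r)`` except the top bin, which is
    closed so that ``v == domain_bound`` lands in bin ``n_bins - 1``.
    Values below 0 or above the domain bound return :data:`OUT_OF_RANGE`
    (a value, not an error: a grid may be reused on data that exceeds
    the range it was built from).
    """
    if not np.isfinite(v) or v < 0 or v > grid.domain_bound:
        return OUT_OF_RANGE
    idx = int(v / grid.resolution)
    return min(idx, grid.n_bins - 1)


def bin_values(values: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Vectorized :func:`bin_value`; returns int array with OUT_OF_RANGE sentinels."""
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~np.isfinite(values) | (values < 0) | (values > grid.domain_bound)
    idx = np.floor_divide(np.where(bad, 0.0, values), grid.resolution).astype(int)
    idx = np.minimum(idx, grid.n_bins - 1)
    idx[bad] = OUT_OF_RANGE
    return idx


def bin_edge(expr_a: np.ndarray, expr_b: np.ndarray, grid: BinGrid) -> EdgeImage:
    """Bin one gene pair's samples into a 2-D count image.

    ``expr_a`` indexes columns (x axis), ``expr_b`` rows (y axis).
    Samples with a missing or out-of-range value for either gene are
    dropped and tallied in ``n_samples_dropped``; the count mass of the
    image always equals the number of retained samples.
    """
    expr_a = np.asarray(expr_a, dtype=float)
    expr_b = np.asarray(expr_b, dtype=float)
    if expr_a.shape != expr_b.shape or expr_a.ndim != 1:
        raise ValueError(
            f"expression vectors must be equal-length 1-D, got shapes "
            f"{expr_a.shape} and {expr_b.shape}"
        )
    ia = bin_values(expr_a, grid)
    ib = bin_values(expr_b, grid)
    ok = (ia != OUT_OF_RANGE) & (ib != OUT_OF_RANGE)
    n = grid.n_bins
    flat = np.bincount(ib[ok] * n + ia[ok], minlength=n * n)
    counts = flat.reshape(n, n)
    used = int(ok.sum())
    return EdgeImage(counts=counts, n_samples_used=used,
                     n_samples_dropped=int(expr_a.size - used))


def normalize_image(img: EdgeImage, log_compress: bool = False) -> np.ndarray:
    """Scale a count image to [0, 1] intensities for blob detection.

    With ``log_compress`` the counts pass through ``ln(1+x)`` first,
    damping dense low-expression corners that can otherwise swamp the
    detectors. The output maximum is exactly 1.
    """
    if img.n_samples_used == 0:
        raise ValueError("cannot normalize an image with no samples")
    x = img.counts.astype(float)
    if log_compress:
        x = np.log1p(x)
    return x / x.max()
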