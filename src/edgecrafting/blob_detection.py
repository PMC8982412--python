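"""Scale-space blob detection on binned expression images.

A "blob" here is a bright, roughly circular region of the 2-D count
image of one gene pair — a subpopulation of samples with a distinct
bivariate expression location (typically one phenotype group).  Three
classic detectors are provided, each a search for local maxima of a
scale-normalized response over position and scale sigma:

LoG
    Negative Laplacian of Gaussian, ``-sigma^2 * (L_xx + L_yy)`` of the
    image smoothed at sigma.  The canonical detector.
DoG
    Difference of successively Gaussian-smoothed images with a
    geometric sigma ladder, rescaled by ``1/(sigma_ratio - 1)`` so it
    approximates the scale-normalized LoG.
DoH
    Determinant of the Hessian of the smoothed image,
    ``sigma^4 * (L_xx * L_yy - L_xy^2)``.  Insensitive to blobs smaller
    than about 3 bins across, which is why the downstream inclusion
    rule asks for agreement of only 2 of the 3 detectors.

Candidates are local maxima of the response stack over a 3x3x3
neighbourhood, thresholded on response, then greedily pruned so that no
two surviving blobs overlap (as disks of radius ``sqrt(2)*sigma`` for
LoG/DoG, ``sigma`` for DoH) by more than the configured fraction; the
stronger response survives, with exact ties broken by (row, col, sigma)
order so output is deterministic.  Smoothing uses reflective boundary
handling and blob centers may lie on image borders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "Blob",
    "BlobSet",
    "DetectorConfig",
    "METHODS",
    "detect_blobs",
    "detect_all_methods",
    "count_multimodal_methods",
    "passes_blob_criterion",
    "blob_radius_factor",
]

METHODS = ("LoG", "DoG", "DoH")


@dataclass(frozen=True)
class Blob:
    """One detected subpopulation: center (bin units) and scale."""

    row: float
    col: float
    sigma: float
    response: float = 0.0


@dataclass
class BlobSet:
    """All blobs one detector found in one edge image."""

    method: str
    blobs: list[Blob]

    def __len__(self) -> int:
        return len(self.blobs)


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables shared by the three detectors.

    ``max_sigma=None`` means "a quarter of the image side", resolved per
    image; all scales are in bin units.  ``response_threshold`` applies
    to the scale-normalized response of max-normalized images.
    """

    min_sigma: float = 1.0
    max_sigma: float | None = None
    num_sigma: int = 10
    sigma_ratio: float = 1.6
    response_threshold: float = 0.05
    overlap: float = 0.5
    min_blobs: int = 2

    def __post_init__(self) -> None:
        if self.max_sigma is not None and self.min_sigma >= self.max_sigma:
            raise ValueError("min_sigma must be < max_sigma")
        if self.num_sigma < 2:
            raise ValueError("num_sigma must be >= 2")
        if self.sigma_ratio <= 1:
            raise ValueError("sigma_ratio must be > 1")
        if self.response_threshold < 0 or not 0 <= self.overlap <= 1:
            raise ValueError("thresholds must be >= 0 and overlap in [0, 1]")

    def resolved_max_sigma(self, n_bins: int) -> float:
        ms = n_bins / 4 if self.max_sigma is None else self.max_sigma
        if ms <= self.min_sigma:
            ms = self.min_sigma * 2
        return ms


def blob_radius_factor(method: str) -> float:
    """Disk radius per unit sigma: sqrt(2) for LoG/DoG, 1 for DoH."""
    return 1.0 if method == "DoH" else math.sqrt(2.0)


def _log_sigmas(cfg: DetectorConfig, n_bins: int) -> np.ndarray:
    return np.linspace(cfg.min_sigma, cfg.resolved_max_sigma(n_bins),
                       cfg.num_sigma)


def _dog_sigmas(cfg: DetectorConfig, n_bins: int) -> np.ndarray:
    max_sigma = cfg.resolved_max_sigma(n_bins)
    k = int(math.log(max_sigma / cfg.min_sigma) / math.log(cfg.sigma_ratio)) + 1
    return cfg.min_sigma * cfg.sigma_ratio ** np.arange(k + 1)


def _log_stack(image: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    return np.stack([
        -(s ** 2) * ndimage.gaussian_laplace(image, s, mode="reflect")
        for s in sigmas
    ])


def _dog_stack(image: np.ndarray, sigmas: np.ndarray,
               sigma_ratio: float) -> np.ndarray:
    smoothed = [ndimage.gaussian_filter(image, s, mode="reflect")
                for s in sigmas]
    sf = 1.0 / (sigma_ratio - 1.0)
    return np.stack([(smoothed[i] - smoothed[i + 1]) * sf
                     for i in range(len(sigmas) - 1)])


def _doh_stack(image: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    layers = []
    for s in sigmas:
        lxx = ndimage.gaussian_filter(image, s, order=(2, 0), mode="reflect")
        lyy = ndimage.gaussian_filter(image, s, order=(0, 2), mode="reflect")
        lxy = ndimage.gaussian_filter(image, s, order=(1, 1), mode="reflect")
        layers.append((s ** 4) * (lxx * lyy - lxy * lxy))
    return np.stack(layers)


def response_stack(image: np.ndarray, method: str,
                   cfg: DetectorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Scale-normalized response cube and the sigma attributed to each layer."""
    n_bins = image.shape[0]
    if method == "LoG":
        sigmas = _log_sigmas(cfg, n_bins)
        return _log_stack(image, sigmas), sigmas
    if method == "DoG":
        sigmas = _dog_sigmas(cfg, n_bins)
        return _dog_stack(image, sigmas, cfg.sigma_ratio), sigmas[:-1]
    if method == "DoH":
        sigmas = _log_sigmas(cfg, n_bins)
        return _doh_stack(image, sigmas), sigmas
    raise ValueError(f"unknown blob detection method {method!r}")


def _local_maxima(stack: np.ndarray, threshold: float) -> np.ndarray:
    """Indices (scale, row, col) of 26-neighbourhood maxima above threshold."""
    footprint_max = ndimage.maximum_filter(stack, size=3, mode="nearest")
    peaks = (stack >= footprint_max) & (stack > threshold)
    return np.argwhere(peaks)


def _disk_overlap(d: float, r1: float, r2: float) -> float:
    """Area fraction of the smaller disk covered by the intersection."""
    if d >= r1 + r2:
        return 0.0
    rs, rl = min(r1, r2), max(r1, r2)
    if d <= rl - rs:
        return 1.0
    # lens area of two intersecting circles
    a1 = rs * rs * math.acos((d * d + rs * rs - rl * rl) / (2 * d * rs))
    a2 = rl * rl * math.acos((d * d + rl * rl - rs * rs) / (2 * d * rl))
    a3 = 0.5 * math.sqrt(max(0.0, (-d + rs + rl) * (d + rs - rl)
                             * (d - rs + rl) * (d + rs + rl)))
    return (a1 + a2 - a3) / (math.pi * rs * rs)


def _prune_overlaps(blobs: list[Blob], radius_factor: float,
                    overlap: float) -> list[Blob]:
    # stronger response wins; exact ties resolved by (row, col, sigma)
    order = sorted(blobs, key=lambda b: (-b.response, b.row, b.col, b.sigma))
    kept: list[Blob] = []
    for b in order:
        ok = True
        for k in kept:
            d = math.hypot(b.row - k.row, b.col - k.col)
            frac = _disk_overlap(d, radius_factor * b.sigma,
                                 radius_factor * k.sigma)
            if frac > overlap:
                ok = False
                break
        if ok:
            kept.append(b)
    return sorted(kept, key=lambda b: (b.row, b.col, b.sigma))


def detect_blobs(image: np.ndarray, method: str,
                 cfg: DetectorConfig | None = None) -> BlobSet:
    """Detect subpopulation blobs in one normalized edge image.

    Parameters
    ----------
    image : ndarray
        Square, finite, non-negative intensity image (normally the
        max-normalized edge image, so intensities lie in [0, 1]).
    method : {"LoG", "DoG", "DoH"}
    cfg : DetectorConfig, optional

    Returns
    -------
    BlobSet with blobs sorted by (row, col, sigma).
    """
    cfg = cfg or DetectorConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square 2-D, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    stack, sigmas = response_stack(image, method, cfg)
    peaks = _local_maxima(stack, cfg.response_threshold)
    candidates = [
        Blob(row=float(r), col=float(c), sigma=float(sigmas[s]),
             response=float(stack[s, r, c]))
        for s, r, c in peaks
    ]
    kept = _prune_overlaps(candidates, blob_radius_factor(method), cfg.overlap)
    return BlobSet(method=method, blobs=kept)


def detect_all_methods(image: np.ndarray,
                       cfg: DetectorConfig | None = None) -> dict[str, BlobSet]:
    """Run all three detectors on one image."""
    return {m: detect_blobs(image, m, cfg) for m in METHODS}


def count_multimodal_methods(blobsets: dict[str, BlobSet],
                             min_blobs: int = 2) -> tuple[dict[str, int], int]:
    """Count blobs per detector and how many detectors saw multimodality.

    A detector "sees multimodality" when it reports at least
    ``min_blobs`` (default 2) subpopulations.
    """
    missing = [m for m in METHODS if m not in blobsets]
    if missing:
        raise ValueError(f"missing blob sets for methods {missing}")
    counts = {m: len(blobsets[m]) for m in METHODS}
    n_multi = sum(1 for m in METHODS if counts[m] >= min_blobs)
    return counts, n_multi


def passes_blob_criterion(n_methods_with_multiple: int,
                          k_required: int = 2) -> bool:
    """Inclusion rule: at least ``k_required`` of the 3 detectors must
    each report more than one subpopulation."""
    if not 0 <= n_methods_with_multiple <= len(METHODS):
        raise ValueError(
            f"n_methods_with_multiple must be in [0, {len(METHODS)}]"
        )
    return n_methods_with_multiple >= k_required
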