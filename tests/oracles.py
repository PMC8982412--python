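"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package under test:
convolutions are explicit numpy correlations on symmetric-padded
arrays, scale-space maxima are found with naive loops, and mutual
information is the literal term-by-term double sum over module
intersections.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# mutual information: literal double sum over modules

def mi_double_sum(u, v) -> float:
    """MI(U,V) = sum_ij |Ui n Vj|/N * ln(N |Ui n Vj| / (|Ui| |Vj|))."""
    u = list(u)
    v = list(v)
    n = len(u)
    modules_u = {lab: {i for i, x in enumerate(u) if x == lab} for lab in set(u)}
    modules_v = {lab: {i for i, x in enumerate(v) if x == lab} for lab in set(v)}
    total = 0.0
    for ui in modules_u.values():
        for vj in modules_v.values():
            inter = len(ui & vj)
            if inter == 0:
                continue
            total += (inter / n) * math.log(n * inter / (len(ui) * len(vj)))
    return total


def entropy_direct(labels) -> float:
    labels = list(labels)
    n = len(labels)
    return -sum(
        (labels.count(lab) / n) * math.log(labels.count(lab) / n)
        for lab in set(labels)
    )


def silhouette_direct(points, labels) -> float:
    """Per-point (b - a)/max(a, b), averaged; singletons score 0."""
    points = np.asarray(points, dtype=float)
    labels = list(labels)
    scores = []
    for i, p in enumerate(points):
        own = [j for j, l in enumerate(labels) if l == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = float(np.mean([np.linalg.norm(p - points[j]) for j in own]))
        b = min(
            float(np.mean([np.linalg.norm(p - points[j])
                           for j, l in enumerate(labels) if l == other]))
            for other in set(labels) if other != labels[i]
        )
        scores.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# scale-space blob responses by explicit correlation

def _gaussian_kernel(sigma: float, order: int) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return phi * (-x / sigma ** 2)
    if order == 2:
        return phi * (x * x / sigma ** 4 - 1.0 / sigma ** 2)
    raise ValueError(order)


def _correlate_axis(img: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    r = len(kernel) // 2
    pad = [(r, r) if ax == axis else (0, 0) for ax in range(img.ndim)]
    padded = np.pad(img, pad, mode="symmetric")
    out = np.zeros_like(img, dtype=float)
    for k, w in enumerate(kernel):
        sl = [slice(None)] * img.ndim
        sl[axis] = slice(k, k + img.shape[axis])
        out += w * padded[tuple(sl)]
    return out


def smooth(img: np.ndarray, sigma: float,
           order: tuple[int, int] = (0, 0)) -> np.ndarray:
    out = _correlate_axis(img, _gaussian_kernel(sigma, order[0]), axis=0)
    return _correlate_axis(out, _gaussian_kernel(sigma, order[1]), axis=1)


def log_response(img: np.ndarray, sigma: float) -> np.ndarray:
    lap = smooth(img, sigma, (2, 0)) + smooth(img, sigma, (0, 2))
    return -(sigma ** 2) * lap


def dog_response(img: np.ndarray, s1: float, s2: float,
                 sigma_ratio: float) -> np.ndarray:
    return (smooth(img, s1) - smooth(img, s2)) / (sigma_ratio - 1.0)


def doh_response(img: np.ndarray, sigma: float) -> np.ndarray:
    lxx = smooth(img, sigma, (2, 0))
    lyy = smooth(img, sigma, (0, 2))
    lxy = smooth(img, sigma, (1, 1))
    return (sigma ** 4) * (lxx * lyy - lxy * lxy)


def scan_maxima(stack: np.ndarray, sigmas: np.ndarray,
                threshold: float) -> set[tuple[float, float, float]]:
    """All (row, col, sigma) whose response is a 26-neighbourhood maximum
    above threshold, found by exhaustive looping with clamped borders."""
    ns, h, w = stack.shape
    found = set()
    for s in range(ns):
        for r in range(h):
            for c in range(w):
                val = stack[s, r, c]
                if val <= threshold:
                    continue
                is_max = True
                for ds in (-1, 0, 1):
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            s2 = min(max(s + ds, 0), ns - 1)
                            r2 = min(max(r + dr, 0), h - 1)
                            c2 = min(max(c + dc, 0), w - 1)
                            if stack[s2, r2, c2] > val:
                                is_max = False
                if is_max:
                    found.add((float(r), float(c), float(sigmas[s])))
    return found


def blob_maxima(img: np.ndarray, method: str, sigmas: np.ndarray,
                sigma_ratio: float, threshold: float
                ) -> set[tuple[float, float, float]]:
    """Exhaustive scale-space maxima scan for one detector."""
    if method == "LoG":
        stack = np.stack([log_response(img, s) for s in sigmas])
        attributed = sigmas
    elif method == "DoG":
        stack = np.stack([
            dog_response(img, sigmas[i], sigmas[i + 1], sigma_ratio)
            for i in range(len(sigmas) - 1)
        ])
        attributed = sigmas[:-1]
    elif method == "DoH":
        stack = np.stack([doh_response(img, s) for s in sigmas])
        attributed = sigmas
    else:
        raise ValueError(method)
    return scan_maxima(stack, np.asarray(attributed), threshold)
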