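"""Independent brute-force oracles used by the unit and acceptance tests.

Each function recomputes a quantity by direct enumeration or explicit loops,
sharing no code path with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def sift_hard_descriptor(pixels: np.ndarray, r0: int, c0: int,
                         patch: int = 16) -> np.ndarray:
    """Raw 4x4x8 gradient-orientation histogram of one patch, hard binning,
    computed with explicit per-pixel loops (central differences, one-sided
    at the image border)."""
    h, w = pixels.shape
    hist = np.zeros((4, 4, 8))
    cs = patch // 4
    for py in range(patch):
        for px in range(patch):
            r, c = r0 + py, c0 + px
            if r == 0:
                gy = pixels[r + 1, c] - pixels[r, c]
            elif r == h - 1:
                gy = pixels[r, c] - pixels[r - 1, c]
            else:
                gy = (pixels[r + 1, c] - pixels[r - 1, c]) / 2.0
            if c == 0:
                gx = pixels[r, c + 1] - pixels[r, c]
            elif c == w - 1:
                gx = pixels[r, c] - pixels[r, c - 1]
            else:
                gx = (pixels[r, c + 1] - pixels[r, c - 1]) / 2.0
            mag = np.hypot(gx, gy)
            theta = np.arctan2(gy, gx) % (2 * np.pi)
            b = int(theta // (np.pi / 4)) % 8
            hist[py // cs, px // cs, b] += mag
    return hist.reshape(128)


def normalize_clamp(raw: np.ndarray, clamp: float = 0.2) -> np.ndarray:
    norm = np.linalg.norm(raw)
    if norm == 0:
        return np.zeros_like(raw)
    v = raw / norm
    v = np.minimum(v, clamp)
    return v / np.linalg.norm(v)


def nearest_center_counts(vectors: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Histogram of nearest-center assignments by exhaustive scan; ties to
    the lowest center index."""
    counts = np.zeros(len(centers), dtype=int)
    for v in vectors:
        best, best_d = 0, np.inf
        for j, c in enumerate(centers):
            d = float(np.sum((v - c) ** 2))
            if d < best_d - 1e-15:
                best, best_d = j, d
        counts[best] += 1
    return counts


def best_two_partition(points: np.ndarray) -> tuple[float, list[np.ndarray]]:
    """Exhaustive minimum of the 2-cluster k-means objective over all
    assignments of points to two non-empty clusters."""
    n = len(points)
    best_obj, best_centers = np.inf, None
    for bits in itertools.product([0, 1], repeat=n):
        if len(set(bits)) < 2:
            continue
        obj = 0.0
        centers = []
        for k in (0, 1):
            members = points[[i for i in range(n) if bits[i] == k]]
            mu = members.mean(axis=0)
            centers.append(mu)
            obj += float(np.sum((members - mu) ** 2))
        if obj < best_obj:
            best_obj, best_centers = obj, centers
    return best_obj, best_centers


def pairwise_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC by enumerating every (positive, negative) pair; ties half credit."""
    pos = [s for s, lbl in zip(scores, y) if lbl == 1]
    neg = [s for s, lbl in zip(scores, y) if lbl == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def wilcoxon_exact_by_enumeration(d: np.ndarray) -> tuple[float, float]:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns.

    Returns (W_plus of the observed differences, p). Zero differences must
    already be removed; |d| ties get midranks.
    """
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    n = len(d)
    w_obs = float(ranks[d > 0].sum())
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.array(w_all)
    p_low = np.mean(w_all <= w_obs + 1e-12)
    p_high = np.mean(w_all >= w_obs - 1e-12)
    return w_obs, min(1.0, 2.0 * min(p_low, p_high))


def nearest_pool_entry(center: np.ndarray, vectors: np.ndarray) -> tuple[int, float]:
    """Full scan for the pool vector closest to a center (ties to the
    earliest entry)."""
    best, best_d = 0, np.inf
    for j, v in enumerate(vectors):
        d = float(np.linalg.norm(v - center))
        if d < best_d - 1e-15:
            best, best_d = j, d
    return best, best_d
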