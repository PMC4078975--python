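"""Stability-selection feature ranking and traceback to image locations.

Bag-of-words features are ranked by how frequently an l1-regularized
logistic model selects them across many half-size subsamples drawn without
replacement, maximized over a grid of regularization strengths. A
highly-ranked feature is a visual word (a cluster center); since centers
need not coincide with any actual descriptor, the pool descriptor closest to
the center is located and traced back to its source image, gene and patch
location, which can then be rendered as an overlay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .codebook import Block, Codebook, DescriptorPool, layout_index_info
from .errors import ConfigurationError, DataError, ValidationError
from .imaging import ISHImage, N_CELLS, N_ORI
from .learning import l1_logistic_path

logger = logging.getLogger(__name__)

SELECTION_TOL = 1e-8    # |w_j| above this counts as "selected"


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityProfile:
    """Per-feature selection frequencies across the lambda grid."""

    lambda_grid: np.ndarray     # decreasing positive values, length L
    pi: np.ndarray              # (p, L) selection frequencies in [0, 1]
    n_subsamples: int
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def scores(self) -> np.ndarray:
        """Max selection probability across lambda values, per feature."""
        return self.pi.max(axis=1)

    @property
    def n_features(self) -> int:
        return self.pi.shape[0]


def default_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_points: int = 15, ratio: float = 0.01,
) -> np.ndarray:
    """Log-spaced grid from lambda_max down to ratio*lambda_max.

    lambda_max is the smallest penalty at which the l1 solution is exactly
    w = 0: with the bias at the prior log-odds b0, it equals the largest
    absolute component of the gradient of the loss at w = 0,
    max_j |sum_i x_ij r_i| with r_i = -y_i * sigmoid(-y_i b0).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("both classes required")
    b0 = np.log(n_pos / n_neg)
    r = -y * expit(-y * b0)
    lam_max = float(np.max(np.abs(X.T @ r)))
    if lam_max <= 0:
        raise DataError("design matrix has no association with the labels (all-zero gradient)")
    # tiny relative inflation: exactly at lam_max the null solution sits on
    # the subgradient boundary and a first-order solver only reaches it
    # asymptotically; a strict margin makes w = 0 exact
    lam_max *= 1.0 + 1e-4
    return np.geomspace(lam_max, ratio * lam_max, n_points)


def stability_selection(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_subsamples: int = 100,
    seed: int = 0,
    fit_tol: float = 1e-5,
    max_redraws: int = 100,
) -> StabilityProfile:
    """Selection frequencies of l1-logistic models over half-size subsamples.

    For each of ``n_subsamples`` rounds, floor(n/2) rows are drawn without
    replacement (redrawn, up to ``max_redraws`` times, if one class is
    missing) and an l1 path is fit along the grid; feature j counts as
    selected at a given lambda when |w_j| > 1e-8.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64).ravel()
    n, p = X.shape
    if n < 4:
        raise DataError("need at least 4 samples for half-size subsampling")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, dtype=np.float64)
    if np.any(lambda_grid <= 0) or np.any(np.diff(lambda_grid) >= 0):
        raise ConfigurationError("lambda_grid must be positive and strictly decreasing")

    rng = np.random.default_rng(seed)
    half = n // 2
    counts = np.zeros((p, len(lambda_grid)), dtype=np.int64)
    for _ in range(n_subsamples):
        for attempt in range(max_redraws):
            idx = rng.choice(n, size=half, replace=False)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise DataError(
                f"could not draw a two-class subsample of size {half} in {max_redraws} attempts"
            )
        thetas = l1_logistic_path(X[idx], y[idx], lambda_grid, tol=fit_tol)
        counts += (np.abs(thetas[:, :-1]) > SELECTION_TOL).T
    return StabilityProfile(
        lambda_grid, counts / float(n_subsamples), n_subsamples, seed,
        {"n": n, "p": p},
    )


def rank_features(profile: StabilityProfile, q: int) -> list[int]:
    """Top-q feature indices by max selection probability (ties to the
    lower index)."""
    if q < 0 or q > profile.n_features:
        raise ConfigurationError(f"q must be in [0, {profile.n_features}]")
    scores = profile.scores
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [int(i) for i in order[:q]]


# ---------------------------------------------------------------------------
# traceback
# ---------------------------------------------------------------------------

@dataclass
class FeatureTrace:
    """A ranked feature resolved to its closest pool descriptor."""

    feature_index: int
    section: str | None
    level: int
    word: int | None            # None for a zero-descriptor bin
    is_zero_bin: bool = False
    image_id: str = ""
    gene_id: str = ""
    location: tuple[int, int] = (0, 0)   # (row, col) at the feature's level
    distance: float = 0.0
    descriptor: np.ndarray | None = None


def traceback(
    feature_index: int,
    codebook: Codebook,
    pool: DescriptorPool,
    layout: list[Block] | None = None,
) -> FeatureTrace:
    """Locate the pool descriptor closest (l2) to a feature's cluster center.

    ``layout`` defaults to the single-section layout implied by the codebook.
    Zero-descriptor-bin features carry no center; a typed no-center trace is
    returned without searching. Ties go to the earliest pool entry.
    """
    if layout is None:
        layout = [Block(None, lvl, codebook.words(lvl)) for lvl in codebook.levels]
    section, level, kind, word = layout_index_info(layout, feature_index)
    if kind == "zero":
        return FeatureTrace(feature_index, section, level, None, is_zero_bin=True)
    center = codebook.centers[level][word]
    idx = pool.level_indices(level)
    if len(idx) == 0:
        raise DataError(f"pool has no descriptors at level {level}")
    dists = np.linalg.norm(pool.vectors[idx] - center[None, :], axis=1)
    j = idx[int(np.argmin(dists))]
    return FeatureTrace(
        feature_index, section, level, int(word),
        image_id=str(pool.image_ids[j]), gene_id=str(pool.gene_ids[j]),
        location=(int(pool.locations[j, 0]), int(pool.locations[j, 1])),
        distance=float(dists.min()), descriptor=pool.vectors[j].copy(),
    )


def _arrows_for(descriptor: np.ndarray, cell_size: float) -> list[tuple[float, float, float, float]]:
    """(dx_cell_center, dy_cell_center, dx, dy) arrows for each non-zero
    orientation bin; lengths proportional to bin magnitude."""
    hist = np.asarray(descriptor).reshape(N_CELLS, N_CELLS, N_ORI)
    vmax = hist.max()
    if vmax <= 0:
        return []
    arrows = []
    for cr in range(N_CELLS):
        for cc in range(N_CELLS):
            cy = (cr + 0.5) * cell_size
            cx = (cc + 0.5) * cell_size
            for k in range(N_ORI):
                v = hist[cr, cc, k]
                if v <= 0:
                    continue
                ang = 2.0 * np.pi * k / N_ORI
                length = 0.45 * cell_size * v / vmax
                # orientation angle is measured from +col toward +row
                arrows.append((cx, cy, length * np.cos(ang), length * np.sin(ang)))
    return arrows


def render_trace(
    trace: FeatureTrace,
    image: ISHImage,
    out_path: str | Path,
    patch_size: int = 16,
) -> Path:
    """Write an overlay: the image with the traced patch outlined, plus a
    zoomed panel with the 4x4 cell grid and per-bin orientation arrows."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    row, col = trace.location
    h, w = image.shape
    if not (0 <= row < h and 0 <= col < w):
        raise ValidationError(f"trace location {trace.location} outside image {image.shape}")
    half = patch_size // 2
    r0, c0 = row - half, col - half
    r0c, c0c = max(r0, 0), max(c0, 0)
    patch = image.pixels_float()[r0c: r0 + patch_size, c0c: c0 + patch_size]

    fig, (ax0, ax1) = plt.subplots(
        1, 2, figsize=(8, 4),
        gridspec_kw={"width_ratios": [2, 1]},
    )
    ax0.imshow(image.pixels_float(), cmap="gray", vmin=0, vmax=1)
    ax0.add_patch(Rectangle((c0 - 0.5, r0 - 0.5), patch_size, patch_size,
                            edgecolor="red", facecolor="none", lw=1.5))
    ax0.set_title(f"{trace.gene_id} {trace.image_id} level {trace.level}", fontsize=8)
    ax0.set_axis_off()

    ax1.imshow(patch, cmap="gray", vmin=0, vmax=1,
               extent=(0, patch_size, patch_size, 0))
    cell = patch_size / N_CELLS
    for k in range(N_CELLS + 1):
        ax1.axhline(k * cell, color="yellow", lw=0.6)
        ax1.axvline(k * cell, color="yellow", lw=0.6)
    if trace.descriptor is not None:
        for cx, cy, dx, dy in _arrows_for(trace.descriptor, cell):
            ax1.annotate(
                "", xy=(cx + dx, cy + dy), xytext=(cx, cy),
                arrowprops={"arrowstyle": "->", "color": "red", "lw": 0.8},
            )
    ax1.set_xlim(0, patch_size)
    ax1.set_ylim(patch_size, 0)
    ax1.set_axis_off()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
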