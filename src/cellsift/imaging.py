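"""Image I/O, multi-resolution pyramids and dense SIFT descriptor extraction.

An ISH (in situ hybridization) slice is a grayscale image together with a
binary *expression mask* marking the pixels judged to carry gene-expression
signal. Local texture is summarized by dense SIFT: 128-dimensional gradient
orientation histograms (4x4 spatial cells x 8 orientation bins) computed on a
regular grid of overlapping patches, keeping only descriptors whose patch
falls on foreground. Descriptors are extracted at four resolutions of a
factor-2 Gaussian pyramid so coarse and fine expression texture are both
represented.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

N_CELLS = 4          # spatial cells per patch side
N_ORI = 8            # orientation bins over [0, 2*pi)
DESCRIPTOR_DIM = N_CELLS * N_CELLS * N_ORI  # 128
CLAMP = 0.2          # component clamp after the first l2 normalization

SECTION_TYPES = ("coronal", "sagittal")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ISHImage:
    """One grayscale expression slice plus its binary foreground mask."""

    pixels: np.ndarray
    mask: np.ndarray
    gene_id: str = ""
    section_type: str = "coronal"
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.pixels.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape != self.mask.shape:
            raise ValidationError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )
        if not self.image_id:
            self.image_id = f"{self.gene_id}:{self.section_type}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixels_float(self) -> np.ndarray:
        """Pixels as float64 in [0, 1] (integer images divided by 255)."""
        if np.issubdtype(self.pixels.dtype, np.integer):
            return self.pixels.astype(np.float64) / 255.0
        return self.pixels.astype(np.float64)


@dataclass
class Descriptor:
    """A single dense SIFT descriptor (view into a :class:`DescriptorSet`)."""

    v: np.ndarray
    location: tuple[int, int]   # (row, col) of the patch center, 0-based
    level: int
    is_zero: bool
    image_id: str


@dataclass
class DescriptorSet:
    """Array-backed collection of descriptors from one image."""

    vectors: np.ndarray                 # (n, 128) float64
    locations: np.ndarray               # (n, 2) int, patch centers (row, col)
    levels: np.ndarray                  # (n,) int in {0..3}
    is_zero: np.ndarray                 # (n,) bool
    image_id: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if self.vectors.size == 0:
            self.vectors = self.vectors.reshape(0, DESCRIPTOR_DIM)
        self.locations = np.asarray(self.locations, dtype=np.int64).reshape(-1, 2)
        self.levels = np.asarray(self.levels, dtype=np.int64).ravel()
        self.is_zero = np.asarray(self.is_zero, dtype=bool).ravel()
        n = len(self.vectors)
        if not (len(self.locations) == len(self.levels) == len(self.is_zero) == n):
            raise ValidationError("descriptor arrays have inconsistent lengths")

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, i: int) -> Descriptor:
        return Descriptor(
            v=self.vectors[i],
            location=(int(self.locations[i, 0]), int(self.locations[i, 1])),
            level=int(self.levels[i]),
            is_zero=bool(self.is_zero[i]),
            image_id=self.image_id,
        )

    def counts_per_level(self) -> dict[int, int]:
        lvls, counts = np.unique(self.levels, return_counts=True)
        return {int(l): int(c) for l, c in zip(lvls, counts)}

    def nonzero(self) -> "DescriptorSet":
        keep = ~self.is_zero
        return DescriptorSet(
            self.vectors[keep], self.locations[keep], self.levels[keep],
            self.is_zero[keep], self.image_id, dict(self.params),
        )

    @staticmethod
    def empty(image_id: str = "", params: dict | None = None) -> "DescriptorSet":
        return DescriptorSet(
            np.empty((0, DESCRIPTOR_DIM)), np.empty((0, 2), int),
            np.empty(0, int), np.empty(0, bool), image_id, params or {},
        )

    @staticmethod
    def concatenate(sets: list["DescriptorSet"]) -> "DescriptorSet":
        if not sets:
            return DescriptorSet.empty()
        ids = {s.image_id for s in sets}
        if len(ids) > 1:
            raise ValidationError(f"cannot concatenate sets from images {sorted(ids)}")
        return DescriptorSet(
            np.vstack([s.vectors for s in sets]),
            np.vstack([s.locations for s in sets]),
            np.concatenate([s.levels for s in sets]),
            np.concatenate([s.is_zero for s in sets]),
            sets[0].image_id,
            dict(sets[0].params),
        )

    # -- serialization: columnar binary container (.npz) + JSON sidecar -----

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path, vectors=self.vectors, locations=self.locations,
            levels=self.levels, is_zero=self.is_zero,
        )
        sidecar = {"image_id": self.image_id, "params": self.params}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def load(path: str | Path) -> "DescriptorSet":
        path = Path(path)
        with np.load(path) as z:
            arrays = {k: z[k] for k in ("vectors", "locations", "levels", "is_zero")}
        sidecar_path = Path(str(path) + ".json")
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        return DescriptorSet(
            arrays["vectors"], arrays["locations"], arrays["levels"],
            arrays["is_zero"], meta.get("image_id", ""), meta.get("params", {}),
        )

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.vectors, columns=[f"v{i}" for i in range(self.vectors.shape[1])])
        df.insert(0, "is_zero", self.is_zero)
        df.insert(0, "level", self.levels)
        df.insert(0, "col", self.locations[:, 1])
        df.insert(0, "row", self.locations[:, 0])
        df.insert(0, "image_id", self.image_id)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_image_with_mask(
    image_path: str | Path,
    mask_path: str | Path | None,
    gene_id: str = "",
    section_type: str = "coronal",
    image_id: str = "",
    fallback_threshold: float | None = None,
) -> ISHImage:
    """Load a grayscale image and its binary expression mask.

    The mask is binarized as pixel>0 = foreground. When ``mask_path`` is None
    a simple threshold fallback may be enabled: pixels darker than
    ``fallback_threshold`` (stain = expression) become foreground.
    """
    pixels = np.asarray(Image.open(image_path).convert("L"))
    if mask_path is not None:
        mask = np.asarray(Image.open(mask_path).convert("L")) > 0
        if mask.shape != pixels.shape:
            raise ValidationError(
                f"mask shape {mask.shape} does not match image shape {pixels.shape}"
            )
    elif fallback_threshold is not None:
        mask = (pixels.astype(np.float64) / 255.0) < fallback_threshold
    else:
        raise ValidationError(
            f"no mask provided for {image_path} and threshold fallback disabled"
        )
    return ISHImage(pixels, mask, gene_id=gene_id, section_type=section_type,
                    image_id=image_id)


# ---------------------------------------------------------------------------
# pyramid
# ---------------------------------------------------------------------------

def build_pyramid(image: ISHImage, levels: int = 4, min_size: int = 1) -> list[ISHImage]:
    """Factor-2 Gaussian pyramid of ``levels`` resolutions.

    Level 0 is the original; each next level is the previous one smoothed with
    a Gaussian (sigma=1) and downsampled by taking every second pixel. The
    mask is downsampled with an "any contributing pixel foreground" rule so
    foreground is never eroded away by coarsening.
    """
    if levels < 1:
        raise ConfigurationError(f"levels must be >= 1, got {levels}")
    coarsest = min(image.shape) // 2 ** (levels - 1)
    if coarsest < min_size:
        raise ValidationError(
            f"image {image.shape} too small to hold a {min_size}-px patch at level {levels - 1}"
        )
    out = [image]
    for lvl in range(1, levels):
        prev = out[-1]
        smoothed = gaussian_filter(prev.pixels_float(), sigma=1.0)[::2, ::2]
        mask = _downsample_mask_any(prev.mask)
        out.append(ISHImage(smoothed, mask, gene_id=image.gene_id,
                            section_type=image.section_type,
                            image_id=image.image_id))
    return out


def _downsample_mask_any(mask: np.ndarray) -> np.ndarray:
    """2x2 block OR; odd trailing rows/cols contribute to the last block."""
    h, w = mask.shape
    hh, ww = (h + 1) // 2, (w + 1) // 2
    out = np.zeros((hh, ww), dtype=bool)
    for dr in (0, 1):
        for dc in (0, 1):
            block = mask[dr::2, dc::2]
            out[: block.shape[0], : block.shape[1]] |= block
    return out


# ---------------------------------------------------------------------------
# dense SIFT
# ---------------------------------------------------------------------------

def _spatial_weights(patch_size: int, mode: str) -> np.ndarray:
    """Per-cell spatial weight maps, shape (16, patch, patch).

    hard: each pixel contributes fully to its enclosing cell.
    soft: bilinear interpolation toward the 4x4 cell centers, multiplied by a
    Gaussian window (sigma = patch/2) centered on the patch.
    """
    cs = patch_size // N_CELLS
    idx = np.arange(patch_size)
    if mode == "hard":
        cell_of = idx // cs
        w1d = (cell_of[None, :] == np.arange(N_CELLS)[:, None]).astype(np.float64)
        gauss = np.ones((patch_size, patch_size))
    else:
        centers = (np.arange(N_CELLS) + 0.5) * cs - 0.5
        w1d = np.clip(1.0 - np.abs(idx[None, :] - centers[:, None]) / cs, 0.0, None)
        g = np.exp(-0.5 * ((idx - (patch_size - 1) / 2.0) / (patch_size / 2.0)) ** 2)
        gauss = g[:, None] * g[None, :]
    W = np.einsum("rp,cq->rcpq", w1d, w1d).reshape(N_CELLS * N_CELLS, patch_size, patch_size)
    return W * gauss


def _orientation_images(pixels: np.ndarray, mode: str) -> np.ndarray:
    """Per-orientation-bin gradient-magnitude images, shape (8, H, W).

    Gradients by central differences (one-sided at borders); orientation
    theta = atan2(gy, gx) in [0, 2*pi); bin width pi/4 with bin centers at
    k*pi/4. Soft mode splits each pixel's magnitude linearly between the two
    nearest bins; hard mode assigns it wholly to floor(theta / (pi/4)) mod 8.
    """
    gy, gx = np.gradient(pixels)
    mag = np.hypot(gx, gy)
    theta = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    binw = 2.0 * np.pi / N_ORI
    h, w = pixels.shape
    M = np.zeros((N_ORI, h * w))
    flat = np.arange(h * w)
    if mode == "hard":
        b = np.mod(np.floor(theta / binw).astype(np.int64), N_ORI)
        M[b.ravel(), flat] = mag.ravel()
    else:
        t = theta / binw
        b0 = np.floor(t).astype(np.int64)
        frac = t - b0
        b0 = np.mod(b0, N_ORI)
        b1 = np.mod(b0 + 1, N_ORI)
        M[b0.ravel(), flat] += (mag * (1.0 - frac)).ravel()
        M[b1.ravel(), flat] += (mag * frac).ravel()
    return M.reshape(N_ORI, h, w)


def extract_dense_sift(
    image: ISHImage,
    patch_size: int = 16,
    stride: int = 4,
    binning: str = "soft",
    level: int = 0,
    min_foreground_frac: float | None = None,
) -> DescriptorSet:
    """Dense SIFT descriptors on a regular grid, restricted to foreground.

    Patches are half-open ``[r, r+patch) x [c, c+patch)`` with top-left
    corners stepping by ``stride`` from (0, 0). Each raw histogram has
    4x4 cells x 8 orientation bins = 128 entries; non-zero histograms are
    l2-normalized, clamped at 0.2, and renormalized. A descriptor whose raw
    histogram is identically zero is flagged ``is_zero`` and kept as the zero
    vector. A descriptor is retained when the patch-center pixel is in the
    mask (optionally also requiring a minimum foreground fraction).
    """
    if patch_size % N_CELLS != 0:
        raise ConfigurationError(f"patch_size must be divisible by {N_CELLS}")
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    if binning not in ("hard", "soft"):
        raise ConfigurationError(f"unknown binning mode {binning!r}")
    params = {"patch_size": patch_size, "stride": stride, "binning": binning}

    h, w = image.shape
    if h < patch_size or w < patch_size:
        warnings.warn(
            f"image {image.image_id} ({h}x{w}) smaller than patch {patch_size}; "
            "returning empty descriptor set"
        )
        return DescriptorSet.empty(image.image_id, params)

    pixels = image.pixels_float()
    M = _orientation_images(pixels, binning)
    W = _spatial_weights(patch_size, binning)

    win = np.lib.stride_tricks.sliding_window_view(M, (patch_size, patch_size), axis=(1, 2))
    win = win[:, ::stride, ::stride]                       # (8, nR, nC, P, P)
    raw = np.einsum("bijpq,cpq->ijcb", win, W, optimize=True)   # (nR, nC, 16, 8)
    n_r, n_c = raw.shape[:2]
    raw = raw.reshape(n_r * n_c, DESCRIPTOR_DIM)

    rows = np.arange(n_r) * stride + patch_size // 2
    cols = np.arange(n_c) * stride + patch_size // 2
    centers = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)

    keep = image.mask[centers[:, 0], centers[:, 1]]
    if min_foreground_frac is not None:
        mwin = np.lib.stride_tricks.sliding_window_view(
            image.mask, (patch_size, patch_size)
        )[::stride, ::stride]
        frac = mwin.reshape(n_r * n_c, -1).mean(axis=1)
        keep &= frac >= min_foreground_frac
    raw = raw[keep]
    centers = centers[keep]

    norms = np.linalg.norm(raw, axis=1)
    is_zero = norms == 0.0
    vecs = np.zeros_like(raw)
    nz = ~is_zero
    if nz.any():
        v = raw[nz] / norms[nz, None]
        v = np.minimum(v, CLAMP)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        vecs[nz] = v

    return DescriptorSet(
        vecs, centers, np.full(len(vecs), level, dtype=np.int64), is_zero,
        image.image_id, params,
    )


def extract_multiresolution(
    image: ISHImage,
    levels: int = 4,
    patch_size: int = 16,
    stride: int = 4,
    binning: str = "soft",
    min_foreground_frac: float | None = None,
) -> DescriptorSet:
    """Dense SIFT at every level of the factor-2 pyramid, concatenated.

    Levels too small to hold one patch yield no descriptors (with a warning
    from :func:`extract_dense_sift`).
    """
    pyramid = build_pyramid(image, levels=levels)
    sets = [
        extract_dense_sift(img, patch_size=patch_size, stride=stride,
                           binning=binning, level=lvl,
                           min_foreground_frac=min_foreground_frac)
        for lvl, img in enumerate(pyramid)
    ]
    out = DescriptorSet.concatenate(sets)
    out.params = {"patch_size": patch_size, "stride": stride,
                  "binning": binning, "levels": levels}
    return out
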