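"""Visual-word codebooks: descriptor pooling, k-means, and bag-of-words.

Non-zero dense SIFT descriptors from the images of a two-class task are
sampled into a pool (optionally class-balanced, since the class sizes of the
enrichment tasks can be very unequal). The pool is partitioned by resolution
level and one k-means codebook is fit per level; cluster centers are the
"visual words". An image becomes a histogram counting, per level, how many of
its descriptors fall nearest to each word, plus one extra bin per level for
the zero (gradient-free) descriptors. With m words per level and 4 levels the
single-section feature has length (m+1)*4 — 2004 for the default m=500.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ValidationError
from .imaging import DescriptorSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# descriptor pool
# ---------------------------------------------------------------------------

@dataclass
class DescriptorPool:
    """Sampled non-zero descriptors with their provenance."""

    vectors: np.ndarray        # (n, d)
    image_ids: np.ndarray      # (n,) str
    gene_ids: np.ndarray       # (n,) str
    class_labels: np.ndarray   # (n,) str
    levels: np.ndarray         # (n,) int
    locations: np.ndarray      # (n, 2) int
    target_size: int = 0

    def __len__(self) -> int:
        return len(self.vectors)

    def per_class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.class_labels, return_counts=True)
        return {str(l): int(c) for l, c in zip(labels, counts)}

    def per_image_counts(self) -> dict[str, int]:
        ids, counts = np.unique(self.image_ids, return_counts=True)
        return {str(i): int(c) for i, c in zip(ids, counts)}

    def level_indices(self, level: int) -> np.ndarray:
        return np.flatnonzero(self.levels == level)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            Path(path), vectors=self.vectors, image_ids=self.image_ids,
            gene_ids=self.gene_ids, class_labels=self.class_labels,
            levels=self.levels, locations=self.locations,
            target_size=np.array(self.target_size),
        )

    @staticmethod
    def load(path: str | Path) -> "DescriptorPool":
        with np.load(Path(path), allow_pickle=False) as z:
            return DescriptorPool(
                z["vectors"], z["image_ids"], z["gene_ids"], z["class_labels"],
                z["levels"], z["locations"], int(z["target_size"]),
            )


def _fair_allocation(avail: np.ndarray, total: int) -> np.ndarray:
    """Split ``total`` units across bins capped by ``avail`` (water-filling).

    Each bin gets an equal share; bins that cannot absorb their share are
    saturated and the deficit is redistributed among the bins with surplus.
    Any final remainder goes one unit each to the first remaining bins.
    """
    alloc = np.zeros(len(avail), dtype=np.int64)
    remaining = int(min(total, avail.sum()))
    while remaining > 0:
        active = np.flatnonzero(alloc < avail)
        share = remaining // len(active)
        if share == 0:
            alloc[active[:remaining]] += 1
            break
        take = np.minimum(share, avail[active] - alloc[active])
        alloc[active] += take
        remaining -= int(take.sum())
    return alloc


def sample_descriptor_pool(
    images: list[tuple[DescriptorSet, str, str]],
    pool_size: int = 100_000,
    balanced: bool = True,
    seed: int = 0,
) -> DescriptorPool:
    """Sample non-zero descriptors from every image into a pool.

    Parameters
    ----------
    images
        Tuples ``(descriptor_set, gene_id, class_label)``.
    pool_size
        Target total pool size P.
    balanced
        Equalize the two classes: each class gets a quota of floor(P/2)
        (remainder to the first class in order of appearance), divided
        equally across that class's images; per-image deficits are
        redistributed to sibling images with surplus descriptors. Sampling
        is without replacement.
    """
    if not images:
        raise DataError("no images supplied to sample_descriptor_pool")
    nonzero_sets = [(ds.nonzero(), gene, label) for ds, gene, label in images]
    avail = np.array([len(ds) for ds, _, _ in nonzero_sets], dtype=np.int64)
    if avail.sum() == 0:
        raise DataError("no non-zero descriptors in any image")

    rng = np.random.default_rng(seed)
    alloc = np.zeros(len(images), dtype=np.int64)
    if balanced:
        class_order: list[str] = []
        for _, _, label in nonzero_sets:
            if label not in class_order:
                class_order.append(label)
        quotas = {c: pool_size // 2 for c in class_order}
        if class_order:
            quotas[class_order[0]] += pool_size - 2 * (pool_size // 2)
        for cls in class_order:
            members = [i for i, (_, _, l) in enumerate(nonzero_sets) if l == cls]
            cls_avail = avail[members]
            quota = quotas[cls]
            if cls_avail.sum() < quota:
                logger.warning(
                    "class %r supplies %d non-zero descriptors, below its quota %d; "
                    "taking all available", cls, int(cls_avail.sum()), quota,
                )
            alloc[members] = _fair_allocation(cls_avail, quota)
    else:
        if avail.sum() < pool_size:
            logger.warning(
                "total supply %d below pool size %d; taking all available",
                int(avail.sum()), pool_size,
            )
        alloc = _fair_allocation(avail, pool_size)

    vec, iid, gid, lab, lvl, loc = [], [], [], [], [], []
    for (ds, gene, label), take in zip(nonzero_sets, alloc):
        if take == 0:
            continue
        idx = rng.choice(len(ds), size=int(take), replace=False)
        idx.sort()
        vec.append(ds.vectors[idx])
        lvl.append(ds.levels[idx])
        loc.append(ds.locations[idx])
        iid.extend([ds.image_id] * int(take))
        gid.extend([gene] * int(take))
        lab.extend([label] * int(take))
    return DescriptorPool(
        np.vstack(vec), np.array(iid), np.array(gid), np.array(lab),
        np.concatenate(lvl), np.vstack(loc), target_size=pool_size,
    )


# ---------------------------------------------------------------------------
# k-means codebook
# ---------------------------------------------------------------------------

def _sq_distances(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * (X @ C.T)
        + np.sum(C * C, axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def _lloyd(
    X: np.ndarray, m: int, rng: np.random.Generator,
    max_iter: int = 300, tol: float = 1e-4,
) -> tuple[np.ndarray, float, list[float]]:
    """One k-means run: uniform distinct-point init, empty clusters reseeded
    to the point farthest from its assigned center. Returns (centers, final
    objective, per-iteration objective trace)."""
    n = len(X)
    centers = X[rng.choice(n, size=m, replace=False)].copy()
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        d2 = _sq_distances(X, centers)
        labels = d2.argmin(axis=1)
        point_d2 = d2[np.arange(n), labels]
        # reseed empty clusters before measuring the objective
        empties = np.setdiff1d(np.arange(m), labels)
        for k in empties:
            j = int(point_d2.argmax())
            centers[k] = X[j]
            labels[j] = k
            point_d2[j] = 0.0
        obj = float(point_d2.sum())
        trace.append(obj)
        for k in range(m):
            members = labels == k
            if members.any():
                centers[k] = X[members].mean(axis=0)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, np.finfo(float).tiny):
            break
        prev = obj
    d2 = _sq_distances(X, centers)
    obj = float(d2[np.arange(n), d2.argmin(axis=1)].sum())
    trace.append(obj)
    return centers, obj, trace


@dataclass
class Codebook:
    """Per-resolution visual words (k-means cluster centers)."""

    centers: dict[int, np.ndarray]              # level -> (m_level, d)
    meta: dict = field(default_factory=dict)

    @property
    def levels(self) -> list[int]:
        return sorted(self.centers)

    def words(self, level: int) -> int:
        return len(self.centers[level])

    def feature_length(self) -> int:
        """Single-section bag-of-words length: sum of (m_level + 1)."""
        return sum(self.words(l) + 1 for l in self.levels)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, **{f"level_{l}": c for l, c in self.centers.items()})
        Path(str(path) + ".json").write_text(json.dumps(self.meta, indent=1, default=str))

    @staticmethod
    def load(path: str | Path) -> "Codebook":
        path = Path(path)
        with np.load(path) as z:
            centers = {int(k.split("_")[1]): z[k] for k in z.files}
        sidecar = Path(str(path) + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return Codebook(centers, meta)


def fit_codebooks(
    pool: DescriptorPool,
    m: int = 500,
    restarts: int = 3,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
    max_per_level: int | None = None,
) -> Codebook:
    """Fit one k-means codebook per resolution level of the pool.

    Each level runs Lloyd's algorithm ``restarts`` times (seeds seed, seed+1,
    ...) and keeps the run with the smallest squared-Euclidean objective. If
    a level holds fewer than ``m`` descriptors, that level's word count is
    reduced to the supply (with a warning). ``max_per_level`` optionally
    subsamples each level's pool (seeded) before clustering.
    """
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    levels = sorted(set(int(l) for l in np.unique(pool.levels)))
    if not levels:
        raise DataError("empty descriptor pool")
    centers: dict[int, np.ndarray] = {}
    meta: dict = {"m": m, "restarts": restarts, "seed": seed, "levels": {}}
    for lvl in levels:
        idx = pool.level_indices(lvl)
        if len(idx) == 0:
            raise DataError(f"pool level {lvl} is empty")
        if max_per_level is not None and len(idx) > max_per_level:
            sub_rng = np.random.default_rng([seed, lvl])
            idx = idx[np.sort(sub_rng.choice(len(idx), size=max_per_level, replace=False))]
        X = pool.vectors[idx]
        m_lvl = m
        if len(X) < m:
            m_lvl = len(X)
            logger.warning(
                "pool level %d has only %d descriptors; reducing words to %d",
                lvl, len(X), m_lvl,
            )
        objectives, runs = [], []
        for r in range(restarts):
            rng = np.random.default_rng(seed + r)
            C, obj, trace = _lloyd(X, m_lvl, rng, max_iter=max_iter, tol=tol)
            objectives.append(obj)
            runs.append((C, trace))
        best = int(np.argmin(objectives))
        centers[lvl] = runs[best][0]
        meta["levels"][lvl] = {
            "m": m_lvl,
            "n_points": len(X),
            "objectives": objectives,
            "chosen_restart": best,
            "objective_trace": runs[best][1],
        }
    return Codebook(centers, meta)


# ---------------------------------------------------------------------------
# bag-of-words features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One contiguous slice of a feature vector: a level's word bins plus
    its zero-descriptor bin, for one section type."""

    section: str | None
    level: int
    m: int        # word bins; the block occupies m + 1 entries


@dataclass
class BoWFeature:
    """Image-level bag-of-visual-words histogram with zero-descriptor bins."""

    x: np.ndarray
    blocks: list[Block]
    gene_id: str = ""
    image_ids: dict = field(default_factory=dict)   # section -> image_id

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        expected = sum(b.m + 1 for b in self.blocks)
        if len(self.x) != expected:
            raise ValidationError(
                f"feature length {len(self.x)} does not match layout length {expected}"
            )

    def __len__(self) -> int:
        return len(self.x)

    def index_info(self, i: int) -> tuple[str | None, int, str, int | None]:
        """Map a flat index back to (section, level, kind, word).

        ``kind`` is "word" (word gives the word index) or "zero" (word None).
        """
        if i < 0 or i >= len(self.x):
            raise IndexError(i)
        offset = 0
        for b in self.blocks:
            width = b.m + 1
            if i < offset + width:
                j = i - offset
                if j < b.m:
                    return (b.section, b.level, "word", j)
                return (b.section, b.level, "zero", None)
            offset += width
        raise IndexError(i)   # pragma: no cover

    @property
    def sections(self) -> list[str | None]:
        seen: list[str | None] = []
        for b in self.blocks:
            if b.section not in seen:
                seen.append(b.section)
        return seen


def layout_index_info(blocks: list[Block], i: int) -> tuple[str | None, int, str, int | None]:
    """Index lookup on a bare layout (no feature values needed)."""
    dummy = BoWFeature(np.zeros(sum(b.m + 1 for b in blocks), dtype=np.int64), blocks)
    return dummy.index_info(i)


def quantize(
    dset: DescriptorSet,
    codebook: Codebook,
    section: str | None = None,
    gene_id: str = "",
) -> BoWFeature:
    """Assign each descriptor to its nearest visual word at its own level.

    Non-zero descriptors increment the bin of the l2-nearest center (ties go
    to the lowest center index); zero descriptors increment the level's zero
    bin. Levels are concatenated in ascending order.
    """
    present = set(int(l) for l in np.unique(dset.levels))
    missing = present - set(codebook.levels)
    if missing:
        raise ValidationError(f"descriptor levels {sorted(missing)} absent from codebook")
    parts, blocks = [], []
    for lvl in codebook.levels:
        C = codebook.centers[lvl]
        counts = np.zeros(len(C) + 1, dtype=np.int64)
        sel = (dset.levels == lvl) & ~dset.is_zero
        if sel.any():
            d2 = _sq_distances(dset.vectors[sel], C)
            np.add.at(counts, d2.argmin(axis=1), 1)
        counts[len(C)] = int(((dset.levels == lvl) & dset.is_zero).sum())
        parts.append(counts)
        blocks.append(Block(section, lvl, len(C)))
    return BoWFeature(
        np.concatenate(parts), blocks, gene_id=gene_id,
        image_ids={section: dset.image_id},
    )


def concatenate_features(features: list[BoWFeature]) -> BoWFeature:
    """Concatenate per-section features of the same gene (section order as
    given). Duplicate section types are rejected."""
    if not features:
        raise ValidationError("no features to concatenate")
    if len(features) == 1:
        return features[0]
    genes = {f.gene_id for f in features if f.gene_id}
    if len(genes) > 1:
        raise ValidationError(f"features belong to different genes: {sorted(genes)}")
    sections: list[str | None] = []
    for f in features:
        for s in f.sections:
            if s in sections:
                raise ValidationError(f"duplicate section type {s!r} in concatenation")
            sections.append(s)
    image_ids: dict = {}
    for f in features:
        image_ids.update(f.image_ids)
    return BoWFeature(
        np.concatenate([f.x for f in features]),
        [b for f in features for b in f.blocks],
        gene_id=features[0].gene_id,
        image_ids=image_ids,
    )


def relative_frequencies(feature: BoWFeature) -> np.ndarray:
    """Optional per-level relative-frequency normalization of the counts."""
    out = feature.x.astype(np.float64).copy()
    offset = 0
    for b in feature.blocks:
        width = b.m + 1
        total = out[offset:offset + width].sum()
        if total > 0:
            out[offset:offset + width] /= total
        offset += width
    return out


def features_to_frame(features: list[BoWFeature], section_label: str = "") -> pd.DataFrame:
    """Feature matrix as a DataFrame: gene_id, image_id, section, f0..f{p-1}."""
    if not features:
        raise ValidationError("no features")
    p = len(features[0])
    rows = []
    for f in features:
        if len(f) != p:
            raise ValidationError("features have inconsistent lengths")
        image_id = "+".join(str(v) for v in f.image_ids.values())
        rows.append([f.gene_id, image_id, section_label, *f.x.tolist()])
    cols = ["gene_id", "image_id", "section"] + [f"f{i}" for i in range(p)]
    return pd.DataFrame(rows, columns=cols)
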