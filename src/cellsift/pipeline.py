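"""End-to-end orchestration: synthesize/load -> extract -> codebook ->
featurize -> train-eval / rank -> traceback, from a single config.

A run is driven by a :class:`RunConfig` (readable from a TOML file). A single
master seed deterministically derives per-stage seeds by hashing the stage
name, so each stage is independently reproducible. Intermediates (descriptor
sets, codebooks, feature tables) are cached on disk keyed by a hash of the
config fields that affect them; identical config + seed reproduces an
identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .codebook import (Codebook, DescriptorPool, concatenate_features,
                       features_to_frame, fit_codebooks, quantize,
                       sample_descriptor_pool)
from .errors import ConfigurationError, DataError
from .imaging import DescriptorSet, ISHImage, extract_multiresolution
from .learning import AUCReport, evaluate_protocol
from .ranking import (FeatureTrace, default_lambda_grid, rank_features,
                      render_trace, stability_selection, traceback)
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset, read_dataset
from .tasks import TaskSpec, build_task, task_gene_sets

logger = logging.getLogger(__name__)

COMBINED = "combined"


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (master_seed * 2654435761)) % (2**31 - 1)


@dataclass
class RunConfig:
    out_dir: str = "cellsift_run"
    data_dir: str | None = None               # None -> synthesize
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    # descriptor params
    patch_size: int = 16
    stride: int = 4
    levels: int = 4
    binning: str = "soft"
    # codebook params
    pool_size: int = 100_000
    words_single: int = 500
    words_combined: int = 250
    restarts: int = 3
    max_pool_per_level: int | None = None
    # tasks / protocol
    tasks: list = field(default_factory=lambda: [["N-vs-Neg", 1.5]])
    sections: list = field(default_factory=lambda: ["coronal", "sagittal", COMBINED])
    n_reps: int = 30
    train_fraction: float = 2.0 / 3.0
    # ranking (optional)
    ranking: dict | None = None   # {task, threshold, section, subsamples, top, render}
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        syn = raw.pop("synthetic", {})
        if "genes_per_class" in syn:
            syn["genes_per_class"] = tuple(syn["genes_per_class"])
        if "fold_ranges" in syn:
            syn["fold_ranges"] = {k: tuple(v) for k, v in syn["fold_ranges"].items()}
        if "texture_params" in syn:
            syn["texture_params"] = {k: tuple(v) for k, v in syn["texture_params"].items()}
        cfg = cls(synthetic=SyntheticConfig(**syn), **raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def __post_init__(self) -> None:
        for entry in self.tasks:
            TaskSpec(entry[0], float(entry[1]))   # validates
        for s in self.sections:
            if s not in ("coronal", "sagittal", COMBINED):
                raise ConfigurationError(f"unknown section mode {s!r}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _cache_dir(config: RunConfig) -> Path:
    d = Path(config.out_dir) / "cache"
    d.mkdir(parents=True, exist_ok=True)
    return d


def load_or_synthesize(config: RunConfig) -> SyntheticDataset:
    if config.data_dir is not None:
        logger.info("loading dataset from %s", config.data_dir)
        return read_dataset(config.data_dir)
    logger.info("synthesizing dataset (seed %d)", config.synthetic.seed)
    return generate_dataset(config.synthetic)


def extract_all(config: RunConfig, images: list[ISHImage],
                force: bool = False) -> dict[str, DescriptorSet]:
    """Dense multi-resolution SIFT for every image, cached per image."""
    key_fields = {"patch_size": config.patch_size, "stride": config.stride,
                  "levels": config.levels, "binning": config.binning}
    key = hashlib.sha256(json.dumps(key_fields, sort_keys=True).encode()).hexdigest()[:12]
    cache = _cache_dir(config)
    out: dict[str, DescriptorSet] = {}
    for im in images:
        safe_id = im.image_id.replace(":", "_").replace("/", "_")
        path = cache / f"desc-{key}-{safe_id}.npz"
        if path.exists() and not force:
            out[im.image_id] = DescriptorSet.load(path)
            continue
        ds = extract_multiresolution(
            im, levels=config.levels, patch_size=config.patch_size,
            stride=config.stride, binning=config.binning,
        )
        logger.info("extracted %d descriptors (%d non-zero) from %s",
                    len(ds), int((~ds.is_zero).sum()), im.image_id)
        ds.save(path)
        out[im.image_id] = ds
    return out


def _task_pool_and_codebook(
    config: RunConfig,
    dataset: SyntheticDataset,
    descriptors: dict[str, DescriptorSet],
    spec: TaskSpec,
    section: str,
    words: int,
    force: bool = False,
) -> tuple[DescriptorPool, Codebook, set[str], set[str]]:
    universe = set(dataset.gene_classes) or {im.gene_id for im in dataset.images}
    positives, negatives = task_gene_sets(dataset.enrichment, spec, universe)
    entries = []
    for im in dataset.images:
        if im.section_type != section:
            continue
        if im.gene_id in positives:
            label = "positive"
        elif im.gene_id in negatives:
            label = "negative"
        else:
            continue
        entries.append((descriptors[im.image_id], im.gene_id, label))
    if not entries:
        raise DataError(f"no images for task {spec.task} in section {section}")

    key_fields = {"task": spec.task, "t": spec.fold_threshold, "section": section,
                  "pool": config.pool_size, "words": words,
                  "restarts": config.restarts, "seed": config.seed,
                  "cap": config.max_pool_per_level}
    key = hashlib.sha256(json.dumps(key_fields, sort_keys=True).encode()).hexdigest()[:12]
    cache = _cache_dir(config)
    pool_path = cache / f"pool-{key}.npz"
    cb_path = cache / f"codebook-{key}.npz"
    if pool_path.exists() and cb_path.exists() and not force:
        return DescriptorPool.load(pool_path), Codebook.load(cb_path), positives, negatives

    pool = sample_descriptor_pool(
        entries, pool_size=config.pool_size, balanced=True,
        seed=stage_seed(config.seed, f"pool:{spec.task}:{section}"),
    )
    codebook = fit_codebooks(
        pool, m=words, restarts=config.restarts,
        seed=stage_seed(config.seed, f"codebook:{spec.task}:{section}:{words}"),
        max_per_level=config.max_pool_per_level,
    )
    pool.save(pool_path)
    codebook.save(cb_path)
    return pool, codebook, positives, negatives


def featurize_task(
    dataset: SyntheticDataset,
    descriptors: dict[str, DescriptorSet],
    codebooks: dict[str, Codebook],
    genes: set[str],
    sections: list[str],
) -> pd.DataFrame:
    """Per-gene features for the requested sections; for more than one
    section the per-section features of each gene are concatenated (pairing
    the i-th image of each section)."""
    rows = []
    for gene in sorted(genes):
        per_section = {
            s: sorted(dataset.images_for(gene, s), key=lambda im: im.image_id)
            for s in sections
        }
        n_pairs = min(len(v) for v in per_section.values())
        for k in range(n_pairs):
            feats = [
                quantize(descriptors[per_section[s][k].image_id], codebooks[s],
                         section=s, gene_id=gene)
                for s in sections
            ]
            rows.append(concatenate_features(feats))
    label = "+".join(sections)
    return features_to_frame(rows, section_label=label)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = load_or_synthesize(config)
    descriptors = extract_all(config, dataset.images, force=force)

    report: dict = {
        "provenance": {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "cellsift_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
        },
        "tasks": {},
    }

    ranking_ctx = None
    for task_name, threshold in config.tasks:
        spec = TaskSpec(task_name, float(threshold))
        task_report: dict = {}
        per_section_cb: dict[str, Codebook] = {}
        per_section_pool: dict[str, DescriptorPool] = {}
        genes_pos: set[str] = set()
        genes_neg: set[str] = set()
        for mode in config.sections:
            if mode == COMBINED:
                section_list = ["coronal", "sagittal"]
                words = config.words_combined
            else:
                section_list = [mode]
                words = config.words_single
            cbs: dict[str, Codebook] = {}
            pools: dict[str, DescriptorPool] = {}
            for s in section_list:
                pool, cb, genes_pos, genes_neg = _task_pool_and_codebook(
                    config, dataset, descriptors, spec, s, words, force=force)
                cbs[s], pools[s] = cb, pool
            frame = featurize_task(dataset, descriptors, cbs,
                                   genes_pos | genes_neg, section_list)
            labeled = build_task(dataset.enrichment, spec, frame)
            auc_report = evaluate_protocol(
                labeled, n_reps=config.n_reps,
                train_fraction=config.train_fraction,
                seed=stage_seed(config.seed, f"protocol:{spec.task}:{mode}"),
            )
            task_report[mode] = {
                "aucs": auc_report.aucs.tolist(),
                "selected_lambdas": auc_report.lambdas.tolist(),
                "summary": auc_report.summary(),
                "n_rows": len(labeled),
                "n_features": labeled.n_features,
                "n_genes_pos": len(genes_pos),
                "n_genes_neg": len(genes_neg),
            }
            logger.info("task %s (%s): median AUC %.3f", spec.task, mode,
                        auc_report.summary()["median"])
            if (config.ranking is not None
                    and config.ranking.get("task") == task_name
                    and float(config.ranking.get("threshold", threshold)) == float(threshold)
                    and config.ranking.get("section", "coronal") == mode):
                ranking_ctx = (spec, mode, labeled, frame, cbs, pools)
            per_section_cb.update(cbs)
            per_section_pool.update(pools)
        report["tasks"][f"{task_name}@{threshold}"] = task_report

    if config.ranking is not None and ranking_ctx is not None:
        report["ranking"] = _run_ranking(config, dataset, ranking_ctx)

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    logger.info("report written to %s", report_path)
    return report


def _run_ranking(config: RunConfig, dataset: SyntheticDataset, ctx) -> dict:
    spec, mode, labeled, frame, cbs, pools = ctx
    rcfg = config.ranking or {}
    grid = default_lambda_grid(labeled.X, labeled.y)
    profile = stability_selection(
        labeled.X, labeled.y, grid,
        n_subsamples=int(rcfg.get("subsamples", 100)),
        seed=stage_seed(config.seed, f"rank:{spec.task}:{mode}"),
    )
    top = rank_features(profile, int(rcfg.get("top", 10)))
    # a feature that no subsample ever selected carries no evidence; do not
    # trace it even if it pads out the requested top-q
    top = [fi for fi in top if profile.scores[fi] > 0.0]
    section_list = ["coronal", "sagittal"] if mode == COMBINED else [mode]
    # layout of the feature vector, reconstructed from the codebooks
    from .codebook import Block
    layout = [Block(s, lvl, cbs[s].words(lvl))
              for s in section_list for lvl in cbs[s].levels]
    traces = []
    render_dir = rcfg.get("render")
    for fi in top:
        tr = traceback(fi, cbs[_trace_section(layout, fi)],
                       pools[_trace_section(layout, fi)], layout)
        entry = {
            "feature_index": fi,
            "score": float(profile.scores[fi]),
            "section": tr.section,
            "level": tr.level,
            "word": tr.word,
            "is_zero_bin": tr.is_zero_bin,
            "image_id": tr.image_id,
            "gene_id": tr.gene_id,
            "location": list(tr.location),
            "distance": tr.distance,
        }
        if render_dir and not tr.is_zero_bin:
            rd = Path(render_dir)
            rd.mkdir(parents=True, exist_ok=True)
            image = _image_at_level(dataset, tr, config)
            out = render_trace(tr, image, rd / f"feature_{fi}.png",
                               patch_size=config.patch_size)
            entry["overlay"] = str(out)
        traces.append(entry)
    return {
        "task": spec.task, "threshold": spec.fold_threshold, "section": mode,
        "lambda_grid": grid.tolist(),
        "top_features": traces,
    }


def _trace_section(layout, feature_index: int) -> str:
    from .codebook import layout_index_info

    section, _, _, _ = layout_index_info(layout, feature_index)
    return section


def _image_at_level(dataset: SyntheticDataset, tr: FeatureTrace,
                    config: RunConfig) -> ISHImage:
    from .imaging import build_pyramid

    for im in dataset.images:
        if im.image_id == tr.image_id:
            return build_pyramid(im, levels=config.levels)[tr.level]
    raise DataError(f"image {tr.image_id} not found in dataset")
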