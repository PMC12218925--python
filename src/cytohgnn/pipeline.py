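"""End-to-end pipeline: images -> CNN features -> hypergraph -> classifier
-> evaluation report, plus dataset reading and run manifests.

A run is fully specified by a :class:`RunConfig` (JSON or YAML on disk) and
is reproducible from (config, seed): every artefact (features, hypergraph,
checkpoint, training log, reports, manifest) is written under the output
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .backbone import CompoundScalingBackbone
from .classifier import (
    GCNClassifier,
    HGNNConfig,
    HypergraphClassifier,
    ablate_propagation,
)
from .evaluation import (
    EvaluationReport,
    cross_validate,
    stratified_holdout,
    stratified_kfold,
)
from .exceptions import DegenerateInputError, FormatError, InvalidConfigError
from .feature_table import FeatureTable, load_feature_table, save_feature_table
from .hypergraph import build_hypergraph, save_hypergraph
from .scaling import ScalingConfig
from .synthetic import ClusterSpec, gen_feature_clusters

logger = logging.getLogger("cytohgnn")

__all__ = ["RunConfig", "read_image_dataset", "run_pipeline"]

IMAGE_EXTENSIONS = (".png", ".bmp")


@dataclass
class RunConfig:
    """One document tying together every stage configuration."""

    protocol: str = "holdout"  # holdout | kfold | ablate
    k: int = 10
    seed: int = 0
    # input: exactly one of image_dir / feature_table / synthetic
    image_dir: Optional[str] = None
    feature_table: Optional[str] = None
    synthetic: Optional[Dict] = None
    output_dir: str = "cytohgnn_run"
    scaling: Dict = field(default_factory=dict)
    hgnn: Dict = field(default_factory=dict)
    holdout_fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_folds: int = 5
    with_gcn_baseline: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        if not isinstance(data, dict):
            raise FormatError(f"config {path} must hold a mapping")
        return cls(**data)

    def to_dict(self) -> Dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_image_dataset(root_path) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Load a class-per-subdirectory image tree.

    Classes and files are ordered lexicographically for determinism; BMP
    and PNG files are accepted.  Unreadable files are skipped with a
    logged warning; an empty class directory is an error.

    Returns ``(images, labels, class_names)`` with images as a uint8 array
    when shapes agree, otherwise a list of arrays.
    """
    from PIL import Image

    root = Path(root_path)
    if not root.is_dir():
        raise FormatError(f"{root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise DegenerateInputError(
            f"{root} must contain at least 2 class subdirectories, found {len(class_dirs)}"
        )
    images, labels = [], []
    n_skipped = 0
    for cls_id, cls_dir in enumerate(class_dirs):
        files = sorted(
            f for f in cls_dir.iterdir() if f.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise DegenerateInputError(f"class directory {cls_dir} holds no readable images")
        for f in files:
            try:
                with Image.open(f) as im:
                    images.append(np.asarray(im.convert("RGB")))
            except Exception as exc:
                n_skipped += 1
                logger.warning("skipping unreadable image %s: %s", f, exc)
                continue
            labels.append(cls_id)
    if n_skipped:
        logger.warning("skipped %d unreadable files under %s", n_skipped, root)
    class_names = [d.name for d in class_dirs]
    shapes = {img.shape for img in images}
    if len(shapes) == 1:
        images = np.stack(images)
    return images, np.asarray(labels, dtype=np.int64), class_names


def _obtain_features(config: RunConfig, out: Path) -> FeatureTable:
    sources = [config.image_dir, config.feature_table, config.synthetic]
    if sum(s is not None for s in sources) != 1:
        raise InvalidConfigError(
            "exactly one of image_dir, feature_table, synthetic must be set"
        )
    if config.feature_table is not None:
        return load_feature_table(config.feature_table)
    if config.synthetic is not None:
        spec = ClusterSpec(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        table = gen_feature_clusters(spec)
        logger.info("generated synthetic clusters: %s samples", table.n_samples)
        return table
    images, labels, class_names = read_image_dataset(config.image_dir)
    logger.info("loaded %d images from %s", len(labels), config.image_dir)
    backbone = CompoundScalingBackbone(
        ScalingConfig(**config.scaling), seed=config.seed
    )
    table = backbone.extract_feature_table(images, labels, class_names=class_names)
    save_feature_table(table, out / "features.csv", fmt="csv")
    save_feature_table(table, out / "features", fmt="npy")
    return table


def _report_paths(report: EvaluationReport, out: Path, stem: str) -> None:
    report.to_json(out / f"{stem}.json")
    report.to_csv(out / f"{stem}.csv")
    report.confusion_to_csv(out / f"{stem}_confusion.csv")


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the configured protocol and write all artefacts.

    Returns a dictionary with the evaluation report(s) and the output
    directory.  Raises with a stage-tagged message on failure.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "features"
        table = _obtain_features(config, out)
        stage = "hypergraph"
        hg = build_hypergraph(table, config.k)
        save_hypergraph(hg, out / "hypergraph.edges")
        hgnn_cfg = HGNNConfig(
            in_dim=table.n_features,
            n_classes=table.n_classes,
            seed=config.seed,
            **config.hgnn,
        )
        results: Dict = {"output_dir": str(out)}
        stage = f"protocol:{config.protocol}"
        if config.protocol == "holdout":
            plan = stratified_holdout(
                table.labels, fractions=config.holdout_fractions, seed=config.seed
            )
            model = HypergraphClassifier(
                table.features, table.labels, k=config.k,
                hypergraph=hg, config=hgnn_cfg, class_names=table.class_names,
            )
            fit = model.fit(plan.train_idx, plan.val_idx)
            fit.history.to_csv(out / "training_log.csv", index=False)
            _save_checkpoint(fit.params, hgnn_cfg, config.seed, out / "checkpoint")
            report = fit.evaluate(plan.test_idx)
            _report_paths(report, out, "report_holdout")
            results.update(
                report=report,
                split_sizes={r: int(plan.indices(r).size) for r in ("train", "val", "test")},
            )
            if config.with_gcn_baseline:
                from .evaluation import gcn_baseline

                results["gcn_report"] = gcn_baseline(
                    table.features, table.labels, config.k, plan,
                    config=hgnn_cfg, class_names=table.class_names,
                )
                _report_paths(results["gcn_report"], out, "report_gcn_holdout")
        elif config.protocol == "kfold":
            reports, aggregate = cross_validate(
                table.features, table.labels, k=config.k, config=hgnn_cfg,
                n_folds=config.n_folds, seed=config.seed,
                class_names=table.class_names,
            )
            for i, rep in enumerate(reports):
                _report_paths(rep, out, f"report_fold{i}")
            (out / "report_kfold_aggregate.json").write_text(json.dumps(aggregate, indent=2))
            results.update(fold_reports=reports, aggregate=aggregate)
        elif config.protocol == "ablate":
            plan = stratified_holdout(
                table.labels, fractions=config.holdout_fractions, seed=config.seed
            )
            rep_with, rep_without = ablate_propagation(
                table.features, table.labels,
                plan.train_idx, plan.val_idx, plan.test_idx,
                k=config.k, config=hgnn_cfg, class_names=table.class_names,
            )
            _report_paths(rep_with, out, "report_with_propagation")
            _report_paths(rep_without, out, "report_without_propagation")
            results.update(report_with=rep_with, report_without=rep_without)
        else:
            raise InvalidConfigError(f"unknown protocol {config.protocol!r}")
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"cytohgnn": __version__, "numpy": np.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _save_checkpoint(params: Dict, hgnn_cfg: HGNNConfig, seed: int, stem: Path) -> None:
    np.savez(stem.with_suffix(".npz"), **params)
    meta = {"config": asdict(hgnn_cfg), "seed": seed}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))
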