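"""End-to-end pipeline orchestration.

Ties the five stages together — phantom/ROI acquisition, grayscale
conversion, intensity-clustering segmentation, pixel-distribution feature
extraction, and classifier evaluation — driven by a single TOML
configuration, and writes every intermediate artifact (cohort manifest,
DAT feature tables, performance table, test confusion matrix, best-model
JSON) plus a run manifest with the config hash and seeds, so reruns with
the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from osteoseg import phantom
from osteoseg.classifiers import MlpConfig, TreeConfig, save_model
from osteoseg.evaluation import RunConfig, average_performance, global_performance, run_experiment
from osteoseg.features import FeatureTable, pixel_distribution, write_dat
from osteoseg.phantom import PhantomParams, class_params, generate_split
from osteoseg.roi_io import write_image
from osteoseg.segmentation import DEFAULT_K_LIST, ClusterConfig, segment

logger = logging.getLogger("osteoseg.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one end-to-end run."""

    n_train_per_class: int = 30
    n_test_nonosteo: int = 22
    n_test_osteo: int = 20
    phantom_nonosteo: PhantomParams = field(
        default_factory=lambda: class_params(phantom.NONOSTEOPOROSIS)
    )
    phantom_osteo: PhantomParams = field(default_factory=lambda: class_params(phantom.OSTEOPOROSIS))
    run: RunConfig = field(default_factory=RunConfig)
    seed: int = 0
    save_images: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """A fast single-K demo: phantoms, K-means and FCM at K=10, all classifiers."""
    return PipelineConfig(
        n_train_per_class=8,
        n_test_nonosteo=6,
        n_test_osteo=6,
        run=RunConfig(k_list=(10,), seed=seed),
        seed=seed,
    )


def study_scale_config(seed: int = 0) -> PipelineConfig:
    """The full experiment shape: 30+30 train, 22+20 test, two segmentation
    methods, three classifiers, K in {8, 10, 12, 15}."""
    return PipelineConfig(run=RunConfig(k_list=DEFAULT_K_LIST, seed=seed), seed=seed)


def _derived_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] & 0x7FFFFFFF)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a TOML file; omitted keys keep defaults."""
    doc = tomllib.loads(Path(path).read_text())
    ph = doc.get("phantom", {})
    base = PhantomParams(
        **{k: v for k, v in ph.items() if k not in ("porosity_nonosteo", "porosity_osteo")}
    )
    p_non = dataclasses.replace(base, porosity=ph.get("porosity_nonosteo", phantom.POROSITY_NONOSTEO))
    p_ost = dataclasses.replace(base, porosity=ph.get("porosity_osteo", phantom.POROSITY_OSTEO))
    seg = doc.get("segmentation", {})
    clf = doc.get("classifiers", {})
    run = RunConfig(
        segmentation_methods=tuple(seg.get("methods", ("kmeans", "fcm"))),
        k_list=tuple(seg.get("k_list", DEFAULT_K_LIST)),
        classifiers=tuple(clf.get("methods", ("tree", "nb", "mlp"))),
        tree_config=TreeConfig(**clf.get("tree", {})),
        mlp_config=MlpConfig(**{k: tuple(v) if k == "hidden_sizes" else v for k, v in clf.get("mlp", {}).items()}),
        seed=doc.get("seed", 0),
        rounding=doc.get("rounding", "half-up"),
    )
    split = doc.get("split", {})
    return PipelineConfig(
        n_train_per_class=split.get("n_train_per_class", 30),
        n_test_nonosteo=split.get("n_test_nonosteo", 22),
        n_test_osteo=split.get("n_test_osteo", 20),
        phantom_nonosteo=p_non,
        phantom_osteo=p_ost,
        run=run,
        seed=doc.get("seed", 0),
        save_images=doc.get("save_images", False),
    )


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write artifacts under ``out_dir``.

    Returns a summary dict (selected model, test metrics, artifact paths).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # Stage 1-2: labeled grayscale ROIs (phantom cohorts).
    train_seed = _derived_seed(cfg.seed, 1)
    test_seed = _derived_seed(cfg.seed, 2)
    train = generate_split(
        cfg.n_train_per_class,
        cfg.n_train_per_class,
        cfg.phantom_nonosteo,
        cfg.phantom_osteo,
        seed=train_seed,
        id_prefix="train-",
    )
    test = generate_split(
        cfg.n_test_nonosteo,
        cfg.n_test_osteo,
        cfg.phantom_nonosteo,
        cfg.phantom_osteo,
        seed=test_seed,
        id_prefix="test-",
    )
    logger.info("stage=cohort train=%d test=%d elapsed=%.1fs", len(train), len(test), time.time() - t0)
    if cfg.save_images:
        img_dir = out_dir / "images"
        img_dir.mkdir(exist_ok=True)
        for img, _ in train + test:
            write_image(img, img_dir / f"{img.source_id}.png")

    # Stage 3-4: segmentation and feature extraction, persisted as DAT.
    features_cache = {}
    feat_dir = out_dir / "features"
    feat_dir.mkdir(exist_ok=True)
    for method in cfg.run.segmentation_methods:
        for K in cfg.run.k_list:
            ccfg = ClusterConfig(K=K, method=method, seed=cfg.run.seed)
            tables = []
            for split_name, split_data in (("train", train), ("test", test)):
                rows = [
                    pixel_distribution(segment(img, ccfg), label=label, source_id=img.source_id)
                    for img, label in split_data
                ]
                table = FeatureTable(rows=rows, K=K)
                write_dat(table, feat_dir / f"{method}_k{K}_{split_name}.dat")
                tables.append(table)
            features_cache[(method, K)] = tuple(tables)
            logger.info("stage=segment method=%s K=%d elapsed=%.1fs", method, K, time.time() - t0)

    # Stage 5: train/test evaluation and model selection.
    result = run_experiment(cfg.run, train, test, features_cache=features_cache)
    logger.info(
        "stage=evaluate best=%s/%s K=%d test_accuracy=%.2f elapsed=%.1fs",
        result.best["method"],
        result.best["classifier"],
        result.best["K"],
        result.test_metrics["accuracy"],
        time.time() - t0,
    )

    df = result.table.to_dataframe()
    agg_rows = []
    for method in cfg.run.segmentation_methods:
        for clf in cfg.run.classifiers:
            agg_rows.append(
                {
                    "segmentation": method,
                    "classifier": clf,
                    "K": -1,
                    "metric": "average_performance",
                    "value": average_performance(result.table, method, clf, cfg.run.k_list),
                }
            )
        agg_rows.append(
            {
                "segmentation": method,
                "classifier": "all",
                "K": -1,
                "metric": "global_performance",
                "value": global_performance(result.table, method, cfg.run.classifiers, cfg.run.k_list),
            }
        )
    pd.concat([df, pd.DataFrame(agg_rows)], ignore_index=True).to_csv(
        out_dir / "performance_table.csv", index=False
    )

    cm = result.test_confusion
    pd.DataFrame(
        {
            "actual_osteoporosis": [cm.tp, cm.fn],
            "actual_nonosteoporosis": [cm.fp, cm.tn],
        },
        index=["pred_osteoporosis", "pred_nonosteoporosis"],
    ).to_csv(out_dir / "confusion_test.csv")

    save_model(result.model, out_dir / "best_model.json")

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "train_seed": train_seed,
        "test_seed": test_seed,
        "best": result.best,
        "test_metrics": result.test_metrics,
        "test_confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(summary, indent=1))
    return summary
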