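"""End-to-end orchestration of the pairwise classification experiments.

One configuration drives, per diagnostic pair (e.g. AD/HC): pair-specific
QC, image encoding, the stratified 9:1 split, the association scan with its
linear-SVM baseline, convolutional-network training with 5-fold
cross-validation, and Grad-CAM saliency with per-variant group tests.  With
three tasks the shared-locus intersection is computed across them.  A JSON
manifest records config hash, seeds, per-stage status and artifact paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import ConvNetClassifier, TrainConfig
from .data import GenotypeDataset
from .encoding import SNPImageEncoder
from .evaluation import crossvalidate, split_dataset
from .gwas import association_scan, manhattan_qq_data, scan_features, svm_baseline
from .interpret import group_difference_test, saliency_per_variant, shared_loci
from .io import read_plink_text
from .qc import QCThresholds, run_qc

log = logging.getLogger(__name__)

DEFAULT_TASKS = (("AD", "HC"), ("HC", "MCI"), ("AD", "MCI"))


@dataclass
class PipelineConfig:
    ped_path: str = ""
    map_path: str = ""
    diagnosis_path: str = None
    output_dir: str = "dlgwas_run"
    tasks: tuple = DEFAULT_TASKS
    qc: QCThresholds = field(default_factory=QCThresholds)
    encoding_side: str = "auto"
    train: TrainConfig = field(default_factory=TrainConfig)
    test_fraction: float = 0.1
    cv_folds: int = 5
    svm_repeats: int = 500
    saliency_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qc" in raw:
            raw["qc"] = QCThresholds(**raw["qc"])
        if "train" in raw:
            raw["train"] = TrainConfig(**raw["train"])
        if "tasks" in raw:
            raw["tasks"] = tuple(tuple(t) for t in raw["tasks"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tasks"] = [list(t) for t in self.tasks]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, dataset: GenotypeDataset = None) -> dict:
    """Run every configured task; returns the manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "tasks": {},
        "stages": {},
        "artifacts": {},
    }

    try:
        if dataset is None:
            dataset = read_plink_text(cfg.ped_path, cfg.map_path, cfg.diagnosis_path)
        manifest["stages"]["load"] = "ok"
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        manifest["stages"]["load"] = f"failed: {exc}"
        _write_manifest(manifest, out)
        raise

    saliency_tables = {}
    for case_group, control_group in cfg.tasks:
        task = f"{case_group}_vs_{control_group}"
        try:
            result = _run_task(cfg, dataset, case_group, control_group, out / task)
            manifest["tasks"][task] = result
            manifest["stages"][task] = "ok"
            tdir = out / task
            sal_path = tdir / "saliency_tests.tsv"
            if sal_path.exists():
                saliency_tables[task] = pd.read_csv(sal_path, sep="\t")
        except Exception as exc:  # noqa: BLE001
            log.exception("task %s failed", task)
            manifest["stages"][task] = f"failed: {exc}"

    if len(cfg.tasks) >= 3 and len(saliency_tables) >= 3:
        shared = shared_loci(saliency_tables, threshold=cfg.saliency_alpha, use="fdr")
        path = out / "shared_loci.tsv"
        shared.to_csv(path, sep="\t", index=False)
        manifest["artifacts"]["shared_loci"] = str(path)
        manifest["stages"]["shared_loci"] = "ok"
        manifest["n_shared_loci"] = int(shared["shared"].sum())
    else:
        manifest["stages"]["shared_loci"] = "skipped (needs 3 tasks)"

    _write_manifest(manifest, out)
    if any(str(v).startswith("failed") for v in manifest["stages"].values()):
        raise RuntimeError("one or more pipeline stages failed; see manifest")
    return manifest


def _run_task(cfg: PipelineConfig, dataset, case_group, control_group, tdir: Path) -> dict:
    tdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    pair = dataset.select_groups([case_group, control_group])

    # pair-specific QC
    filtered, report = run_qc(pair, cfg.qc)
    (tdir / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    if filtered.n_samples == 0 or filtered.n_variants == 0:
        return {"status": "empty-after-qc", "qc": report.summary_counts()}

    labels = filtered.samples["group"].to_numpy()

    # 9:1 split over subjects (validation handled inside the classifier)
    split = split_dataset(labels, test_fraction=cfg.test_fraction, seed=cfg.seed)
    pool_idx, test_idx = split.train_pool, split.test

    # association scan + SVM baseline on the training pool
    scan = association_scan(filtered.subset(sample_idx=pool_idx), case_group, control_group)
    scan.table.to_csv(tdir / "association.tsv", sep="\t", index=False)
    plot = manhattan_qq_data(scan)
    plot["manhattan"].to_csv(tdir / "manhattan.csv", index=False)
    plot["qq"].to_csv(tdir / "qq.csv", index=False)

    feats, feat_rsids = scan_features(filtered, scan)
    svm = None
    if feats.shape[1] > 0:
        svm_res = svm_baseline(
            feats[pool_idx],
            labels[pool_idx],
            repeats=cfg.svm_repeats,
            test_fraction=cfg.test_fraction,
            seed=cfg.seed,
        )
        svm_res["roc"].to_csv(tdir / "svm_roc.csv", index=False)
        svm = {k: v for k, v in svm_res.items() if k != "roc"}

    # encoding
    encoder = SNPImageEncoder(side=cfg.encoding_side).fit(filtered)
    images = encoder.transform(filtered)
    (tdir / "pixel_map.json").write_text(encoder.pixel_map_.to_json())

    # CNN / ResNet with 5-fold cross-validation on the training pool
    tc = cfg.train.resolved()
    clf = ConvNetClassifier(
        family=tc.family,
        width=tc.width,
        learning_rate=tc.learning_rate,
        batch_size=tc.batch_size,
        epochs=tc.epochs,
        weight_decay=tc.weight_decay,
        validation_fraction=tc.validation_fraction,
        random_state=cfg.seed,
    )
    cv = crossvalidate(
        clf,
        images[pool_idx],
        labels[pool_idx],
        k=cfg.cv_folds,
        seed=cfg.seed,
        X_test=images[test_idx],
        y_test=labels[test_idx],
        positive_class=case_group,
    )
    cv.folds.to_csv(tdir / "cv_folds.csv", index=False)
    cv.roc.to_csv(tdir / "cnn_roc.csv", index=False)

    # final model on the full training pool for interpretation
    final = ConvNetClassifier(
        family=tc.family,
        width=tc.width,
        learning_rate=tc.learning_rate,
        batch_size=tc.batch_size,
        epochs=tc.epochs,
        weight_decay=tc.weight_decay,
        validation_fraction=tc.validation_fraction,
        random_state=cfg.seed,
    ).fit(images[pool_idx], labels[pool_idx])
    final.loss_trace_.to_csv(tdir / "loss_trace.csv", index=False)

    heat = final.grad_cam(images)
    sal = saliency_per_variant(heat, encoder.pixel_map_)
    used = encoder.pixel_map_.n_variants_used
    tests = group_difference_test(
        sal, labels, variant_ids=filtered.variants["rsid"].to_numpy()[:used],
        alpha=cfg.saliency_alpha,
    )
    tests.to_csv(tdir / "saliency_tests.tsv", sep="\t", index=False)

    metrics = cv.summary()
    result = {
        "status": "ok",
        "seconds": round(time.time() - t0, 2),
        "qc": report.summary_counts(),
        "dims_after_qc": [filtered.n_samples, filtered.n_variants],
        "scan": {
            "n_tests": scan.n_tests,
            "threshold": scan.threshold,
            "inflation_factor": scan.inflation_factor,
            "n_significant": int(len(scan.significant())),
            "svm_features": feat_rsids,
        },
        "svm": svm,
        "cnn": metrics,
        "n_significant_saliency_fdr": int(tests["significant_fdr"].sum()),
    }
    (tdir / "metrics.json").write_text(json.dumps(result, indent=2, default=str))
    return result


def _write_manifest(manifest: dict, out: Path) -> None:
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["artifacts"]["manifest"] = str(path)
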