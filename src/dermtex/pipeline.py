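"""End-to-end experiment orchestration.

One experiment = images → per-channel planes → descriptor features
(grayscale, colored, or hybrid) → train/test split → optional SMOTE on the
training partition → classifier fit/predict → confusion matrix, metrics and
a JSON-serializable run report.

All randomness (stratified split, SMOTE, classifier seeding) flows from one
top-level seed that is recorded in the report, so two runs of the same
config are identical. Extracted feature matrices can be cached on disk
keyed by a hash of the data identity and the feature configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import balance, evaluation
from .colorspace import ColorSpace, load_image, to_planes
from .descriptors import DEFAULT_CONFIG, DescriptorConfig, extract
from .errors import ComparisonError, ConfigError, InputError, SplitError
from .fixtures import FixtureSpec, make_dataset
from .fusion import colored_feature, hybrid_feature

__all__ = [
    "ExperimentConfig",
    "extract_features",
    "run_experiment",
    "run_grid",
    "compare_runs",
    "load_manifest",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment run.

    ``descriptors`` with more than one entry builds the hybrid
    (concatenated) feature of the listed descriptors, each extracted in
    ``space``. ``space="GRAY"`` gives classical grayscale features;
    anything else gives colored (per-channel concatenated) features.
    """

    descriptors: tuple[str, ...] = ("LBP",)
    space: str = "GRAY"
    classifier: str = "XGBOOST"
    manifest: str | None = None  # CSV with header path,label
    train_manifest: str | None = None  # predefined split (overrides manifest)
    test_manifest: str | None = None
    fixture: FixtureSpec | None = None
    test_size: float = 0.2
    seed: int = 42
    smote: bool = False
    smote_k: int = 5
    normalize: bool = True
    averaging: str = "weighted"
    cache_dir: str | None = None

    def feature_key(self) -> dict:
        """The config fields that determine the feature matrix."""
        data_id: object
        if self.fixture is not None:
            data_id = asdict(self.fixture)
        elif self.train_manifest is not None:
            data_id = [self.train_manifest, self.test_manifest]
        else:
            data_id = self.manifest
        return {
            "data": data_id,
            "descriptors": list(self.descriptors),
            "space": self.space,
            "normalize": self.normalize,
        }


def load_manifest(manifest: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load images and labels listed in a ``path,label`` CSV manifest.

    Relative paths are resolved against the manifest's directory.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise InputError(f"manifest not found: {manifest}")
    df = pd.read_csv(manifest)
    if not {"path", "label"} <= set(df.columns):
        raise InputError("manifest must have columns 'path' and 'label'")
    images = []
    for rel in df["path"]:
        p = Path(rel)
        if not p.is_absolute():
            p = manifest.parent / p
        images.append(load_image(p))
    return np.stack(images), df["label"].to_numpy(dtype=np.int64)


def _image_features(
    img: np.ndarray, descriptors: tuple[str, ...], space: str, cfg: DescriptorConfig
) -> np.ndarray:
    space_id = ColorSpace(space.upper())
    parts = []
    for d in descriptors:
        if space_id is ColorSpace.GRAY:
            (plane,) = to_planes(img, space_id)
            parts.append(extract(plane, d, cfg))
        else:
            parts.append(colored_feature(img, d, space_id, cfg))
    return parts[0].values if len(parts) == 1 else hybrid_feature(parts).values


def extract_features(
    images: np.ndarray,
    descriptors: tuple[str, ...],
    space: str,
    cfg: DescriptorConfig | None = None,
) -> np.ndarray:
    """Feature matrix (N×D) for a stack of RGB images."""
    cfg = cfg or DEFAULT_CONFIG
    return np.stack([_image_features(img, tuple(descriptors), space, cfg) for img in images])


def _cached_features(cfg: ExperimentConfig, images: np.ndarray, dcfg: DescriptorConfig) -> np.ndarray:
    if cfg.cache_dir is None:
        return extract_features(images, cfg.descriptors, cfg.space, dcfg)
    key = hashlib.sha256(
        json.dumps(cfg.feature_key(), sort_keys=True, default=str).encode()
    ).hexdigest()[:24]
    cache = Path(cfg.cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    path = cache / f"features_{key}.npy"
    if path.exists():
        return np.load(path)
    X = extract_features(images, cfg.descriptors, cfg.space, dcfg)
    np.save(path, X)
    return X


def _load_data(cfg: ExperimentConfig):
    """Resolve images + labels and the split, per the configured source."""
    if cfg.fixture is not None:
        images, labels, _ = make_dataset(cfg.fixture)
        return images, labels, None
    if cfg.train_manifest is not None:
        if cfg.test_manifest is None:
            raise ConfigError("train_manifest requires test_manifest")
        X_tr_img, y_tr = load_manifest(cfg.train_manifest)
        X_te_img, y_te = load_manifest(cfg.test_manifest)
        n_tr = len(y_tr)
        images = np.concatenate([X_tr_img, X_te_img])
        labels = np.concatenate([y_tr, y_te])
        split = (np.arange(n_tr), np.arange(n_tr, n_tr + len(y_te)))
        return images, labels, split
    if cfg.manifest is not None:
        images, labels = load_manifest(cfg.manifest)
        return images, labels, None
    raise ConfigError("config needs a fixture spec, a manifest, or train/test manifests")


def run_experiment(cfg: ExperimentConfig, dcfg: DescriptorConfig | None = None) -> dict:
    """Run one experiment and return its report as a plain dict."""
    if len(cfg.descriptors) == 0:
        raise ConfigError("at least one descriptor is required")
    dcfg = dcfg or DescriptorConfig(normalize=cfg.normalize)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    images, labels, predefined = _load_data(cfg)
    timings["load_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    X = _cached_features(cfg, images, dcfg)
    timings["features_s"] = time.perf_counter() - t0

    if predefined is not None:
        tr_idx, te_idx = predefined
    else:
        try:
            tr_idx, te_idx = train_test_split(
                np.arange(len(labels)),
                test_size=cfg.test_size,
                random_state=cfg.seed,
                stratify=labels,
            )
        except ValueError as exc:
            raise SplitError(f"stratified split failed: {exc}") from exc
    X_tr, y_tr = X[tr_idx], labels[tr_idx]
    X_te, y_te = X[te_idx], labels[te_idx]
    n_classes = int(labels.max()) + 1
    if np.unique(y_tr).size < n_classes or np.unique(y_te).size < n_classes:
        raise SplitError("a class is empty in the train or test partition")

    if cfg.smote:
        t0 = time.perf_counter()
        X_tr, y_tr = balance.smote(X_tr, y_tr, k=cfg.smote_k, seed=cfg.seed)
        timings["smote_s"] = time.perf_counter() - t0

    spec = evaluation.ClassifierSpec(kind=cfg.classifier, seed=cfg.seed)
    t0 = time.perf_counter()
    y_pred = evaluation.fit_predict(spec, X_tr, y_tr, X_te)
    timings["classify_s"] = time.perf_counter() - t0

    cm = evaluation.confusion(y_te, y_pred, n_classes=n_classes)
    rep = evaluation.metrics(cm, averaging=cfg.averaging)
    return {
        "config": {
            "descriptors": list(cfg.descriptors),
            "space": cfg.space,
            "classifier": cfg.classifier,
            "smote": cfg.smote,
            "normalize": cfg.normalize,
            "averaging": cfg.averaging,
            "test_size": cfg.test_size,
        },
        "seed": cfg.seed,
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
        "feature_length": int(X.shape[1]),
        "delegate": evaluation.delegate_info(spec),
        "confusion": cm.tolist(),
        "metrics": {
            "accuracy": rep.accuracy,
            "precision": rep.precision,
            "recall": rep.recall,
            "f1": rep.f1,
        },
        "metrics_percent": rep.as_percent(),
        "y_true": [int(v) for v in y_te],
        "y_pred": [int(v) for v in y_pred],
        "test_indices": [int(i) for i in te_idx],
        "timings": timings,
    }


def run_grid(
    base: ExperimentConfig,
    descriptors: list[str],
    spaces: list[str],
    classifiers: list[str],
    dcfg: DescriptorConfig | None = None,
) -> list[dict]:
    """Run the full descriptor × color-space × classifier grid.

    Features are extracted once per (descriptor, space) pair and shared
    between classifiers.
    """
    from dataclasses import replace

    reports = []
    for space in spaces:
        for d in descriptors:
            for clf in classifiers:
                cfg = replace(base, descriptors=(d,), space=space, classifier=clf)
                reports.append(run_experiment(cfg, dcfg))
    return reports


def compare_runs(report_a: dict, report_b: dict) -> dict:
    """Welch t-test between two runs' predictions plus metric deltas.

    Both reports must have been evaluated on the identical test set.
    """
    if report_a["test_indices"] != report_b["test_indices"] or report_a["y_true"] != report_b["y_true"]:
        raise ComparisonError("reports were evaluated on different test sets")
    welch = evaluation.welch_ttest(report_a["y_pred"], report_b["y_pred"])
    deltas = {
        k: report_a["metrics"][k] - report_b["metrics"][k] for k in report_a["metrics"]
    }
    return {
        "welch": welch.as_dict(),
        "metric_deltas": deltas,
        "a": {"config": report_a["config"], "metrics": report_a["metrics"]},
        "b": {"config": report_b["config"], "metrics": report_b["metrics"]},
    }
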