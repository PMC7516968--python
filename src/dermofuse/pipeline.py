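"""End-to-end orchestration of the CAD pipeline.

Stage order (leakage-free by construction):

1. segment every image and extract handcraft + deep features;
2. concatenate per image into the full feature vector (deep block first,
   then the 43 handcraft slots);
3. stratified 75/25 train/test split;
4. z-score normalization fitted on the training partition only;
5. mutual-information scoring and mean-threshold selection on the
   training partition only;
6. SMOTE balancing of the training partition only;
7. shallow-classifier training and evaluation on the untouched test
   partition.

All randomness (split, SMOTE, surrogate extractor weights) flows from
one master seed through named substreams, so a run is bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .balance import LabeledDataset, smote, split, zscore_fit_apply
from .deepfeat import concat_features, extract_deep, get_extractor
from .evaluate import confusion, evaluate as evaluate_model, predict, train_classifier
from .fusion import FeatureMatrix, mi_scores, select_features
from .handcraft import HANDCRAFT_FEATURE_NAMES, handcraft_vector
from .preprocess import preprocess

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with documented defaults."""

    sigma: float = 3.0  # Gaussian blur, px
    glcm_levels: int = 32
    glcm_distance: int = 1
    extractor: str = "surrogate"  # or a registry backbone name
    extractor_dim: int = 64  # surrogate output length
    mi_k: int = 3  # neighbors for the kNN MI estimator
    smote_k: int = 5  # neighbors for SMOTE interpolation
    train_fraction: float = 0.75
    classifier: str = "svm_rbf"
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunReport:
    """Reproducibility record of one pipeline run."""

    config: dict
    n_images: int
    n_features_total: int
    n_features_selected: int
    selected_names: list[str]
    mi_threshold: float
    train_size: int
    test_size: int
    train_class_counts: dict
    train_class_counts_after_smote: dict
    test_class_counts: dict
    confusion: dict
    metrics: dict
    version: str = field(default="")
    timestamp: float = field(default=0.0)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def comparable(self) -> dict:
        """Report contents with the timestamp stripped, for equality checks."""
        d = asdict(self)
        d.pop("timestamp")
        return d


def _substream_seeds(master: int, n: int) -> list[int]:
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(
    images: list[np.ndarray],
    labels: np.ndarray,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run the full CAD pipeline on labeled RGB images.

    ``labels`` are binary, 1 = melanoma (positive class).
    """
    config = config or PipelineConfig()
    labels = np.asarray(labels, dtype=np.int64)
    if len(images) != len(labels):
        raise ValueError("images and labels lengths differ")
    if len(images) < 4:
        raise ValueError("need at least 4 labeled images")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    split_seed, smote_seed, surrogate_seed, clf_seed = _substream_seeds(config.seed, 4)
    ex = get_extractor(config.extractor, seed=surrogate_seed, dim=config.extractor_dim)

    rows = []
    for idx, img in enumerate(images):
        try:
            roi = preprocess(img, sigma=config.sigma)
            hand = handcraft_vector(
                roi,
                glcm_levels=config.glcm_levels,
                glcm_distance=config.glcm_distance,
            )
            deep = extract_deep(roi, ex)
        except Exception as exc:  # noqa: BLE001 - re-raise with item context
            raise RuntimeError(f"feature extraction failed on image {idx}: {exc}") from exc
        rows.append(concat_features(deep, hand))

    feature_names = tuple(
        [f"deep_{i}" for i in range(ex.dim)] + list(HANDCRAFT_FEATURE_NAMES)
    )
    data = FeatureMatrix(X=np.vstack(rows), feature_names=feature_names, y=labels)

    train, test = split(data, train_fraction=config.train_fraction, seed=split_seed)
    train, test = zscore_fit_apply(train, test)

    scores = mi_scores(train, k=config.mi_k)
    mask = select_features(scores)
    keep = mask.keep
    selected_names = [n for n, k in zip(train.feature_names, keep) if k]
    train_sel = FeatureMatrix(
        X=train.X[:, keep], feature_names=tuple(selected_names), y=train.y
    )
    test_sel = FeatureMatrix(
        X=test.X[:, keep], feature_names=tuple(selected_names), y=test.y
    )

    train_ds = LabeledDataset(X=train_sel.X, y=train_sel.y)
    balanced = smote(train_ds, k_neighbors=config.smote_k, seed=smote_seed)

    model = train_classifier(balanced, kind=config.classifier, hyper={"seed": clf_seed})
    report = evaluate_model(model, test_sel.X, test_sel.y)
    y_pred, _ = predict(model, test_sel.X)
    conf = confusion(test_sel.y, y_pred)

    return RunReport(
        config=asdict(config),
        n_images=len(images),
        n_features_total=data.p,
        n_features_selected=int(keep.sum()),
        selected_names=selected_names,
        mi_threshold=float(mask.threshold),
        train_size=train.n,
        test_size=test.n,
        train_class_counts={str(k): v for k, v in train_ds.class_counts.items()},
        train_class_counts_after_smote={
            str(k): v for k, v in balanced.class_counts.items()
        },
        test_class_counts={
            str(int(c)): int(n) for c, n in zip(*np.unique(test.y, return_counts=True))
        },
        confusion={"tp": conf.tp, "tn": conf.tn, "fp": conf.fp, "fn": conf.fn},
        metrics=report.as_dict(),
        version=__version__,
        timestamp=time.time(),
    )
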