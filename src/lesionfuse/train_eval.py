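"""Model assembly, training loop and the evaluation suite.

The public surface follows the statsmodels convention: build a
:class:`LesionFusionModel` from aligned arrays plus a :class:`RunConfig`,
call :meth:`~LesionFusionModel.fit` and receive a
:class:`LesionFusionResults` carrying the trained parameters, the training
history, an ``evaluate`` method producing a :class:`MetricsReport`, and a
``summary()`` table.

Evaluation reports overall accuracy, per-class and macro precision, recall
(sensitivity), specificity and F1, one-vs-rest ROC-AUC per class, and the
confusion matrix (rows = true class, columns = predicted).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn import metrics as skmetrics

from ._tensor import Tensor, cross_entropy
from .encoders import ClinicalMLP, WeightedResNet
from .fusion import FUSION_METHODS, FusionConfigError, build_fusion
from .io_core import DX_LABELS, RunConfig
from .nn import Adam, Linear, Module

__all__ = [
    "MetricsReport", "TrainHistory", "MultimodalNet", "ImageOnlyNet",
    "MetadataOnlyNet", "build_model", "train_model", "evaluate_model",
    "confusion_matrix", "roc_auc_ovr", "softmax_probs",
    "LesionFusionModel", "LesionFusionResults", "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    pass


# --------------------------------------------------------------------- metrics
def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """C[i, j] = #(true == i and predicted == j)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.min(initial=0) < 0 or arr.max(initial=0) >= n_classes:
            raise ValueError(f"{name} labels out of range 0..{n_classes - 1}")
    return skmetrics.confusion_matrix(
        y_true, y_pred, labels=np.arange(n_classes))


def roc_auc_ovr(scores: np.ndarray, y_true) -> tuple[np.ndarray, list[int]]:
    """One-vs-rest AUC per class from its score column.

    Classes with zero positives or zero negatives get ``nan`` and are listed
    as undefined rather than silently zeroed.
    """
    y_true = np.asarray(y_true)
    n_classes = scores.shape[1]
    aucs = np.full(n_classes, np.nan)
    undefined: list[int] = []
    for k in range(n_classes):
        pos = y_true == k
        if pos.all() or not pos.any():
            undefined.append(k)
            continue
        aucs[k] = skmetrics.roc_auc_score(pos.astype(int), scores[:, k])
    return aucs, undefined


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _nanmacro(values: np.ndarray) -> float:
    return float(np.nanmean(values)) if not np.isnan(values).all() else float("nan")


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray              # per class
    recall: np.ndarray                 # sensitivity, per class
    specificity: np.ndarray
    f1: np.ndarray
    auc: np.ndarray
    confusion: np.ndarray
    undefined_classes: list[int] = field(default_factory=list)
    class_names: tuple[str, ...] = DX_LABELS

    @property
    def macro_precision(self) -> float:
        return _nanmacro(self.precision)

    @property
    def macro_recall(self) -> float:
        return _nanmacro(self.recall)

    @property
    def macro_specificity(self) -> float:
        return _nanmacro(self.specificity)

    @property
    def macro_f1(self) -> float:
        return _nanmacro(self.f1)

    @property
    def macro_auc(self) -> float:
        return _nanmacro(self.auc)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall,
                      "specificity": self.macro_specificity,
                      "f1": self.macro_f1, "auc": self.macro_auc},
            "per_class": {
                name: {"precision": float(self.precision[i]),
                       "recall": float(self.recall[i]),
                       "specificity": float(self.specificity[i]),
                       "f1": float(self.f1[i]),
                       "auc": float(self.auc[i])}
                for i, name in enumerate(self.class_names[:len(self.precision)])
            },
            "confusion": self.confusion.tolist(),
            "undefined_classes": self.undefined_classes,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def metrics_from_predictions(y_true, y_pred, probs: np.ndarray | None,
                             n_classes: int,
                             class_names=DX_LABELS) -> MetricsReport:
    c = confusion_matrix(y_true, y_pred, n_classes)
    n = c.sum()
    tp = np.diag(c).astype(float)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    tn = n - tp - fp - fn
    support = c.sum(axis=1)
    undefined = [k for k in range(n_classes) if support[k] == 0]

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        specificity = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    for k in undefined:          # absent class: flag, do not report zeros
        precision[k] = recall[k] = specificity[k] = f1[k] = np.nan

    if probs is not None:
        auc, auc_undef = roc_auc_ovr(probs, y_true)
        undefined = sorted(set(undefined) | set(auc_undef))
    else:
        auc = np.full(n_classes, np.nan)
    return MetricsReport(
        accuracy=float(tp.sum() / n), precision=precision, recall=recall,
        specificity=specificity, f1=f1, auc=auc, confusion=c,
        undefined_classes=undefined,
        class_names=tuple(class_names)[:n_classes])


# ---------------------------------------------------------------------- models
class MultimodalNet(Module):
    """Image encoder + clinical encoder + fusion + feed-forward classifier."""

    def __init__(self, image_encoder: WeightedResNet,
                 clinical_encoder: ClinicalMLP, fusion_module,
                 rng: np.random.Generator, n_classes: int = 7,
                 head_hidden: int = 128):
        super().__init__()
        self.image_encoder = image_encoder
        self.clinical_encoder = clinical_encoder
        self.fusion = fusion_module
        self.fc1 = Linear(fusion_module.out_dim, head_hidden, rng)
        self.fc2 = Linear(head_hidden, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, x_img: Tensor, x_meta: Tensor,
                capture: dict | None = None) -> Tensor:
        fx = self.image_encoder.features(x_img, capture)
        fy = self.clinical_encoder(x_meta)
        z = self.fusion(fx, fy)
        return self.fc2(self.fc1(z).relu())


class ImageOnlyNet(Module):
    """Image-only ablation: the weighted-residual encoder's class head."""

    def __init__(self, image_encoder: WeightedResNet):
        super().__init__()
        self.image_encoder = image_encoder
        self.n_classes = image_encoder.class_head.weight.shape[1]

    def forward(self, x_img: Tensor, x_meta=None,
                capture: dict | None = None) -> Tensor:
        return self.image_encoder.classify(x_img, capture)


class MetadataOnlyNet(Module):
    """Metadata-only ablation: clinical MLP plus the same classifier head."""

    def __init__(self, clinical_encoder: ClinicalMLP,
                 rng: np.random.Generator, n_classes: int = 7,
                 head_hidden: int = 128):
        super().__init__()
        self.clinical_encoder = clinical_encoder
        self.fc1 = Linear(clinical_encoder.out_dim, head_hidden, rng)
        self.fc2 = Linear(head_hidden, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, x_img, x_meta: Tensor,
                capture: dict | None = None) -> Tensor:
        return self.fc2(self.fc1(self.clinical_encoder(x_meta)).relu())


def build_model(fusion_method: str, clinical_in_features: int,
                config: RunConfig | None = None,
                seed: int | None = None) -> Module:
    """Assemble a model; ``fusion_method`` may also be ``image_only`` or
    ``metadata_only`` for the unimodal ablations."""
    config = config or RunConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    if fusion_method not in FUSION_METHODS and fusion_method not in (
            "image_only", "metadata_only"):
        raise FusionConfigError(
            f"unknown fusion method {fusion_method!r}; valid names: "
            f"{sorted(FUSION_METHODS)} plus 'image_only'/'metadata_only'")
    if config.n_classes < 2:
        raise ValueError("n_classes must be >= 2")

    if fusion_method == "metadata_only":
        clin = ClinicalMLP(clinical_in_features, rng,
                           hidden=config.clinical_hidden,
                           out_dim=config.clinical_dim)
        return MetadataOnlyNet(clin, rng, n_classes=config.n_classes)

    image = WeightedResNet(
        rng, base_width=config.base_width, feature_dim=config.image_dim,
        n_classes=config.n_classes, dropout_p=config.dropout_p,
        leaky_slope=config.leaky_slope,
        literal_softmax_head=config.literal_softmax_head)
    if fusion_method == "image_only":
        return ImageOnlyNet(image)

    clin = ClinicalMLP(clinical_in_features, rng,
                       hidden=config.clinical_hidden,
                       out_dim=config.clinical_dim)
    fus = build_fusion(fusion_method, config.image_dim, config.clinical_dim,
                       rng, **config.fusion)
    return MultimodalNet(image, clin, fus, rng, n_classes=config.n_classes)


# -------------------------------------------------------------------- training
@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    eval_metrics: list[dict] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.losses)


def _forward(model: Module, x_img, x_meta) -> Tensor:
    ti = Tensor(x_img) if x_img is not None else None
    tm = Tensor(x_meta) if x_meta is not None else None
    return model(ti, tm)


def train_model(model: Module, train_data, config: RunConfig,
                logger=None) -> TrainHistory:
    """Mini-batch Adam training with cross-entropy on class scores.

    ``train_data`` is ``(X_img, X_meta, y)``; either modality array may be
    None for the unimodal ablations.  Deterministic given ``config.seed``
    (seeded shuffles fix the data order).
    """
    x_img, x_meta, y = train_data
    n = len(y)
    if config.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {config.optimizer!r}")
    if config.loss != "cross_entropy":
        raise ValueError(f"unsupported loss {config.loss!r}")
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainHistory(seed=config.seed,
                           config=dataclasses.asdict(config))
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b, start in enumerate(range(0, n, config.batch_size)):
            idx = order[start:start + config.batch_size]
            bi = x_img[idx] if x_img is not None else None
            bm = x_meta[idx] if x_meta is not None else None
            logits = _forward(model, bi, bm)
            loss = cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {b}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        history.losses.append(epoch_loss / n)
        if logger is not None:
            logger.info("epoch %d/%d loss %.4f", epoch + 1, config.epochs,
                        history.losses[-1])
    model.eval()
    return history


def predict_scores(model: Module, x_img, x_meta,
                   batch_size: int = 128) -> np.ndarray:
    """Forward the data in eval mode; returns the logits matrix."""
    model.eval()
    n = len(x_img) if x_img is not None else len(x_meta)
    out = []
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        bi = x_img[sl] if x_img is not None else None
        bm = x_meta[sl] if x_meta is not None else None
        out.append(_forward(model, bi, bm).data)
    return np.concatenate(out, axis=0)


def evaluate_model(model: Module, test_data,
                   class_names=DX_LABELS) -> MetricsReport:
    """Evaluate on an untouched (never balanced/augmented) test split."""
    x_img, x_meta, y = test_data
    logits = predict_scores(model, x_img, x_meta)
    probs = softmax_probs(logits)
    preds = logits.argmax(axis=1)
    return metrics_from_predictions(y, preds, probs, model.n_classes,
                                    class_names)


# ------------------------------------------------------- model/results facade
class LesionFusionModel:
    """Multimodal lesion classifier specified by data plus a RunConfig.

    Parameters
    ----------
    images : (N, 3, S, S) float array in [0, 1], or None for metadata-only.
    metadata : (N, d_c) encoded clinical matrix, or None for image-only.
    labels : (N,) integer class labels.
    config : RunConfig; ``config.fusion_method`` selects the fusion operator
        or one of the unimodal ablations.
    """

    def __init__(self, images, metadata, labels, config: RunConfig,
                 feature_names: list[str] | None = None,
                 class_names=DX_LABELS):
        if images is None and metadata is None:
            raise ValueError("at least one modality is required")
        self.images = images
        self.metadata = metadata
        self.labels = np.asarray(labels)
        self.config = config
        self.feature_names = feature_names
        self.class_names = class_names
        d_c = metadata.shape[1] if metadata is not None else 1
        self.net = build_model(config.fusion_method, d_c, config)

    @classmethod
    def from_manifest(cls, manifest, images, config: RunConfig,
                      stats="fit"):
        """Construct from a manifest + raw image dict (fits preprocessing
        statistics when ``stats='fit'``)."""
        from .preprocess import assemble_arrays
        x_img, encoded, labels, stats = assemble_arrays(
            manifest, images, stats, config.image_size)
        model = cls(x_img, encoded.matrix, labels, config,
                    feature_names=encoded.feature_names)
        model.stats = stats
        return model

    def fit(self, logger=None) -> "LesionFusionResults":
        history = train_model(self.net, (self.images, self.metadata,
                                         self.labels), self.config, logger)
        return LesionFusionResults(self, history)


class LesionFusionResults:
    """Fitted-model results: trained parameters, history, evaluation."""

    def __init__(self, model: LesionFusionModel, history: TrainHistory):
        self.model = model
        self.net = model.net
        self.history = history
        self.config = model.config

    def predict_scores(self, images, metadata) -> np.ndarray:
        return predict_scores(self.net, images, metadata)

    def predict_proba(self, images, metadata) -> np.ndarray:
        return softmax_probs(self.predict_scores(images, metadata))

    def predict(self, images, metadata) -> np.ndarray:
        return self.predict_scores(images, metadata).argmax(axis=1)

    def evaluate(self, images, metadata, labels) -> MetricsReport:
        return evaluate_model(self.net, (images, metadata, labels),
                              self.model.class_names)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.net.parameters()))

    def summary(self, test_report: MetricsReport | None = None) -> str:
        cfg = self.config
        lines = [
            "Multimodal lesion classifier",
            "=" * 44,
            f"{'fusion method':<24}{cfg.fusion_method}",
            f"{'classes':<24}{self.net.n_classes}",
            f"{'parameters':<24}{self.n_parameters():,}",
            f"{'epochs':<24}{len(self.history)}",
            f"{'batch size':<24}{cfg.batch_size}",
            f"{'learning rate':<24}{cfg.learning_rate}",
            f"{'optimizer':<24}{cfg.optimizer}",
            f"{'seed':<24}{cfg.seed}",
            f"{'final training loss':<24}"
            f"{self.history.losses[-1]:.4f}" if self.history.losses else
            f"{'final training loss':<24}n/a",
        ]
        if test_report is not None:
            lines += [
                "-" * 44,
                f"{'test accuracy':<24}{test_report.accuracy:.4f}",
                f"{'macro F1':<24}{test_report.macro_f1:.4f}",
                f"{'macro AUC':<24}{test_report.macro_auc:.4f}",
            ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        from .io_core import save_checkpoint
        save_checkpoint(self.net, self.config, path)
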