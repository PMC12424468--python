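"""Split, class balancing, image preprocessing and metadata encoding.

The pipeline order is fixed: stratified split first, then balancing by
augmentation/undersampling on the training split only, then per-modality
preprocessing with all statistics fitted on the (balanced) training split.
Test data is never balanced or augmented, and transforming it never updates
fitted statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize
from sklearn.preprocessing import OneHotEncoder

from .io_core import (DX_TYPES, LOCALIZATIONS, SEXES, AugmentSpec,
                      ClinicalRecord, DatasetManifest, read_image_file)

__all__ = [
    "split_dataset", "balance_classes", "augment_image", "preprocess_image",
    "impute_and_encode", "PreprocessStats", "EncodedMetadata",
    "assemble_arrays", "AUGMENT_OPS", "default_augment_params",
]

AUGMENT_OPS = ("replicate", "jitter", "hflip", "vflip", "rotate", "scale")

_CAT_VOCABS = {"dx_type": list(DX_TYPES), "sex": list(SEXES),
               "localization": list(LOCALIZATIONS)}


def split_dataset(manifest: DatasetManifest, train_fraction: float,
                  seed: int) -> tuple[DatasetManifest, DatasetManifest]:
    """Stratified train/test split, deterministic given ``seed``.

    Per-class train counts are ``round(class_count * train_fraction)``; the
    two splits are disjoint and exhaustive.  Stratification guarantees every
    class appears in both splits (requires >= 2 members per class).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1): {train_fraction}")
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(manifest.records):
        by_class.setdefault(r.dx, []).append(i)
    for dx, idxs in by_class.items():
        if len(idxs) < 2:
            raise ValueError(
                f"class {dx!r} has {len(idxs)} member(s); need at least 2 "
                f"to appear in both splits")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for dx in sorted(by_class):
        idxs = np.array(by_class[dx])
        rng.shuffle(idxs)
        n_train = int(np.floor(len(idxs) * train_fraction + 0.5))
        n_train = min(max(n_train, 1), len(idxs) - 1)
        train_idx.extend(idxs[:n_train])
        test_idx.extend(idxs[n_train:])
    train = manifest.subset(sorted(train_idx))
    test = manifest.subset(sorted(test_idx))
    train.split_tag, test.split_tag = "train", "test"
    return train, test


def default_augment_params(op: str, rng: np.random.Generator) -> dict:
    """Draw augmentation parameters from the package defaults."""
    if op == "jitter":
        return {"amplitude": 0.02}
    if op == "rotate":
        return {"angle": float(rng.uniform(-30, 30))}
    if op == "scale":
        return {"factor": float(rng.uniform(0.9, 1.1))}
    return {}


def balance_classes(manifest: DatasetManifest, target_per_class: int,
                    augment_ops=AUGMENT_OPS, seed: int = 0
                    ) -> DatasetManifest:
    """Equalize per-class counts on a training manifest.

    Classes above the target are randomly undersampled (outputs are a subset
    of the originals); classes below it are filled with replicated and
    augmented copies, each keeping a provenance link to its source image.
    Idempotent on an already balanced manifest.
    """
    if target_per_class < 1:
        raise ValueError("target_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[ClinicalRecord]] = {}
    for r in manifest.records:
        by_class.setdefault(r.dx, []).append(r)
    for dx, recs in by_class.items():
        if not recs:
            raise ValueError(f"cannot balance empty class {dx!r}")

    out: list[ClinicalRecord] = []
    for dx in sorted(by_class):
        recs = by_class[dx]
        if len(recs) >= target_per_class:
            keep = rng.choice(len(recs), size=target_per_class, replace=False)
            out.extend(recs[i] for i in sorted(keep))
            continue
        out.extend(recs)
        n_fill = target_per_class - len(recs)
        for k in range(n_fill):
            src = recs[int(rng.integers(len(recs)))]
            op = augment_ops[int(rng.integers(len(augment_ops)))]
            params = default_augment_params(op, rng)
            spec = AugmentSpec(op=op, params=params,
                               seed=int(rng.integers(2 ** 31)))
            base_id = src.source_image_id or src.image_id
            out.append(ClinicalRecord(
                image_id=f"{src.image_id}-aug{k:05d}",
                lesion_id=src.lesion_id, dx=src.dx, dx_type=src.dx_type,
                age=src.age, sex=src.sex, localization=src.localization,
                source_image_id=base_id, augment=spec))
    balanced = DatasetManifest(out, dict(manifest.image_paths),
                               manifest.split_tag)
    return balanced


def augment_image(image: np.ndarray, op: str, params: dict | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply one augmentation to a raw H x W x 3 array (0-255 scale).

    Output preserves shape and value range.  Jitter noise is bounded by its
    amplitude (fraction of full scale); axis-aligned rotations are exact;
    arbitrary angles and rescales keep the canvas size by crop/pad.
    """
    params = params or {}
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got {image.shape}")
    img = np.asarray(image, dtype=np.float64)
    if op == "replicate":
        out = img
    elif op == "jitter":
        amp = params.get("amplitude", 0.02)
        if amp == 0:
            out = img
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            out = img + rng.normal(0, amp * 255.0, size=img.shape)
    elif op == "hflip":
        out = img[:, ::-1, :]
    elif op == "vflip":
        out = img[::-1, :, :]
    elif op == "rotate":
        angle = params.get("angle", 0.0)
        if angle % 90 == 0:
            out = np.rot90(img, k=int(angle // 90) % 4, axes=(0, 1))
        else:
            out = ndimage.rotate(img, angle, axes=(1, 0), reshape=False,
                                 mode="nearest", order=1)
    elif op == "scale":
        factor = params.get("factor", 1.0)
        h, w = img.shape[:2]
        zoomed = ndimage.zoom(img, (factor, factor, 1), order=1,
                              mode="nearest")
        zh, zw = zoomed.shape[:2]
        if factor >= 1.0:                       # centre crop
            y0, x0 = (zh - h) // 2, (zw - w) // 2
            out = zoomed[y0:y0 + h, x0:x0 + w]
        else:                                   # centre pad with edge values
            out = np.zeros_like(img)
            y0, x0 = (h - zh) // 2, (w - zw) // 2
            out += np.mean(zoomed, axis=(0, 1))
            out[y0:y0 + zh, x0:x0 + zw] = zoomed
    else:
        raise ValueError(f"unknown augmentation op {op!r}; "
                         f"valid ops: {AUGMENT_OPS}")
    return np.clip(out, 0, 255).astype(image.dtype if np.issubdtype(
        image.dtype, np.integer) else np.float64)


def preprocess_image(raw: np.ndarray, image_size: int) -> np.ndarray:
    """Resize to ``image_size`` square and scale to [0, 1] by dividing by 255."""
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {raw.shape}")
    arr = np.asarray(raw, dtype=np.float64)
    if arr.shape[0] != image_size or arr.shape[1] != image_size:
        arr = resize(arr, (image_size, image_size, 3), preserve_range=True,
                     anti_aliasing=True)
    out = arr / 255.0
    return np.clip(out, 0.0, 1.0).astype(np.float32)


@dataclass
class EncodedMetadata:
    matrix: np.ndarray                 # n x d_c float32
    feature_names: list[str]
    image_ids: list[str]


@dataclass
class PreprocessStats:
    """Imputation and standardization statistics fitted on the training split."""
    age_median: float = 0.0
    age_mean: float = 0.0
    age_std: float = 1.0
    modes: dict = field(default_factory=dict)   # per categorical feature
    include_dx_type: bool = True
    fitted: bool = False

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "PreprocessStats":
        with open(path) as fh:
            return cls(**json.load(fh))


def _categorical_columns(include_dx_type: bool) -> list[str]:
    cols = ["dx_type", "sex", "localization"]
    if not include_dx_type:
        cols.remove("dx_type")
    return cols


def impute_and_encode(manifest: DatasetManifest,
                      stats: PreprocessStats | str = "fit",
                      include_dx_type: bool = True):
    """Impute missing metadata, one-hot encode, standardize the numerics.

    With ``stats="fit"`` the median age and categorical modes are computed on
    the given (training) manifest and returned alongside the encoding; with a
    fitted :class:`PreprocessStats` the stored statistics are applied without
    being updated.  The diagnosis is never part of the features.

    Returns ``(EncodedMetadata, labels, PreprocessStats)``.
    """
    fitting = isinstance(stats, str)
    if fitting and stats != "fit":
        raise ValueError(f"stats must be a PreprocessStats or 'fit': {stats!r}")
    if not fitting:
        if not stats.fitted:
            raise RuntimeError("PreprocessStats must be fitted before use")
        include_dx_type = stats.include_dx_type

    df = pd.DataFrame({
        "age": [r.age for r in manifest.records],
        "dx_type": [r.dx_type for r in manifest.records],
        "sex": [r.sex for r in manifest.records],
        "localization": [r.localization for r in manifest.records],
    })
    cat_cols = _categorical_columns(include_dx_type)

    if fitting:
        observed = df["age"].dropna()
        if observed.empty:
            raise ValueError("cannot fit: every age value is missing")
        median = float(observed.median())
        ages = df["age"].fillna(median).astype(float)
        mean = float(ages.mean())
        std = float(ages.std(ddof=0))
        if std == 0.0:
            std = 1.0
        modes = {}
        for col in cat_cols:
            obs = df[col].dropna()
            modes[col] = (obs.mode().iloc[0] if not obs.empty
                          else _CAT_VOCABS[col][0])
        stats = PreprocessStats(age_median=median, age_mean=mean, age_std=std,
                                modes=modes, include_dx_type=include_dx_type,
                                fitted=True)
    ages = df["age"].fillna(stats.age_median).astype(float)
    z_age = (ages - stats.age_mean) / stats.age_std

    encoder = OneHotEncoder(
        categories=[_CAT_VOCABS[c] for c in cat_cols],
        sparse_output=False, handle_unknown="error", dtype=np.float32)
    cat_df = df[cat_cols].copy()
    for col in cat_cols:
        cat_df[col] = cat_df[col].fillna(stats.modes[col])
    onehot = encoder.fit_transform(cat_df)     # fixed vocab: fit is data-free

    matrix = np.column_stack([z_age.to_numpy(np.float32), onehot]).astype(
        np.float32)
    names = ["age"] + [f"{col}={v}" for col in cat_cols
                       for v in _CAT_VOCABS[col]]
    encoded = EncodedMetadata(matrix=matrix, feature_names=names,
                              image_ids=manifest.image_ids)
    return encoded, manifest.labels(), stats


def _load_raw(record: ClinicalRecord, images: dict | None,
              manifest: DatasetManifest) -> np.ndarray:
    base_id = record.source_image_id or record.image_id
    if images is not None and base_id in images:
        raw = images[base_id]
    else:
        raw = read_image_file(manifest.image_paths[base_id])
    if record.augment is not None:
        rng = np.random.default_rng(record.augment.seed)
        raw = augment_image(raw, record.augment.op, record.augment.params,
                            rng)
    return raw


def assemble_arrays(manifest: DatasetManifest, images: dict | None,
                    stats: PreprocessStats | str, image_size: int,
                    include_dx_type: bool = True):
    """Build aligned (image batch, metadata matrix, labels) arrays.

    Row i of the metadata, label i and image i all belong to the same
    image_id; augmented records are rebuilt from their source image.
    Returns ``(X_img (N,3,S,S), encoded, labels, stats)``.
    """
    encoded, labels, stats = impute_and_encode(manifest, stats,
                                               include_dx_type)
    imgs = np.empty((len(manifest), 3, image_size, image_size),
                    dtype=np.float32)
    for i, record in enumerate(manifest.records):
        raw = _load_raw(record, images, manifest)
        imgs[i] = preprocess_image(raw, image_size).transpose(2, 0, 1)
    return imgs, encoded, labels, stats
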