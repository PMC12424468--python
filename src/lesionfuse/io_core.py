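"""Dataset manifest, run configuration, format readers and checkpointing.

The metadata schema follows the public HAM10000 distribution: one CSV row per
dermatoscopic image, keyed by ``image_id``, with the diagnosis (``dx``), how
it was confirmed (``dx_type``), and the patient's age, sex and lesion site.
Vocabularies are fixed in the schema rather than inferred from data so that
one-hot encodings have stable widths across cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "DX_LABELS", "DX_TYPES", "SEXES", "LOCALIZATIONS", "SCHEMA_COLUMNS",
    "ClinicalRecord", "AugmentSpec", "DatasetManifest", "RunConfig",
    "SchemaError", "ValidationError", "CheckpointError",
    "read_metadata_table", "write_manifest", "read_image_file",
    "save_checkpoint", "load_checkpoint", "setup_logging",
]

# Fixed schema vocabularies (HAM10000 conventions).
DX_LABELS = ("MEL", "NV", "BCC", "AKIEC", "BKL", "DF", "VASC")
DX_TYPES = ("histo", "follow_up", "consensus", "confocal")
SEXES = ("male", "female", "unknown")
LOCALIZATIONS = (
    "back", "lower extremity", "trunk", "upper extremity", "abdomen",
    "face", "chest", "foot", "unknown", "neck", "scalp", "hand", "ear",
    "genital", "acral",
)
SCHEMA_COLUMNS = ("lesion_id", "image_id", "dx", "dx_type", "age", "sex",
                  "localization")

# Tokens that mark a missing age in distributed CSVs.
_AGE_NA_TOKENS = {"", "NA", "unknown age", "nan"}
_CAT_NA_TOKENS = {"", "NA", "nan"}


class SchemaError(ValueError):
    """A required column is absent or the file does not match the schema."""


class ValidationError(ValueError):
    """Row-level contents violate the schema (e.g. an unknown diagnosis)."""


class CheckpointError(RuntimeError):
    """A checkpoint is incompatible with the model it is loaded into."""


@dataclass
class AugmentSpec:
    """Provenance of a synthetic training record: how to rebuild its image."""
    op: str                       # replicate | jitter | hflip | vflip | rotate | scale
    params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class ClinicalRecord:
    image_id: str
    lesion_id: str
    dx: str
    dx_type: str | None
    age: float | None            # None marks missing before imputation
    sex: str | None
    localization: str | None
    source_image_id: str | None = None   # set on balanced/augmented copies
    augment: AugmentSpec | None = None

    def __post_init__(self):
        if self.dx not in DX_LABELS:
            raise ValidationError(
                f"unknown dx label {self.dx!r} for image {self.image_id!r}; "
                f"expected one of {DX_LABELS}")


@dataclass
class DatasetManifest:
    """Ordered clinical records plus the image each one is joined to."""
    records: list[ClinicalRecord]
    image_paths: dict[str, str] = field(default_factory=dict)
    split_tag: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __post_init__(self):
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate image_id in manifest: {dupes[:5]}")

    @property
    def image_ids(self) -> list[str]:
        return [r.image_id for r in self.records]

    def labels(self) -> np.ndarray:
        """Integer class labels in the fixed DX_LABELS order."""
        lut = {d: i for i, d in enumerate(DX_LABELS)}
        return np.array([lut[r.dx] for r in self.records], dtype=np.int64)

    def class_counts(self) -> dict[str, int]:
        counts = {d: 0 for d in DX_LABELS}
        for r in self.records:
            counts[r.dx] += 1
        return counts

    def subset(self, indices) -> "DatasetManifest":
        recs = [self.records[i] for i in indices]
        paths = {}
        for r in recs:
            base_id = r.source_image_id or r.image_id
            if base_id in self.image_paths:
                paths[base_id] = self.image_paths[base_id]
        return DatasetManifest(recs, paths, self.split_tag)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "lesion_id": r.lesion_id, "image_id": r.image_id, "dx": r.dx,
                "dx_type": r.dx_type if r.dx_type is not None else "",
                "age": r.age if r.age is not None else "",
                "sex": r.sex if r.sex is not None else "",
                "localization": (r.localization
                                 if r.localization is not None else ""),
            })
        return pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))

    def validate_alignment(self) -> None:
        missing = [r.image_id for r in self.records
                   if (r.source_image_id or r.image_id) not in self.image_paths]
        if missing:
            raise ValidationError(
                f"{len(missing)} records without an image path, e.g. "
                f"{missing[:3]}")


def read_metadata_table(path: str | Path) -> DatasetManifest:
    """Parse a HAM10000-schema CSV into a manifest, preserving row order.

    Empty cells and NA tokens become explicit missing markers (``None``),
    never zeros.  A missing required column raises :class:`SchemaError`;
    unknown ``dx`` labels raise :class:`ValidationError` naming the rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"metadata file {path} is missing required column(s) "
            f"{missing_cols}")

    bad = [i for i, v in enumerate(df["dx"]) if v not in DX_LABELS]
    if bad:
        raise ValidationError(
            f"unknown dx label(s) at row(s) {bad[:10]}: "
            f"{sorted(set(df['dx'].iloc[bad]))}")

    records = []
    for row in df.itertuples(index=False):
        age_raw = str(row.age).strip()
        age = None if age_raw in _AGE_NA_TOKENS else float(age_raw)
        dx_type = None if str(row.dx_type).strip() in _CAT_NA_TOKENS else row.dx_type
        sex = None if str(row.sex).strip() in _CAT_NA_TOKENS else row.sex
        loc = None if str(row.localization).strip() in _CAT_NA_TOKENS else row.localization
        records.append(ClinicalRecord(
            image_id=row.image_id, lesion_id=row.lesion_id, dx=row.dx,
            dx_type=dx_type, age=age, sex=sex, localization=loc))
    return DatasetManifest(records)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    manifest.to_dataframe().to_csv(path, index=False)


def write_manifest_extended(manifest: DatasetManifest,
                            path: str | Path) -> None:
    """Write a manifest including augmentation provenance columns, so a
    balanced training split can be persisted and rebuilt exactly."""
    df = manifest.to_dataframe()
    df["source_image_id"] = [r.source_image_id or "" for r in manifest.records]
    df["augment_op"] = [r.augment.op if r.augment else ""
                        for r in manifest.records]
    df["augment_params"] = [json.dumps(r.augment.params) if r.augment else ""
                            for r in manifest.records]
    df["augment_seed"] = [r.augment.seed if r.augment else ""
                          for r in manifest.records]
    df["split_tag"] = manifest.split_tag or ""
    df.to_csv(path, index=False)


def read_manifest_extended(path: str | Path) -> DatasetManifest:
    """Read a manifest written by :func:`write_manifest_extended`."""
    base = read_metadata_table(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    split_tag = None
    if "split_tag" in df.columns and len(df) and df["split_tag"].iloc[0]:
        split_tag = df["split_tag"].iloc[0]
    if "source_image_id" in df.columns:
        for rec, (_, row) in zip(base.records, df.iterrows()):
            if row["source_image_id"]:
                rec.source_image_id = row["source_image_id"]
            if row.get("augment_op", ""):
                rec.augment = AugmentSpec(
                    op=row["augment_op"],
                    params=json.loads(row["augment_params"] or "{}"),
                    seed=int(row["augment_seed"] or 0))
    base.split_tag = split_tag
    return base


def attach_image_dir(manifest: DatasetManifest,
                     images_dir: str | Path) -> DatasetManifest:
    """Resolve each record's (source) image_id to a file in ``images_dir``."""
    images_dir = Path(images_dir)
    for r in manifest.records:
        base_id = r.source_image_id or r.image_id
        if base_id in manifest.image_paths:
            continue
        for ext in (".png", ".jpg", ".jpeg", ".PNG", ".JPG"):
            cand = images_dir / f"{base_id}{ext}"
            if cand.exists():
                manifest.image_paths[base_id] = str(cand)
                break
        else:
            raise FileNotFoundError(
                f"no image file for id {base_id!r} in {images_dir}")
    return manifest


def read_image_file(path: str | Path) -> np.ndarray:
    """Decode a PNG/JPEG into an H x W x 3 uint8 array.

    Grayscale inputs are replicated across channels; alpha channels dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (OSError, SyntaxError) as exc:
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    return arr


@dataclass
class RunConfig:
    """Training configuration; defaults are the published training recipe."""
    image_size: int = 256
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 0.001
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    fusion_method: str = "concat"
    # architecture widths (configurable; defaults give 512-d image and
    # 256-d clinical embeddings)
    base_width: int = 64
    image_dim: int = 512
    clinical_hidden: int = 128
    clinical_dim: int = 256
    dropout_p: float = 0.3
    leaky_slope: float = 0.01
    literal_softmax_head: bool = False
    n_classes: int = 7
    fusion: dict = field(default_factory=dict)   # per-method hyperparameters

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def save_checkpoint(model, config: RunConfig, path: str | Path) -> None:
    """Write model state plus its run configuration to a single .npz file."""
    state = model.state_dict()
    meta = json.dumps(dataclasses.asdict(config))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path, model=None):
    """Load a checkpoint; if ``model`` is given, restore its state.

    Returns ``(state_dict, RunConfig)``.  A fusion-method or shape mismatch
    raises :class:`CheckpointError`.
    """
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files if k != "__config__"}
        meta = json.loads(bytes(npz["__config__"].tobytes()).decode())
    config = RunConfig(**meta)
    if model is not None:
        try:
            model.load_state_dict(state)
        except ValueError as exc:
            raise CheckpointError(str(exc)) from exc
    return state, config


def setup_logging(out_dir: str | Path | None = None,
                  name: str = "lesionfuse") -> logging.Logger:
    """Plain-text log to stderr and, when ``out_dir`` is given, to a file."""
    logger = logging.getLogger(name)
    logger.setLevel(logging.INFO)
    if not logger.handlers:
        fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            fh = logging.FileHandler(Path(out_dir) / f"{name}.log")
            fh.setFormatter(fmt)
            logger.addHandler(fh)
    return logger
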