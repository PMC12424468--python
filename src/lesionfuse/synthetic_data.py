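"""Seeded synthetic dermatoscopic cohorts for end-to-end pipeline testing.

The generator emulates the *structure* of a public dermatoscopy archive —
seven diagnostic classes with a realistic imbalance, clinical metadata
(age 0-85 in 5-year steps, sex, lesion site, confirmation method) — and
procedurally plants a class signal in the images, the metadata, both, or an
XOR combination of the two.

The XOR mode is the designed probe for fusion superiority: the class label is
the exclusive-or of one binary image cue (lesion luminance) and one binary
metadata cue (lesion-site group), each cue individually near-uninformative.
A mild prior bias on the metadata cue caps any image-only classifier at a
Bayes accuracy of ~0.64 (and a metadata-only classifier at exactly 0.5),
while a fusion model that combines the cues can approach the much higher
joint ceiling; all three ceilings are computed exactly by
:func:`xor_bayes_accuracy` from the planted rates.

Class counts use a deterministic largest-remainder allocation so count-based
checks are exact, and the same ``(config, seed)`` always yields byte-identical
metadata and pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .io_core import (DX_LABELS, DX_TYPES, LOCALIZATIONS, SEXES,
                      ClinicalRecord, DatasetManifest)

__all__ = [
    "SynthConfig", "LesionStyle", "allocate_class_counts",
    "generate_metadata", "generate_cohort", "render_lesion_image",
    "class_style", "xor_bayes_accuracy", "XOR_CLASSES",
]

# Class imbalance of the emulated archive (counts of the seven diagnoses).
_ARCHIVE_COUNTS = {"MEL": 1113, "NV": 6705, "BCC": 514, "AKIEC": 327,
                   "BKL": 1099, "DF": 115, "VASC": 142}
_TOTAL = sum(_ARCHIVE_COUNTS.values())
DEFAULT_PROPORTIONS = tuple(_ARCHIVE_COUNTS[d] / _TOTAL for d in DX_LABELS)

# Baseline (label-independent) metadata distributions.
_SEX_P = (0.54, 0.45, 0.01)
_DX_TYPE_P = (0.53, 0.37, 0.07, 0.03)
_LOC_P = (0.22, 0.21, 0.10, 0.10, 0.08, 0.07, 0.05, 0.04, 0.03, 0.03,
          0.02, 0.01, 0.01, 0.01, 0.02)

# Class-conditional metadata shifts (means/preferences, used when the
# metadata modality carries signal).
_AGE_MEAN = {"MEL": 60, "NV": 35, "BCC": 65, "AKIEC": 70, "BKL": 60,
             "DF": 40, "VASC": 45}
_PREFERRED_LOC = {
    "MEL": ("back", "face"), "NV": ("trunk", "back"),
    "BCC": ("face", "neck"), "AKIEC": ("face", "scalp"),
    "BKL": ("trunk", "face"), "DF": ("lower extremity",),
    "VASC": ("trunk", "face"),
}
_DX_TYPE_BY_CLASS = {       # malignant lesions mostly histo-confirmed
    "MEL": (0.90, 0.02, 0.05, 0.03), "NV": (0.25, 0.60, 0.10, 0.05),
    "BCC": (0.92, 0.02, 0.04, 0.02), "AKIEC": (0.80, 0.05, 0.10, 0.05),
    "BKL": (0.55, 0.25, 0.15, 0.05), "DF": (0.60, 0.20, 0.15, 0.05),
    "VASC": (0.45, 0.25, 0.25, 0.05),
}

XOR_CLASSES = ("NV", "MEL")          # labels used by the two-class XOR probe
_XOR_LOC_GROUP0 = ("back", "trunk", "chest", "abdomen", "upper extremity")
_XOR_LOC_GROUP1 = ("lower extremity", "face", "foot", "neck", "scalp",
                   "hand", "ear", "genital", "acral", "unknown")


@dataclass(frozen=True)
class LesionStyle:
    """Rendering parameters for one lesion."""
    color: tuple[float, float, float]
    radius_frac: float = 0.24          # mean radius as a fraction of image size
    irregularity: float = 0.15         # radial border perturbation amplitude
    texture_sigma: float = 10.0        # internal texture noise (0-255 scale)


# Class-conditional styles: colours separated enough that a pixel-mean
# threshold distinguishes well-separated pairs.
_CLASS_STYLES = {
    "MEL": LesionStyle((60, 40, 35), 0.26, 0.35, 18.0),
    "NV": LesionStyle((150, 100, 70), 0.24, 0.10, 8.0),
    "BCC": LesionStyle((205, 150, 135), 0.22, 0.20, 10.0),
    "AKIEC": LesionStyle((185, 125, 100), 0.22, 0.25, 22.0),
    "BKL": LesionStyle((170, 140, 100), 0.24, 0.15, 14.0),
    "DF": LesionStyle((140, 85, 60), 0.15, 0.08, 8.0),
    "VASC": LesionStyle((185, 60, 90), 0.20, 0.06, 6.0),
}
_NEUTRAL_STYLE = LesionStyle((160, 110, 80), 0.22, 0.12, 10.0)
# The two XOR image-cue styles: a very dark vs a very light lesion.  The cue
# is carried by overall lesion luminance (not hue alone) so that it remains
# salient under global average pooling.
_XOR_STYLES = (LesionStyle((45, 30, 25), 0.30, 0.10, 8.0),
               LesionStyle((225, 160, 150), 0.30, 0.10, 8.0))

_SKIN_TONE = np.array([224.0, 172.0, 140.0])


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    n_samples: int = 1000
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    image_size: int = 64
    signal_mode: str = "both"          # image_only | metadata_only | both | xor
    background_sigma: float = 6.0      # background texture noise
    hair_rate: float = 0.3             # expected hair-strand artifacts / image
    cue_flip_rate_image: float = 0.02  # XOR mode: rendered-cue noise
    cue_flip_rate_meta: float = 0.02
    # Prior of the latent metadata cue.  A value away from 0.5 leaves the
    # metadata cue marginally useless but makes the image cue *near*-
    # uninformative (Bayes accuracy = max(prior, 1 - prior) for an
    # image-only classifier), which anchors the bound computed by
    # :func:`xor_bayes_accuracy` and gives the image branch a marginal
    # gradient to latch onto during joint training.
    xor_meta_cue_prior: float = 0.65
    missing_age_rate: float = 0.05     # fraction of blanked ages
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.class_proportions, dtype=float)
        if self.signal_mode not in ("image_only", "metadata_only", "both",
                                    "xor"):
            raise SynthConfigError(
                f"unknown signal_mode {self.signal_mode!r}")
        if self.signal_mode != "xor":
            if len(p) != len(DX_LABELS):
                raise SynthConfigError(
                    f"class_proportions must have {len(DX_LABELS)} entries")
            if abs(p.sum() - 1.0) > 1e-6:
                raise SynthConfigError(
                    f"class_proportions sum to {p.sum():.6f}, expected 1")
            if (p <= 0).any():
                raise SynthConfigError("class_proportions must be positive")
        if self.n_samples < len(DX_LABELS) and self.signal_mode != "xor":
            raise SynthConfigError("n_samples must be >= number of classes")


def allocate_class_counts(n: int, proportions) -> np.ndarray:
    """Deterministic largest-remainder allocation of ``n`` among classes."""
    p = np.asarray(proportions, dtype=float)
    exact = n * p
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    # ties broken by class order (stable argsort on negated fractions)
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def class_style(dx: str) -> LesionStyle:
    return _CLASS_STYLES[dx]


def _perturbed_radius(theta: np.ndarray, irregularity: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Radial border modulation: a short sum of random harmonics."""
    if irregularity == 0:
        return np.ones_like(theta)
    mod = np.zeros_like(theta)
    for k in range(2, 6):
        amp = rng.uniform(0.2, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        mod += amp * np.sin(k * theta + phase)
    mod /= np.max(np.abs(mod)) + 1e-9
    return 1.0 + irregularity * mod


def render_lesion_image(dx_or_style, image_size: int,
                        rng: np.random.Generator,
                        background_sigma: float = 6.0,
                        hair_rate: float = 0.3) -> np.ndarray:
    """Render one synthetic lesion: skin-tone background, one elliptical
    lesion with class-conditional colour / border irregularity / texture,
    optional dark hair-strand artifacts.  Returns H x W x 3 uint8."""
    style = (dx_or_style if isinstance(dx_or_style, LesionStyle)
             else class_style(dx_or_style))
    s = image_size
    base = _SKIN_TONE + rng.normal(0, 8, size=3)
    img = np.clip(base[None, None, :]
                  + rng.normal(0, background_sigma, size=(s, s, 3)), 0, 255)

    # ellipse geometry
    cy, cx = (s / 2 + rng.uniform(-0.06, 0.06) * s for _ in range(2))
    r_mean = style.radius_frac * s * rng.uniform(0.85, 1.15)
    aspect = rng.uniform(0.7, 1.0)
    angle = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:s, 0:s]
    dy, dx_ = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx_ + sa * dy) / r_mean
    v = (-sa * dx_ + ca * dy) / (r_mean * aspect)
    theta = np.arctan2(v, u)
    rr = np.sqrt(u ** 2 + v ** 2)
    boundary = _perturbed_radius(theta, style.irregularity, rng)
    mask = rr <= boundary

    lesion_color = np.asarray(style.color, dtype=float) + rng.normal(0, 6, 3)
    texture = rng.normal(0, style.texture_sigma, size=(s, s, 3))
    # darken towards the centre for a mild radial gradient
    depth = np.clip(1.0 - rr / np.maximum(boundary, 1e-9), 0, 1)
    lesion = (lesion_color[None, None, :] * (1.0 - 0.25 * depth[..., None])
              + texture)
    img[mask] = np.clip(lesion, 0, 255)[mask]

    # hair-strand artifacts: dark quadratic arcs across the frame
    n_hairs = rng.poisson(hair_rate)
    for _ in range(n_hairs):
        x0, x1 = rng.uniform(0, s, size=2)
        y0, y1 = rng.uniform(0, s, size=2)
        bend = rng.uniform(-0.4, 0.4) * s
        t = np.linspace(0, 1, 3 * s)
        xs = (1 - t) * x0 + t * x1
        ys = (1 - t) * y0 + t * y1 + bend * t * (1 - t)
        xi = np.clip(np.round(xs).astype(int), 0, s - 1)
        yi = np.clip(np.round(ys).astype(int), 0, s - 1)
        img[yi, xi] = img[yi, xi] * 0.25
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _draw_choice(rng, values, p):
    return values[rng.choice(len(values), p=np.asarray(p) / np.sum(p))]


def _baseline_age(rng) -> float:
    return float(np.clip(np.round(rng.uniform(0, 85) / 5) * 5, 0, 85))


def _class_age(dx: str, rng) -> float:
    a = rng.normal(_AGE_MEAN[dx], 12.0)
    return float(np.clip(np.round(a / 5) * 5, 0, 85))


def _metadata_row(i: int, dx: str, signal: bool, rng) -> ClinicalRecord:
    if signal:
        age = _class_age(dx, rng)
        dxt = _draw_choice(rng, DX_TYPES, _DX_TYPE_BY_CLASS[dx])
        if rng.random() < 0.5:
            loc = _PREFERRED_LOC[dx][rng.choice(len(_PREFERRED_LOC[dx]))]
        else:
            loc = _draw_choice(rng, LOCALIZATIONS, _LOC_P)
    else:
        age = _baseline_age(rng)
        dxt = _draw_choice(rng, DX_TYPES, _DX_TYPE_P)
        loc = _draw_choice(rng, LOCALIZATIONS, _LOC_P)
    sex = _draw_choice(rng, SEXES, _SEX_P)
    return ClinicalRecord(
        image_id=f"SYN{i:07d}", lesion_id=f"SYNL{i:07d}", dx=dx,
        dx_type=dxt, age=age, sex=sex, localization=loc)


def _xor_rows(config: SynthConfig, rng):
    """Two-class XOR cohort: label = image cue XOR metadata cue.

    Labels are allocated exactly 50/50; given the label, the latent cue pair
    is drawn from its conditional distribution under a fair image-cue prior
    and a (by default mildly biased) metadata-cue prior, then each rendered
    cue is flipped at its observation-noise rate.
    """
    n = config.n_samples
    counts = allocate_class_counts(n, (0.5, 0.5))
    labels = np.concatenate([np.zeros(counts[0], int), np.ones(counts[1], int)])
    rng.shuffle(labels)
    pm = config.xor_meta_cue_prior
    rows, img_cues = [], []
    for i, y in enumerate(labels):
        # pairs (c_img, c_meta) with c_img ^ c_meta == y; image prior is 0.5
        # so the conditional weight of c_meta = 1 is simply pm
        c_meta = int(rng.random() < pm)
        c_img = c_meta ^ int(y)
        # observation noise on each rendered cue
        obs_img = c_img ^ int(rng.random() < config.cue_flip_rate_image)
        obs_meta = c_meta ^ int(rng.random() < config.cue_flip_rate_meta)
        group = _XOR_LOC_GROUP1 if obs_meta else _XOR_LOC_GROUP0
        loc = group[rng.choice(len(group))]
        rec = ClinicalRecord(
            image_id=f"SYN{i:07d}", lesion_id=f"SYNL{i:07d}",
            dx=XOR_CLASSES[y],
            dx_type=_draw_choice(rng, DX_TYPES, _DX_TYPE_P),
            age=_baseline_age(rng),
            sex=_draw_choice(rng, SEXES, _SEX_P),
            localization=loc)
        rows.append(rec)
        img_cues.append(obs_img)
    return rows, img_cues


def generate_metadata(config: SynthConfig) -> DatasetManifest:
    """Metadata-only cohort (no images rendered); see :func:`generate_cohort`."""
    manifest, _ = generate_cohort(config, render_images=False)
    return manifest


def generate_cohort(config: SynthConfig, out_dir: str | Path | None = None,
                    render_images: bool = True):
    """Generate a cohort: returns ``(manifest, images)``.

    ``images`` maps image_id to an H x W x 3 uint8 array (empty when
    ``render_images`` is False).  When ``out_dir`` is given the images are
    written as PNGs and a ``metadata.csv`` alongside, in exactly the schema
    :func:`lesionfuse.io_core.read_metadata_table` reads.
    """
    rng = np.random.default_rng(config.seed)
    meta_signal = config.signal_mode in ("metadata_only", "both")
    image_signal = config.signal_mode in ("image_only", "both")

    if config.signal_mode == "xor":
        rows, img_cues = _xor_rows(config, rng)
        styles = [_XOR_STYLES[c] for c in img_cues]
    else:
        counts = allocate_class_counts(config.n_samples,
                                       config.class_proportions)
        dx_seq = np.concatenate([np.full(c, k) for k, c in enumerate(counts)])
        rng.shuffle(dx_seq)
        rows = [_metadata_row(i, DX_LABELS[k], meta_signal, rng)
                for i, k in enumerate(dx_seq)]
        styles = [class_style(r.dx) if image_signal else _NEUTRAL_STYLE
                  for r in rows]

    # blank a stated fraction of ages to exercise imputation
    for r in rows:
        if rng.random() < config.missing_age_rate:
            r.age = None

    images: dict[str, np.ndarray] = {}
    if render_images:
        for rec, style in zip(rows, styles):
            images[rec.image_id] = render_lesion_image(
                style, config.image_size, rng,
                background_sigma=config.background_sigma,
                hair_rate=config.hair_rate)

    manifest = DatasetManifest(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        for image_id, arr in images.items():
            path = img_dir / f"{image_id}.png"
            Image.fromarray(arr).save(path)
            manifest.image_paths[image_id] = str(path)
        manifest.to_dataframe().to_csv(out_dir / "metadata.csv", index=False)
    return manifest, images


def xor_bayes_accuracy(config: SynthConfig) -> dict[str, float]:
    """Exact Bayes-optimal accuracies for the XOR cohort, by enumeration.

    The joint distribution over (label, observed image cue, observed
    metadata cue) is enumerated from the generator's planted rates: balanced
    labels, conditional cue pairs under the metadata-cue prior, and the two
    observation-noise flip rates.  Each classifier's ceiling is the sum over
    its observable of the larger class posterior mass.
    """
    f1, f2 = config.cue_flip_rate_image, config.cue_flip_rate_meta
    pm = config.xor_meta_cue_prior
    # joint[y, obs_img, obs_meta]
    joint = np.zeros((2, 2, 2))
    for y in (0, 1):
        for c_meta in (0, 1):
            p_pair = 0.5 * (pm if c_meta else 1 - pm)
            c_img = c_meta ^ y
            for o_img in (0, 1):
                p_i = (1 - f1) if o_img == c_img else f1
                for o_meta in (0, 1):
                    p_m = (1 - f2) if o_meta == c_meta else f2
                    joint[y, o_img, o_meta] += p_pair * p_i * p_m

    def bayes(marginal: np.ndarray) -> float:
        # marginal[y, observable]: pick the majority label per observation
        return float(marginal.max(axis=0).sum())

    return {
        "image_only": bayes(joint.sum(axis=2)),
        "metadata_only": bayes(joint.sum(axis=1)),
        "fused": bayes(joint.reshape(2, 4)),
    }
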