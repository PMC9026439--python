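"""Training-set augmentation for paired two-stage samples.

Three strategies are supported, mirroring the ablation grid: geometric
transforms (rotation, flips, zoom) that keep tumour shapes realistic,
Mixup (convex image/label blending), and minority-class upsampling that
duplicates minority pairs with fresh geometric transforms until the two
classes are balanced.

One spatial transform is drawn per call and applied IDENTICALLY to both
stage images of a pair — independent draws would destroy the
cross-stage correspondence the dual-branch architecture exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy import ndimage
from skimage.transform import rescale

from .errors import ValidationError
from .manifest import MANIFEST_COLUMNS, load_image, pair_table, validate_manifest
from .preprocessing import PairedSample

STRATEGIES = ("none", "geometric", "mixup", "upsample_minority")


@dataclass
class AugmentConfig:
    strategy: str = "none"
    rotation_range: float = 15.0           # degrees, symmetric
    allow_hflip: bool = True
    allow_vflip: bool = True
    zoom_range: tuple[float, float] = (0.9, 1.1)
    mixup_alpha: float = 0.2               # Beta(a, a) concentration
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"strategy must be one of {STRATEGIES}")
        if self.zoom_range[0] <= 0 or self.zoom_range[0] > self.zoom_range[1]:
            raise ValidationError(f"invalid zoom_range {self.zoom_range}")
        if self.mixup_alpha <= 0:
            raise ValidationError("mixup_alpha must be > 0")
        if self.rotation_range < 0:
            raise ValidationError("rotation_range must be >= 0")


def _rotate(img: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg == 0.0:
        return img
    out = ndimage.rotate(img, angle_deg, reshape=False, order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _zoom(img: np.ndarray, factor: float) -> np.ndarray:
    """Rescale then centre-crop (zoom in) or reflect-pad (zoom out)."""
    if factor == 1.0:
        return img
    h, w = img.shape
    z = rescale(img, factor, order=1, mode="reflect", anti_aliasing=factor < 1,
                preserve_range=True)
    zh, zw = z.shape
    if zh >= h:
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        out = z[r0:r0 + h, c0:c0 + w]
    else:
        pr, pc = h - zh, w - zw
        out = np.pad(z, ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)),
                     mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _apply_transform(img: np.ndarray, angle: float, hflip: bool, vflip: bool,
                     zoom: float) -> np.ndarray:
    out = img
    if hflip:
        out = out[:, ::-1]
    if vflip:
        out = out[::-1, :]
    out = _rotate(out, angle)
    return _zoom(out, zoom)


def geometric_augment(sample: PairedSample, config: AugmentConfig,
                      rng: np.random.Generator) -> PairedSample:
    """Draw one (rotation, flips, zoom) transform and apply it to both
    stage images; the label and sizes are unchanged."""
    angle = float(rng.uniform(-config.rotation_range, config.rotation_range)) \
        if config.rotation_range > 0 else 0.0
    hflip = config.allow_hflip and bool(rng.random() < 0.5)
    vflip = config.allow_vflip and bool(rng.random() < 0.5)
    zoom = float(rng.uniform(*config.zoom_range))
    return PairedSample(
        _apply_transform(sample.pre, angle, hflip, vflip, zoom),
        _apply_transform(sample.post, angle, hflip, vflip, zoom),
        sample.label, sample.patient_id, sample.frame_index)


def mixup(sample_a: PairedSample, sample_b: PairedSample,
          lam: float) -> PairedSample:
    """Convex combination of two pairs with the SAME lambda for both
    stages; the label becomes the soft vector lam*onehot(a)+(1-lam)*onehot(b)."""
    if not 0.0 <= lam <= 1.0:
        raise ValidationError(f"lambda must be in [0,1], got {lam}")
    if lam == 1.0:
        return sample_a
    if lam == 0.0:
        return sample_b
    label = lam * sample_a.label_vector + (1.0 - lam) * sample_b.label_vector
    return PairedSample(
        lam * sample_a.pre + (1.0 - lam) * sample_b.pre,
        lam * sample_a.post + (1.0 - lam) * sample_b.post,
        label, sample_a.patient_id, sample_a.frame_index)


def draw_mixup_lambda(config: AugmentConfig, rng: np.random.Generator) -> float:
    return float(rng.beta(config.mixup_alpha, config.mixup_alpha))


def upsample_minority(manifest: pd.DataFrame, config: AugmentConfig,
                      rng: np.random.Generator,
                      out_dir: str | Path | None = None) -> pd.DataFrame:
    """Duplicate minority-class TRAIN pairs with fresh geometric
    transforms until per-class pair counts are equal; the test split is
    untouched and every original row survives.

    Transformed copies are written next to the originals (or under
    ``out_dir``) with an ``aug`` suffix and appended as new frame
    indices.
    """
    validate_manifest(manifest)
    train = manifest[manifest["split"] == "train"]
    if len(train) == 0:
        raise ValidationError("train split is empty")
    pairs = pair_table(train)
    counts = pairs["label"].value_counts()
    if len(counts) < 2:
        raise ValidationError("both classes must be present in the train split")
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return manifest.copy()
    pool = pairs[pairs["label"] == minority].reset_index(drop=True)
    picks = rng.integers(0, len(pool), size=deficit)
    next_frame = {pid: int(g["frame_index"].max()) + 1
                  for pid, g in manifest.groupby("patient_id")}
    new_rows = []
    for j, pick in enumerate(picks):
        row = pool.iloc[int(pick)]
        sample = PairedSample(load_image(row["path_pre"]), load_image(row["path_post"]),
                              row["label"], row["patient_id"], int(row["frame_index"]))
        aug = geometric_augment(sample, config, rng)
        base = Path(out_dir) if out_dir is not None else Path(row["path_pre"]).parent
        base.mkdir(parents=True, exist_ok=True)
        k = next_frame[row["patient_id"]]
        next_frame[row["patient_id"]] += 1
        for stage, img in (("pre", aug.pre), ("post1", aug.post)):
            path = base / f"{stage}_{k:03d}_aug.png"
            iio.imwrite(path, (np.clip(img, 0, 1) * 255).round().astype(np.uint8))
            new_rows.append({"patient_id": row["patient_id"], "label": row["label"],
                             "stage": stage, "frame_index": k,
                             "path": str(path), "split": "train"})
    out = pd.concat([manifest, pd.DataFrame(new_rows, columns=MANIFEST_COLUMNS)],
                    ignore_index=True)
    return out
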