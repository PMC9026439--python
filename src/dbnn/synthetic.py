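"""Seeded synthetic cohorts of paired two-stage speckled ultrasound-like
images.

Each synthetic patient carries a hypoechoic (darker-than-background)
elliptical lesion rendered over a multiplicative speckle field — the
envelope of smoothed complex Gaussian noise, whose Rayleigh-like
granularity mimics B-mode texture.  The stage-1 (pre-treatment) lesion
parameters are drawn from the SAME priors for both classes; the class
signal lives entirely in the stage-1 -> stage-2 change: responders
(pCR) shrink by a factor drawn from ``pcr_shrinkage_range`` while
non-responders keep (or slightly grow) their lesion via
``nonpcr_shrinkage_range``.  A classifier looking at stage 1 alone is
therefore near chance by construction, which is exactly the premise the
dual-branch architecture is meant to exploit.

Everything is deterministic in (config, seed): identical configs yield
byte-identical images and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy.ndimage import gaussian_filter

from .errors import ValidationError, GeometryError
from .manifest import write_manifest, new_manifest_frame

#: background mean intensity of the rendered field
BG_MEAN = 0.55
#: spatial correlation (pixels) of the speckle granules
SPECKLE_SIGMA = 1.5


@dataclass
class SyntheticConfig:
    """Knobs of the phantom generator.

    Defaults emulate the study conditions: ~34.2% pCR prevalence, 16-20
    frames per patient, and a 445x445 rendering canvas matching the ROI
    dimension (set ``image_size`` to the network input size for a fast
    mode that skips the downstream resize).
    """

    n_patients: int = 114
    pcr_fraction: float = 0.342
    frames_per_patient_range: tuple[int, int] = (16, 20)
    image_size: int = 445
    lesion_radius_range: tuple[float, float] | None = None
    lesion_contrast: float = 0.35
    pcr_shrinkage_range: tuple[float, float] = (0.0, 0.3)
    nonpcr_shrinkage_range: tuple[float, float] = (0.8, 1.1)
    speckle_scale: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.lesion_radius_range is None:
            # lesion semi-axes span roughly 10-22% of the canvas
            self.lesion_radius_range = (0.10 * self.image_size,
                                        0.22 * self.image_size)
        self.validate()

    def validate(self) -> None:
        def _finite(name, v):
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} must be finite, got {v}")

        for name in ("pcr_fraction", "lesion_contrast", "speckle_scale"):
            _finite(name, getattr(self, name))
        if not 0.0 <= self.pcr_fraction <= 1.0:
            raise ValidationError(f"pcr_fraction must be in [0,1], got {self.pcr_fraction}")
        if self.n_patients < 1:
            raise ValidationError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in ("frames_per_patient_range", "lesion_radius_range",
                     "pcr_shrinkage_range", "nonpcr_shrinkage_range"):
            lo, hi = getattr(self, name)
            _finite(name, (lo, hi))
            if lo > hi:
                raise ValidationError(f"{name}: lower {lo} > upper {hi}")
            if name.endswith("shrinkage_range") and lo < 0:
                raise ValidationError(f"{name}: shrinkage factors must be >= 0")
        if self.frames_per_patient_range[0] < 1:
            raise ValidationError("frames_per_patient_range lower bound must be >= 1")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise ValidationError("lesion_contrast must be in [0,1]")
        if self.speckle_scale < 0:
            raise ValidationError("speckle_scale must be >= 0")
        if self.image_size < 8:
            raise ValidationError("image_size must be >= 8")


@dataclass
class LesionParams:
    """One elliptical hypoechoic lesion: centre (row, col), semi-axes
    (pixels), orientation (radians), intensity deficit vs background."""

    center: tuple[float, float]
    axes: tuple[float, float]
    orientation: float
    contrast: float


@dataclass
class PatientRecord:
    patient_id: str
    label: str                       # 'pCR' | 'non-pCR'
    stage1: LesionParams
    stage2: LesionParams
    shrinkage: float
    n_frames: int


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    patients: list[PatientRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patients)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw per-patient labels, frame counts and two-stage lesion geometry.

    The number of pCR patients is exactly ``round(n_patients * pcr_fraction)``;
    stage-2 semi-axes are the stage-1 axes scaled by a factor drawn from the
    label's shrinkage range.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_pcr = int(round(n * config.pcr_fraction))
    labels = np.array(["pCR"] * n_pcr + ["non-pCR"] * (n - n_pcr))
    rng.shuffle(labels)

    size = config.image_size
    lo_r, hi_r = config.lesion_radius_range
    f_lo, f_hi = config.frames_per_patient_range
    patients = []
    for i, label in enumerate(labels):
        a = rng.uniform(lo_r, hi_r)
        b = rng.uniform(lo_r, hi_r)
        # keep the lesion inside the canvas with a safety margin
        margin = max(a, b) * 1.1 + 2
        cr = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
        cc = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
        theta = rng.uniform(0.0, np.pi)
        contrast = config.lesion_contrast * rng.uniform(0.8, 1.2)
        stage1 = LesionParams((cr, cc), (a, b), theta, contrast)
        rng_range = (config.pcr_shrinkage_range if label == "pCR"
                     else config.nonpcr_shrinkage_range)
        s = rng.uniform(*rng_range)
        jitter = rng.normal(0.0, 0.01 * size, size=2)
        stage2 = LesionParams((cr + jitter[0], cc + jitter[1]),
                              (a * s, b * s), theta, contrast)
        n_frames = int(rng.integers(f_lo, f_hi + 1))
        patients.append(PatientRecord(f"P{i:04d}", str(label), stage1, stage2,
                                      float(s), n_frames))
    return SyntheticCohort(config=config, patients=patients)


def lesion_mask(lesion: LesionParams, canvas_size: int) -> np.ndarray:
    """Boolean mask of the rotated ellipse on a canvas_size^2 grid."""
    rr, cc = np.mgrid[0:canvas_size, 0:canvas_size].astype(float)
    dr = rr - lesion.center[0]
    dc = cc - lesion.center[1]
    ct, st = np.cos(lesion.orientation), np.sin(lesion.orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    a, b = lesion.axes
    if a < 0.5 or b < 0.5:          # lesion effectively resolved
        return np.zeros((canvas_size, canvas_size), dtype=bool)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_stage_image(lesion: LesionParams, canvas_size: int,
                       speckle_scale: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Render one frame: multiplicative speckle over a piecewise-constant
    echogenicity field, lesion darker by its contrast, clipped to [0, 1].
    """
    a, b = lesion.axes
    if max(a, b) >= 0.5:
        margin = max(a, b)
        for coord in lesion.center:
            if coord - margin < -1 or coord + margin > canvas_size + 1:
                raise GeometryError(
                    f"lesion (centre {lesion.center}, axes {lesion.axes}) "
                    f"does not fit in a {canvas_size}x{canvas_size} canvas")
    mean_field = np.full((canvas_size, canvas_size), BG_MEAN)
    mean_field[lesion_mask(lesion, canvas_size)] = max(BG_MEAN - lesion.contrast, 0.0)
    if speckle_scale > 0:
        re = gaussian_filter(rng.standard_normal((canvas_size, canvas_size)),
                             SPECKLE_SIGMA)
        im = gaussian_filter(rng.standard_normal((canvas_size, canvas_size)),
                             SPECKLE_SIGMA)
        env = np.hypot(re, im)                       # Rayleigh-like envelope
        tex = 1.0 + speckle_scale * (env / env.mean() - 1.0)
    else:
        tex = 1.0
    return np.clip(mean_field * tex, 0.0, 1.0)


def generate_paired_dataset(cohort: SyntheticCohort,
                            out_dir: str | Path) -> pd.DataFrame:
    """Render and write all frames as 8-bit PNGs and return the manifest.

    For every patient, ``n_frames`` frame pairs are written; the two
    stages of a pair share lesion geometry per stage but have independent
    speckle realisations.  One manifest row per (patient, frame, stage).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise ValidationError(f"cannot create output directory {out_dir}: {e}") from e
    cfg = cohort.config
    rows = []
    for pat in cohort.patients:
        rng = np.random.default_rng([cfg.seed, int(pat.patient_id[1:]), 7])
        pdir = out_dir / pat.patient_id
        pdir.mkdir(exist_ok=True)
        for k in range(pat.n_frames):
            for stage_name, lesion in (("pre", pat.stage1), ("post1", pat.stage2)):
                img = render_stage_image(lesion, cfg.image_size,
                                         cfg.speckle_scale, rng)
                path = pdir / f"{stage_name}_{k:03d}.png"
                iio.imwrite(path, (img * 255).round().astype(np.uint8))
                rows.append({"patient_id": pat.patient_id, "label": pat.label,
                             "stage": stage_name, "frame_index": k,
                             "path": str(path), "split": "unassigned"})
    manifest = new_manifest_frame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def split_patients(manifest: pd.DataFrame, train_fraction: float = 0.8,
                   seed: int = 0) -> pd.DataFrame:
    """Assign train/test at the PATIENT level, preserving class balance.

    Per-class training counts follow a largest-remainder apportionment of
    ``round(n_patients * train_fraction)`` slots, so the pCR:non-pCR
    ratio of each side matches the cohort as closely as integers allow;
    no patient ever appears in both splits.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValidationError(f"train_fraction must be in (0,1], got {train_fraction}")
    pat = manifest[["patient_id", "label"]].drop_duplicates()
    if pat["patient_id"].duplicated().any():
        bad = pat[pat["patient_id"].duplicated()]["patient_id"].iloc[0]
        raise ValidationError(f"patient {bad} has conflicting labels")
    if manifest["label"].isna().any():
        raise ValidationError("every patient needs a label before splitting")
    rng = np.random.default_rng(seed)
    n_total = len(pat)
    target = int(round(n_total * train_fraction))
    classes = sorted(pat["label"].unique())
    quotas = {c: (pat["label"] == c).sum() * train_fraction for c in classes}
    alloc = {c: int(np.floor(quotas[c])) for c in classes}
    # distribute remaining slots by largest fractional remainder
    leftovers = sorted(classes, key=lambda c: quotas[c] - alloc[c], reverse=True)
    i = 0
    while sum(alloc.values()) < target:
        c = leftovers[i % len(leftovers)]
        if alloc[c] < (pat["label"] == c).sum():
            alloc[c] += 1
        i += 1
    train_ids: set[str] = set()
    for c in classes:
        ids = pat.loc[pat["label"] == c, "patient_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        train_ids.update(ids[:alloc[c]])
    out = manifest.copy()
    out["split"] = np.where(out["patient_id"].isin(train_ids), "train", "test")
    return out


def class_ratio(manifest: pd.DataFrame, split: str | None = None) -> float:
    """pCR : non-pCR row ratio of a manifest (optionally one split)."""
    df = manifest if split is None else manifest[manifest["split"] == split]
    n_pcr = (df["label"] == "pCR").sum()
    n_non = (df["label"] == "non-pCR").sum()
    if n_non == 0:
        raise ValidationError("no non-pCR rows; ratio undefined")
    return n_pcr / n_non
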