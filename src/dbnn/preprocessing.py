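"""Frame-to-network preprocessing chain.

An ultrasound cine loop is modelled as an ordered directory of frames.
The chain is: frame extraction at a fixed interval -> quality-control
selection (an explicit index list standing in for the radiologists'
manual review) -> sequential cross-stage pairing (frame k of the
pre-treatment sequence with frame k of the after-cycle-1 sequence, so
each pair is closest in acquisition time) -> ROI crop (default
445x445) -> median denoising (edge-preserving) -> standardisation to
128x128 grayscale in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter
from skimage.transform import resize

from .errors import ValidationError, GeometryError, ContractError

DEFAULT_ROI = 445
DEFAULT_TARGET = 128
DEFAULT_KERNEL = 3
DEFAULT_FRAME_INTERVAL = 5


def as_gray_image(arr) -> np.ndarray:
    """Validate and return an H x W float image with values in [0, 1]."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 3:
        a = a[..., :3] @ np.array([0.299, 0.587, 0.114])
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
        raise ValidationError(f"expected an HxW image with H,W >= 3, got shape {arr.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError("image contains non-finite values")
    if a.min() < 0.0 or a.max() > 1.0:
        raise ValidationError(
            f"intensities must lie in [0,1]; got range [{a.min():.3g}, {a.max():.3g}]"
            " (divide 8-bit values by 255 first)")
    return a


@dataclass
class FrameSequence:
    """Ordered frames from one patient/stage; all frames equal size."""

    frames: list[np.ndarray]
    source: str = ""

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValidationError(f"empty frame sequence (source={self.source!r})")
        self.frames = [as_gray_image(f) for f in self.frames]
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValidationError(f"frames differ in size: {shapes}")

    def __len__(self):
        return len(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass(frozen=True)
class ROIBox:
    """0-based, half-open crop box."""

    row_start: int
    col_start: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValidationError("ROI box must have height, width >= 1")
        if self.row_start < 0 or self.col_start < 0:
            raise ValidationError("ROI box offsets must be non-negative")


@dataclass
class PairedSample:
    """One (pre, post) image pair with its label and provenance.

    ``label`` is 'pCR'/'non-pCR' for ordinary samples; Mixup produces a
    soft length-2 vector in (pCR, non-pCR) order instead.
    """

    pre: np.ndarray
    post: np.ndarray
    label: object
    patient_id: str
    frame_index: int

    def __post_init__(self):
        if self.pre.shape != self.post.shape:
            raise ContractError(
                f"pre {self.pre.shape} and post {self.post.shape} differ in size")

    @property
    def label_vector(self) -> np.ndarray:
        if isinstance(self.label, str):
            return np.array([1.0, 0.0]) if self.label == "pCR" else np.array([0.0, 1.0])
        return np.asarray(self.label, dtype=float)


# ------------------------------------------------------------------ frames

def extract_frames(sequence: FrameSequence, frame_interval: int) -> FrameSequence:
    """Keep frames at indices 0, interval, 2*interval, ... (order kept)."""
    if frame_interval < 1:
        raise ValidationError(f"frame_interval must be >= 1, got {frame_interval}")
    return FrameSequence(sequence.frames[::frame_interval], sequence.source)


def select_frames(sequence: FrameSequence, keep_indices) -> FrameSequence:
    """Keep exactly the listed frames (strictly increasing 0-based indices);
    models the manual quality-control step as a reproducible index list."""
    idx = list(keep_indices)
    if len(idx) == 0:
        raise ValidationError("keep_indices must select at least one frame")
    if any(i < 0 or i >= len(sequence) for i in idx):
        raise ValidationError(f"index out of range 0..{len(sequence) - 1}: {idx}")
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValidationError(f"indices must be strictly increasing, got {idx}")
    return FrameSequence([sequence.frames[i] for i in idx], sequence.source)


def pair_frames(pre_seq: FrameSequence, post_seq: FrameSequence,
                label: str, patient_id: str) -> list[PairedSample]:
    """Pair frame k with frame k; both stages of one patient must have the
    same N (it may differ between patients)."""
    if len(pre_seq) != len(post_seq):
        raise ContractError(
            f"patient {patient_id}: {len(pre_seq)} pre vs {len(post_seq)} post frames;"
            " the two stages of each patient must have the same N")
    return [PairedSample(pre_seq[k], post_seq[k], label, patient_id, k)
            for k in range(len(pre_seq))]


# ------------------------------------------------------------------ images

def crop_roi(image: np.ndarray, box: ROIBox) -> np.ndarray:
    image = as_gray_image(image)
    h, w = image.shape
    if box.row_start + box.height > h:
        raise GeometryError(
            f"ROI rows [{box.row_start}, {box.row_start + box.height}) exceed image height {h}")
    if box.col_start + box.width > w:
        raise GeometryError(
            f"ROI cols [{box.col_start}, {box.col_start + box.width}) exceed image width {w}")
    return image[box.row_start:box.row_start + box.height,
                 box.col_start:box.col_start + box.width]


def centered_roi(image: np.ndarray, side: int = DEFAULT_ROI) -> ROIBox:
    """Centred square box of the given side, shrunk to the image if needed."""
    h, w = np.asarray(image).shape[:2]
    s = min(side, h, w)
    return ROIBox((h - s) // 2, (w - s) // 2, s, s)


def denoise_median(image: np.ndarray, kernel: int = DEFAULT_KERNEL) -> np.ndarray:
    """Median filter with reflect padding (edge not duplicated, i.e.
    ``abc -> cb|abc|ba``); odd kernel >= 3."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValidationError(f"kernel must be an odd integer >= 3, got {kernel}")
    return median_filter(as_gray_image(image), size=kernel, mode="mirror")


def standardize(image: np.ndarray, target: int = DEFAULT_TARGET) -> np.ndarray:
    """Bilinear resample to target x target, clipped to [0, 1]."""
    image = as_gray_image(image)
    if image.shape == (target, target):
        return image
    out = resize(image, (target, target), order=1, mode="reflect",
                 anti_aliasing=image.shape[0] > target, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


@dataclass
class PreprocessParams:
    frame_interval: int = DEFAULT_FRAME_INTERVAL
    roi: ROIBox | None = None          # None -> centred 445 (or full image)
    kernel: int = DEFAULT_KERNEL
    target: int = DEFAULT_TARGET


def preprocess_pair(raw_pair: PairedSample,
                    params: PreprocessParams | None = None) -> PairedSample:
    """crop -> median -> standardize, applied identically to both stages."""
    params = params or PreprocessParams()
    box = params.roi or centered_roi(raw_pair.pre)

    def chain(img):
        return standardize(denoise_median(crop_roi(img, box), params.kernel),
                           params.target)

    return PairedSample(chain(raw_pair.pre), chain(raw_pair.post),
                        raw_pair.label, raw_pair.patient_id, raw_pair.frame_index)


def load_frame_dir(path: str | Path) -> FrameSequence:
    """Read an ordered image-sequence directory (stand-in for a cine loop)."""
    from .manifest import load_image
    path = Path(path)
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg"))
    if not files:
        raise ValidationError(f"no image frames found in {path}")
    return FrameSequence([load_image(p) for p in files], source=str(path))
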