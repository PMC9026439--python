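"""Dataset manifest: the table binding patients -> stage image paths ->
labels -> splits.  Long format, one row per image:

    patient_id, label in {pCR, non-pCR}, stage in {pre, post1},
    frame_index (0-based), path, split in {train, test, unassigned}
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio

from .errors import ValidationError, ContractError

MANIFEST_COLUMNS = ["patient_id", "label", "stage", "frame_index", "path", "split"]
LABELS = ("pCR", "non-pCR")
STAGES = ("pre", "post1")
SPLITS = ("train", "test", "unassigned")


def new_manifest_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    validate_manifest(df)
    return df


def validate_manifest(df: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    bad = set(df["label"].dropna().unique()) - set(LABELS)
    if bad:
        raise ValidationError(f"unknown labels {bad}; expected {LABELS}")
    bad = set(df["stage"].unique()) - set(STAGES)
    if bad:
        raise ValidationError(f"unknown stages {bad}; expected {STAGES}")
    bad = set(df["split"].unique()) - set(SPLITS)
    if bad:
        raise ValidationError(f"unknown splits {bad}; expected {SPLITS}")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    validate_manifest(df)
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(df)
    df.to_csv(path, index=False)


def pair_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long manifest into one row per (patient, frame) pair with
    ``path_pre`` / ``path_post`` columns; enforces the equal-N rule."""
    pre = manifest[manifest["stage"] == "pre"]
    post = manifest[manifest["stage"] == "post1"]
    merged = pre.merge(post, on=["patient_id", "frame_index"],
                       suffixes=("_pre", "_post"), how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", "patient_id"].iloc[0]
        raise ContractError(
            f"patient {bad}: unequal frame counts between stages "
            "(the two stages of each patient must have the same N)")
    out = merged.rename(columns={"label_pre": "label", "split_pre": "split"})
    return out[["patient_id", "frame_index", "label", "split",
                "path_pre", "path_post"]].sort_values(
        ["patient_id", "frame_index"]).reset_index(drop=True)


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float in [0, 1]."""
    try:
        arr = iio.imread(path)
    except OSError as e:
        raise ValidationError(f"cannot read image {path}: {e}") from e
    arr = np.asarray(arr)
    if arr.ndim == 3:                       # luminance per ITU-R BT.601
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr / 255.0
    return arr.astype(np.float64)


def load_pairs(manifest: pd.DataFrame, split: str | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Load all image pairs of a split.

    Returns ``(pre, post, y, pairs)`` where ``pre``/``post`` are
    (N, H, W) arrays, ``y`` is an (N, 2) one-hot label matrix in
    (pCR, non-pCR) order, and ``pairs`` is the pair table used.
    """
    df = manifest if split is None else manifest[manifest["split"] == split]
    if len(df) == 0:
        raise ValidationError(f"split {split!r} is empty")
    pairs = pair_table(df)
    pre = np.stack([load_image(p) for p in pairs["path_pre"]])
    post = np.stack([load_image(p) for p in pairs["path_post"]])
    y = np.zeros((len(pairs), 2))
    y[np.arange(len(pairs)), (pairs["label"] != "pCR").astype(int)] = 1.0
    return pre, post, y, pairs
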