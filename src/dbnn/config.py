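"""YAML round-trip for the package's configuration dataclasses.

A config file has up to five sections::

    synthetic:  SyntheticConfig fields
    model:      ModelConfig fields
    augment:    AugmentConfig fields
    train:      Hyperparams fields
    preprocess: frame_interval / kernel / target / roi [r, c, h, w]
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .synthetic import SyntheticConfig
from .model import ModelConfig
from .augmentation import AugmentConfig
from .training import Hyperparams
from .preprocessing import PreprocessParams, ROIBox

_SECTIONS = ("synthetic", "model", "augment", "train", "preprocess")


def _tuples(d: dict, keys) -> dict:
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d


def load_config(path: str | Path) -> dict:
    """Parse a YAML file into a dict of config objects (present sections only)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    if "synthetic" in raw:
        out["synthetic"] = SyntheticConfig(**_tuples(dict(raw["synthetic"]), (
            "frames_per_patient_range", "lesion_radius_range",
            "pcr_shrinkage_range", "nonpcr_shrinkage_range")))
    if "model" in raw:
        out["model"] = ModelConfig.from_dict(raw["model"])
    if "augment" in raw:
        out["augment"] = AugmentConfig(**_tuples(dict(raw["augment"]), ("zoom_range",)))
    if "train" in raw:
        out["train"] = Hyperparams(**raw["train"])
    if "preprocess" in raw:
        p = dict(raw["preprocess"])
        if p.get("roi") is not None:
            p["roi"] = ROIBox(*p["roi"])
        out["preprocess"] = PreprocessParams(**p)
    return out


def save_config(sections: dict, path: str | Path) -> None:
    doc = {}
    for name in _SECTIONS:
        if name not in sections:
            continue
        obj = sections[name]
        if name == "model":
            doc[name] = obj.to_dict()
        else:
            d = asdict(obj)
            if name == "preprocess" and d.get("roi") is not None:
                r = d["roi"]
                d["roi"] = [r["row_start"], r["col_start"], r["height"], r["width"]]
            d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
            doc[name] = d
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
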