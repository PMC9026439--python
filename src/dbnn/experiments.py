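"""Config-driven ablation runner.

Four sweeps mirror the architecture/ablation grids: network depth (plus
the two feature-sharing modes), the fusion-weight grid, the augmentation
strategies, and single- vs dual-timepoint training.  Every results row
records the seed and the resolved model config, so any row can be
regenerated from the table alone.

A scaled-down "desk" profile (32x32 inputs, channels / 8, short epoch
budget) ships as a first-class configuration so the full sweep structure
runs in minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelConfig, SingleBranchCNN, build_model
from .training import Hyperparams, train_arrays
from .augmentation import AugmentConfig
from .evaluation import full_report, delong_test
from .manifest import load_pairs
from .synthetic import SyntheticConfig
from .errors import ValidationError

RESULT_COLUMNS = ["model", "accuracy", "sensitivity", "specificity", "ppv",
                  "npv", "f1", "auc", "auc_lo", "auc_hi", "seed", "status",
                  "config"]


@dataclass
class SweepSpec:
    kind: str                                   # depth|sharing|fusion_weights|augmentation|single_vs_dual
    model: ModelConfig = field(default_factory=ModelConfig)
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    grid: list | None = None
    seeds: list[int] = field(default_factory=lambda: [0])
    out_dir: str | Path | None = None

    def __post_init__(self):
        if self.grid is not None and len(self.grid) == 0:
            raise ValidationError("grid must be nonempty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValidationError("replicate seeds must be distinct")


class Dataset:
    """In-memory train/test pairs, loadable from a manifest."""

    def __init__(self, train, test, train_pairs=None, test_pairs=None):
        self.train = train          # (pre, post, y)
        self.test = test
        self.train_pairs = train_pairs
        self.test_pairs = test_pairs

    @classmethod
    def from_manifest(cls, manifest: pd.DataFrame) -> "Dataset":
        ptr, qtr, ytr, tr_pairs = load_pairs(manifest, "train")
        pte, qte, yte, te_pairs = load_pairs(manifest, "test")
        return cls((ptr, qtr, ytr), (pte, qte, yte), tr_pairs, te_pairs)


def _variant_config(base: ModelConfig, **overrides) -> ModelConfig:
    d = base.to_dict()
    d.update(overrides)
    # depth changes invalidate layer sets derived for another depth
    if "depth" in overrides:
        for k in ("block_layout", "sharing_layers", "pool_layers"):
            d[k] = overrides.get(k)
    return ModelConfig.from_dict(d)


def _train_and_score(model, data: Dataset, hp: Hyperparams,
                     augment: AugmentConfig | None = None) -> np.ndarray:
    train_arrays(model, *data.train, hp, augment=augment)
    pre, post, _ = data.test
    scores = np.concatenate([model.forward(pre[i:i + 64], post[i:i + 64])[:, 0]
                             for i in range(0, len(pre), 64)])
    return scores


def _row(name: str, cfg: ModelConfig, seed: int, scores=None, labels=None,
         error: str | None = None) -> dict:
    row = {c: None for c in RESULT_COLUMNS}
    row.update(model=name, seed=seed, status="ok",
               config=json.dumps(cfg.to_dict()))
    if error is not None:
        row["status"] = f"failed: {error}"
        return row
    rep = full_report(scores, labels)
    row.update(accuracy=rep.accuracy, sensitivity=rep.sensitivity,
               specificity=rep.specificity, ppv=rep.ppv, npv=rep.npv,
               f1=rep.f1, auc=rep.auc, auc_lo=rep.auc_ci[0],
               auc_hi=rep.auc_ci[1])
    return row


def _run_variant(name: str, cfg: ModelConfig | dict, data: Dataset,
                 hp: Hyperparams, seed: int,
                 augment: AugmentConfig | None = None) -> dict:
    """Train/evaluate one grid cell; any failure (including an invalid
    variant config) marks the row and lets the sweep continue."""
    if isinstance(cfg, dict):        # deferred construction: may be invalid
        try:
            cfg = _variant_config(cfg.pop("_base"), **cfg)
        except Exception as e:
            return _row(name, ModelConfig(), seed, error=str(e))
    try:
        hp_seeded = Hyperparams(**{**vars(hp), "seed": seed})
        model = build_model(cfg, seed=seed)
        scores = _train_and_score(model, data, hp_seeded, augment=augment)
        labels = data.test[2][:, 0].astype(int)
        return _row(name, cfg, seed, scores, labels)
    except Exception as e:          # a failed run marks its row, sweep continues
        return _row(name, cfg, seed, error=str(e))


def _finish(rows: list[dict], spec: SweepSpec, fname: str) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / fname, index=False)
    return table


def run_depth_sweep(spec: SweepSpec, data: Dataset) -> pd.DataFrame:
    """Depths 8..12 without sharing (concat head), then the depth-9
    network with sum- and concat-sharing: 7 rows per seed."""
    depths = spec.grid or [8, 9, 10, 11, 12]
    rows = []
    for seed in spec.seeds:
        for d in depths:
            cfg = {"_base": spec.model, "depth": d, "sharing": "none",
                   "fusion": "concat"}
            rows.append(_run_variant(f"CNN-{d}", cfg, data, spec.hyperparams, seed))
        for name, mode in (("CNN-9 FSS", "sum"), ("CNN-9 FSC", "concat")):
            cfg = _variant_config(spec.model, depth=9, sharing=mode,
                                  fusion="concat")
            rows.append(_run_variant(name, cfg, data, spec.hyperparams, seed))
    return _finish(rows, spec, "depth_sweep.csv")


def run_fusion_grid(spec: SweepSpec, data: Dataset) -> pd.DataFrame:
    """On the sum-sharing backbone: concat head, sum head, and the nine
    weighted (alpha, beta) pairs 0.9/0.1 .. 0.1/0.9 — 11 rows per seed;
    the best-accuracy row is flagged."""
    weights = spec.grid or [(round(a, 1), round(1 - a, 1))
                            for a in np.arange(0.9, 0.05, -0.1)]
    rows = []
    for seed in spec.seeds:
        for name, overrides in [("FSS_concat", {"fusion": "concat"}),
                                ("FSS_sum", {"fusion": "sum"})]:
            cfg = _variant_config(spec.model, sharing="sum", **overrides)
            rows.append(_run_variant(name, cfg, data, spec.hyperparams, seed))
        for a, b in weights:
            cfg = _variant_config(spec.model, sharing="sum", fusion="weighted",
                                  alpha=a, beta=b)
            rows.append(_run_variant(f"FSS ({a}, {b})", cfg, data,
                                     spec.hyperparams, seed))
    table = _finish(rows, spec, "fusion_grid.csv")
    ok = table["accuracy"].astype(float)
    table["best"] = ok == ok.max()
    if spec.out_dir is not None:
        table.to_csv(Path(spec.out_dir) / "fusion_grid.csv", index=False)
    return table


def run_augmentation_sweep(spec: SweepSpec, data: Dataset) -> pd.DataFrame:
    """Fixed dual-branch config, one row per augmentation strategy."""
    strategies = spec.grid or ["none", "geometric", "mixup", "upsample_minority"]
    rows = []
    for seed in spec.seeds:
        for strat in strategies:
            aug = AugmentConfig(strategy=strat, seed=seed)
            row = _run_variant(strat, spec.model, data, spec.hyperparams, seed,
                               augment=aug)
            row["config"] = json.dumps({"model": spec.model.to_dict(),
                                        "augment": vars(aug).copy()},
                                       default=str)
            rows.append(row)
    return _finish(rows, spec, "augmentation_sweep.csv")


def run_single_vs_dual(spec: SweepSpec, data: Dataset
                       ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Single-branch models on each timepoint vs the dual network, plus
    pairwise paired DeLong p-values on the shared test pairs."""
    labels = data.test[2][:, 0].astype(int)
    rows, scores = [], {}
    for seed in spec.seeds:
        for name, builder in [
                ("NAC_pre", lambda s: SingleBranchCNN(spec.model, "pre", seed=s)),
                ("NAC_1", lambda s: SingleBranchCNN(spec.model, "post", seed=s)),
                ("NAC_pre+NAC_1", lambda s: build_model(spec.model, seed=s))]:
            try:
                hp = Hyperparams(**{**vars(spec.hyperparams), "seed": seed})
                model = builder(seed)
                sc = _train_and_score(model, data, hp)
                scores[(name, seed)] = sc
                rows.append(_row(name, spec.model, seed, sc, labels))
            except Exception as e:
                rows.append(_row(name, spec.model, seed, error=str(e)))
    table = _finish(rows, spec, "single_vs_dual.csv")
    pvals = {}
    names = ["NAC_pre", "NAC_1", "NAC_pre+NAC_1"]
    seed0 = spec.seeds[0]
    for a, b in [(0, 1), (0, 2), (1, 2)]:
        ka, kb = (names[a], seed0), (names[b], seed0)
        if ka in scores and kb in scores:
            _, p = delong_test(scores[ka], scores[kb], labels)
            pvals[f"{names[a]} vs {names[b]}"] = p
    if spec.out_dir is not None:
        (Path(spec.out_dir) / "single_vs_dual_pvalues.json").write_text(
            json.dumps(pvals, indent=2))
    return table, pvals


def run_desk_study(seeds: list[int]) -> pd.DataFrame:
    """The scaled-down end-to-end study: for each seed, generate a fresh
    desk-profile cohort (patient-level 80/20 split), train the dual
    network and both single-timepoint baselines, and record their test
    AUCs.  Returns one row per seed with columns auc_dual, auc_pre,
    auc_post."""
    import tempfile

    from .synthetic import generate_cohort, generate_paired_dataset, split_patients
    from .evaluation import auc_mann_whitney
    import dataclasses

    syn, mdl, hp = desk_profile()
    rows = []
    for seed in seeds:
        cohort = generate_cohort(dataclasses.replace(syn, seed=seed))
        with tempfile.TemporaryDirectory() as td:
            manifest = split_patients(generate_paired_dataset(cohort, td),
                                      0.8, seed=seed)
            data = Dataset.from_manifest(manifest)
        labels = data.test[2][:, 0].astype(int)
        hp_s = Hyperparams(**{**vars(hp), "seed": seed})
        row = {"seed": seed}
        for key, model in (("auc_dual", build_model(mdl, seed=seed)),
                           ("auc_pre", SingleBranchCNN(mdl, "pre", seed=seed)),
                           ("auc_post", SingleBranchCNN(mdl, "post", seed=seed))):
            scores = _train_and_score(model, data, hp_s)
            row[key] = auc_mann_whitney(scores, labels)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- profiles

def desk_profile() -> tuple[SyntheticConfig, ModelConfig, Hyperparams]:
    """Scaled-down study profile for CPU runs: 32x32 inputs rendered
    directly at network size, channels divided by 8 (fc width likewise),
    float32 arithmetic, 100 patients with 4-6 frame pairs each, 30
    epochs.  The architecture (depth 9, sharing {2,4,6,9}, pooling
    {2,4,7,9}, weighted 0.2/0.8 fusion) is unchanged.

    The phantom cohort uses a wide lesion-size prior and a moderate
    responder shrinkage so that stage-2 ABSOLUTE size carries partial
    class information (a small post-treatment lesion is suggestive but
    not conclusive) while the stage-1 -> stage-2 relative change remains
    the dominant signal — mirroring the clinical situation where a
    single-timepoint model is mid-range and the paired model is clearly
    better, with the pre-treatment image alone near chance.
    """
    syn = SyntheticConfig(n_patients=100, frames_per_patient_range=(4, 6),
                          image_size=32,
                          lesion_radius_range=(0.06 * 32, 0.30 * 32),
                          pcr_shrinkage_range=(0.35, 0.65))
    mdl = ModelConfig(channels_per_block=[8, 16, 32, 64], fc_width=128,
                      image_size=32, dtype="float32")
    hp = Hyperparams(epochs=30)
    return syn, mdl, hp
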