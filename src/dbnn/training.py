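"""Mini-batch training with the reference recipe: cross-entropy loss,
Adam (lr 0.001), batch size 8, a fixed epoch budget, dropout 0.5.

``train`` consumes a manifest (loading pairs from disk) while
``train_arrays`` works on in-memory arrays; both drive the same loop.
All randomness — shuffling, dropout masks, augmentation draws — derives
from ``Hyperparams.seed``, so a (model, data, seed) triple reproduces
the trained parameters bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import Adam
from .nn import autograd as ag
from .errors import ValidationError, NumericError
from .manifest import load_pairs
from .augmentation import (AugmentConfig, geometric_augment, mixup,
                           draw_mixup_lambda)
from .preprocessing import PairedSample


@dataclass
class Hyperparams:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 8
    epochs: int = 500
    loss: str = "cross_entropy"
    seed: int = 0
    val_fraction: float = 0.0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValidationError(f"unsupported loss {self.loss!r}")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValidationError("val_fraction must be in [0, 1)")


@dataclass
class LossCurve:
    train: list[float] = field(default_factory=list)
    val: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = {"epoch": np.arange(len(self.train)), "train_loss": self.train}
        if self.val:
            d["val_loss"] = self.val
        return pd.DataFrame(d)


def _augment_batch(pre, post, y, augment: AugmentConfig | None,
                   rng: np.random.Generator):
    if augment is None or augment.strategy in ("none", "upsample_minority"):
        return pre, post, y
    n = pre.shape[0]
    if augment.strategy == "geometric":
        out_pre = np.empty_like(pre)
        out_post = np.empty_like(post)
        for i in range(n):
            s = geometric_augment(
                PairedSample(pre[i], post[i], "pCR", "", 0), augment, rng)
            out_pre[i], out_post[i] = s.pre, s.post
        return out_pre, out_post, y
    # mixup: blend each item with a random partner, one lambda per item
    perm = rng.integers(0, n, size=n)
    lam = np.array([draw_mixup_lambda(augment, rng) for _ in range(n)])
    li = lam[:, None, None]
    return (lam_mix(pre, pre[perm], li), lam_mix(post, post[perm], li),
            lam[:, None] * y + (1 - lam[:, None]) * y[perm])


def lam_mix(a, b, lam):
    return lam * a + (1.0 - lam) * b


def _balance_minority(pre, post, y, augment: AugmentConfig,
                      rng: np.random.Generator):
    """In-memory minority upsampling: duplicate minority pairs with fresh
    geometric transforms until the class counts match."""
    cls = y.argmax(axis=1)
    counts = np.bincount(cls, minlength=2)
    if counts.min() == 0:
        raise ValidationError("both classes must be present to balance")
    minority = int(counts.argmin())
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return pre, post, y
    pool = np.flatnonzero(cls == minority)
    picks = pool[rng.integers(0, len(pool), size=deficit)]
    add_pre, add_post = [], []
    for i in picks:
        s = geometric_augment(PairedSample(pre[i], post[i], "pCR", "", 0),
                              augment, rng)
        add_pre.append(s.pre)
        add_post.append(s.post)
    return (np.concatenate([pre, np.stack(add_pre)]),
            np.concatenate([post, np.stack(add_post)]),
            np.concatenate([y, y[picks]]))


def train_arrays(model, pre, post, y, hp: Hyperparams,
                 augment: AugmentConfig | None = None,
                 val: tuple | None = None) -> LossCurve:
    """Train in place on (N, H, W) stacks and (N, 2) label vectors."""
    rng = np.random.default_rng(hp.seed)
    if augment is not None and augment.strategy == "upsample_minority":
        pre, post, y = _balance_minority(pre, post, y, augment, rng)
    n = pre.shape[0]
    if n == 0:
        raise ValidationError("no training samples")
    opt = Adam(model.parameters(), lr=hp.learning_rate)
    curve = LossCurve()
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            bp, bq, by = _augment_batch(pre[idx], post[idx], y[idx], augment, rng)
            opt.zero_grad()
            logits = model.logits(bp, bq, train=True, rng=rng)
            try:
                loss = ag.softmax_cross_entropy(logits, by)
            except NumericError as e:
                raise NumericError(f"diverged at epoch {epoch}: {e}") from e
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        curve.train.append(float(np.mean(losses)))
        if val is not None:
            curve.val.append(evaluate_loss_arrays(model, *val))
    return curve


def train(model, manifest: pd.DataFrame, hp: Hyperparams,
          augment: AugmentConfig | None = None) -> tuple[object, LossCurve]:
    """Train on the manifest's train split; returns (model, loss curve).

    With ``val_fraction > 0`` a patient-level slice of the training
    patients is held out purely to monitor validation loss.
    """
    df = manifest[manifest["split"] == "train"]
    if len(df) == 0:
        raise ValidationError("manifest has an empty train split")
    val = None
    if hp.val_fraction > 0:
        rng = np.random.default_rng(hp.seed)
        patients = np.sort(df["patient_id"].unique())
        n_val = max(1, int(round(len(patients) * hp.val_fraction)))
        val_ids = set(patients[rng.permutation(len(patients))[:n_val]])
        val_df = df[df["patient_id"].isin(val_ids)]
        df = df[~df["patient_id"].isin(val_ids)]
        vp, vq, vy, _ = load_pairs(val_df)
        val = (vp, vq, vy)
    pre, post, y, _ = load_pairs(df)
    curve = train_arrays(model, pre, post, y, hp, augment=augment, val=val)
    return model, curve


def evaluate_loss_arrays(model, pre, post, y, batch_size: int = 64) -> float:
    if pre.shape[0] == 0:
        raise ValidationError("empty sample set")
    total, n = 0.0, pre.shape[0]
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        logits = model.logits(pre[sl], post[sl], train=False)
        z = logits.data - logits.data.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        total += float(-(y[sl] * logp).sum())
    return total / n


def evaluate_loss(model, samples: list[PairedSample]) -> float:
    """Mean cross-entropy of eval-mode predictions over paired samples."""
    if len(samples) == 0:
        raise ValidationError("empty sample set")
    pre = np.stack([s.pre for s in samples])
    post = np.stack([s.post for s in samples])
    y = np.stack([s.label_vector for s in samples])
    return evaluate_loss_arrays(model, pre, post, y)
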