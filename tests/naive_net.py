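"""Brute-force reference forward pass, independent of the package's
im2col/GEMM engine: explicit nested loops over output positions.

Used to pin the dual-branch forward computation (convolution, batch
norm, ReLU, feature sharing, pooling, fc, fusion, softmax) against a
direct transcription of its definition.
"""

import numpy as np


def conv_naive(x, w, b):
    """x (C,H,W), w (O,C,k,k), b (O,) -> (O,H,W); zero padding k//2."""
    c, h, wd = x.shape
    o, _, k, _ = w.shape
    pad = k // 2
    xp = np.zeros((c, h + 2 * pad, wd + 2 * pad))
    xp[:, pad:pad + h, pad:pad + wd] = x
    out = np.zeros((o, h, wd))
    for oc in range(o):
        for r in range(h):
            for cc in range(wd):
                acc = 0.0
                for ic in range(c):
                    for i in range(k):
                        for j in range(k):
                            acc += w[oc, ic, i, j] * xp[ic, r + i, cc + j]
                out[oc, r, cc] = acc + b[oc]
    return out


def bn_eval_naive(x, gamma, beta, mean, var, eps=1e-5):
    out = np.empty_like(x)
    for ch in range(x.shape[0]):
        out[ch] = gamma[ch] * (x[ch] - mean[ch]) / np.sqrt(var[ch] + eps) + beta[ch]
    return out


def pool_naive(x):
    c, h, w = x.shape
    out = np.zeros((c, h // 2, w // 2))
    for ch in range(c):
        for r in range(h // 2):
            for cc in range(w // 2):
                out[ch, r, cc] = x[ch, 2 * r:2 * r + 2, 2 * cc:2 * cc + 2].max()
    return out


def _branch_params(branch, i):
    conv = getattr(branch, f"conv{i}")
    bn = getattr(branch, f"bn{i}")
    return (conv.weight.data, conv.bias.data, bn.gamma.data, bn.beta.data,
            bn.running_mean, bn.running_var)


def naive_forward(model, pre, post):
    """Eval-mode forward of a DBNNModel for a single (pre, post) image
    pair given as (H, W) arrays; returns the two class probabilities."""
    cfg = model.config
    a = pre[None, :, :].astype(float)
    b = post[None, :, :].astype(float)
    for i in range(1, cfg.depth + 1):
        if cfg.sharing == "sum" and i in cfg.sharing_layers:
            ia, ib = a + b, b + a
        elif cfg.sharing == "concat" and i in cfg.sharing_layers:
            ia = np.concatenate([a, b], axis=0)
            ib = np.concatenate([b, a], axis=0)
        else:
            ia, ib = a, b
        wa, ba, ga, bea, ma, va = _branch_params(model.branch_pre, i)
        wb, bb, gb, beb, mb, vb = _branch_params(model.branch_post, i)
        a = np.maximum(bn_eval_naive(conv_naive(ia, wa, ba), ga, bea, ma, va), 0.0)
        b = np.maximum(bn_eval_naive(conv_naive(ib, wb, bb), gb, beb, mb, vb), 0.0)
        if i in cfg.pool_layers:
            a, b = pool_naive(a), pool_naive(b)
    fa = model.fc_pre.weight.data.T @ a.ravel() + model.fc_pre.bias.data
    fb = model.fc_post.weight.data.T @ b.ravel() + model.fc_post.bias.data
    if cfg.fusion == "concat":
        z = np.concatenate([fa, fb])
    elif cfg.fusion == "sum":
        z = fa + fb
    else:
        z = cfg.alpha * fa + cfg.beta * fb
    logits = model.classifier.weight.data.T @ z + model.classifier.bias.data
    e = np.exp(logits - logits.max())
    return e / e.sum()
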