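"""Losses: softmax cross-entropy (classifier) and probability-space BCE
with an optional feature-matching term (GAN)."""

from __future__ import annotations

import numpy as np

from .functional import softmax

_EPS = 1e-7


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy.  Returns (loss, grad wrt logits)."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    loss = -np.log(np.clip(p[np.arange(n), labels], _EPS, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


def bce(prob: np.ndarray, target: float):
    """Mean binary cross-entropy of probabilities against a constant target.

    Returns (loss, grad wrt prob).  Probabilities are clipped away from
    {0, 1} for numerical safety.
    """
    p = np.clip(prob, _EPS, 1.0 - _EPS)
    loss = -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean()
    grad = ((p - target) / (p * (1.0 - p))) / p.size
    return float(loss), grad.astype(prob.dtype)


def feature_matching(real_feats: np.ndarray, fake_feats: np.ndarray):
    """Squared L2 distance between batch-mean discriminator features.

    Returns (loss, grad wrt fake_feats); real features are treated as
    constants (no gradient flows into the discriminator here).
    """
    mr = real_feats.reshape(real_feats.shape[0], -1).mean(axis=0)
    mf = fake_feats.reshape(fake_feats.shape[0], -1).mean(axis=0)
    diff = mf - mr
    loss = float(diff @ diff)
    grad = (2.0 * diff / fake_feats.shape[0]).astype(fake_feats.dtype)
    grad = np.broadcast_to(grad, (fake_feats.shape[0], diff.size))
    return loss, grad.reshape(fake_feats.shape)


def gan_loss(real_scores, fake_scores, real_feats=None, fake_feats=None,
             fm_weight: float = 1.0):
    """Discriminator and generator objectives.

    loss_D = BCE(real -> 1) + BCE(fake -> 0)
    loss_G = BCE(fake -> 1) + fm_weight * ||mean(real_feats) - mean(fake_feats)||^2

    Returns (loss_d, loss_g); gradient plumbing lives in the training loop,
    which re-evaluates the same closed forms piecewise.
    """
    if np.size(real_scores) == 0 or np.size(fake_scores) == 0:
        raise ValueError("empty score batch")
    ld_real, _ = bce(np.asarray(real_scores), 1.0)
    ld_fake, _ = bce(np.asarray(fake_scores), 0.0)
    lg, _ = bce(np.asarray(fake_scores), 1.0)
    if fm_weight and real_feats is not None and fake_feats is not None:
        fm, _ = feature_matching(np.asarray(real_feats), np.asarray(fake_feats))
        lg += fm_weight * fm
    return ld_real + ld_fake, lg
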