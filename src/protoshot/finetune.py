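"""Naive per-episode fine-tuning baseline.

For every episode, a fresh linear softmax head is trained on that
episode's support set alone (the embedding backbone stays frozen by
default) and evaluated on the episode's queries. This is the standard
comparator that episodic prototypical training is expected to beat:
with K*N support images there is simply too little data for per-episode
supervised training to generalize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from protoshot.episodes import Episode
from protoshot.nn import Adam, Param
from protoshot.protonet import embed


class FinetuneDiverged(RuntimeError):
    """Raised when the per-episode loss becomes non-finite; the caller
    records the episode as failed."""


@dataclass(frozen=True)
class FinetuneConfig:
    epochs: int = 50
    learning_rate: float = 0.1
    head_only: bool = True
    backbone_lr: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _train_head(
    zs: np.ndarray, ys: np.ndarray, n_way: int, cfg: FinetuneConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Full-batch Adam on multinomial logistic regression; returns (W, b)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 41]))
    d = zs.shape[1]
    W = Param(0.01 * rng.standard_normal((n_way, d)))
    b = Param(np.zeros(n_way))
    opt = Adam([W, b], lr=cfg.learning_rate)
    onehot = np.eye(n_way)[ys]
    for _ in range(cfg.epochs):
        logits = zs @ W.value.T + b.value
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        loss = -np.log(np.clip(p[np.arange(len(ys)), ys], 1e-12, None)).mean()
        if not np.isfinite(loss):
            raise FinetuneDiverged("non-finite loss while fitting episode head")
        g = (p - onehot) / len(ys)
        W.grad[...] = g.T @ zs
        b.grad[...] = g.sum(axis=0)
        opt.step()
    return W.value, b.value


def finetune_episode(
    backbone,
    pool_images: np.ndarray,
    episode: Episode,
    cfg: FinetuneConfig,
    n_way: int = 4,
    pool_embeddings: np.ndarray | None = None,
) -> dict:
    """Train on the episode's support only; predict its queries.

    ``pool_embeddings`` (precomputed frozen-backbone embeddings of the
    whole pool) can be passed to skip redundant forward passes when many
    episodes share a pool; it is only valid with ``head_only``.

    Returns dict with ``pred``, ``probs``, ``support_accuracy``.
    """
    if not cfg.head_only:
        return _full_finetune_episode(backbone, pool_images, episode, cfg, n_way)
    if pool_embeddings is not None:
        zs = pool_embeddings[episode.support_indices]
        zq = pool_embeddings[episode.query_indices]
    else:
        zs = embed(backbone, pool_images[episode.support_indices])
        zq = embed(backbone, pool_images[episode.query_indices])
    zs = np.asarray(zs, dtype=np.float64)
    zq = np.asarray(zq, dtype=np.float64)
    # standardize features on the support set (conditioning of the logistic
    # fit); the same transform is applied to queries, so no query leakage
    mu, sd = zs.mean(axis=0), zs.std(axis=0)
    sd[sd == 0] = 1.0
    zs = (zs - mu) / sd
    zq = (zq - mu) / sd
    ys = episode.support_labels
    W, b = _train_head(zs, ys, n_way, cfg)
    logits_s = zs @ W.T + b
    support_acc = float((logits_s.argmax(axis=1) == ys).mean())
    logits_q = zq @ W.T + b
    logits_q = logits_q - logits_q.max(axis=1, keepdims=True)
    e = np.exp(logits_q)
    probs = e / e.sum(axis=1, keepdims=True)
    return {
        "pred": logits_q.argmax(axis=1),
        "probs": probs,
        "support_accuracy": support_acc,
        "true": episode.query_labels,
    }


def _full_finetune_episode(
    backbone, pool_images: np.ndarray, episode: Episode, cfg: FinetuneConfig,
    n_way: int,
) -> dict:
    """Joint backbone + head training on the support set (flagged path).

    The backbone is re-initialized from the same seed-derived state for
    every episode so episodes are exchangeable; the incoming backbone only
    supplies the architecture.
    """
    from protoshot.protonet import BackboneConfig, build_backbone

    cfg_bb = BackboneConfig(
        n_blocks=len(backbone.blocks),
        channels=tuple(b[0].cout for b in backbone.blocks),
        embed_dim=backbone.embed_dim,
        image_size=backbone.image_size,
    )
    model = build_backbone(cfg_bb, seed=cfg.seed)
    xs = pool_images[episode.support_indices]
    ys = episode.support_labels
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 43]))
    W = Param(0.01 * rng.standard_normal((n_way, model.embed_dim)))
    b = Param(np.zeros(n_way))
    opt = Adam(model.params() + [W, b], lr=cfg.backbone_lr)
    onehot = np.eye(n_way)[ys]
    for _ in range(cfg.epochs):
        z = model.forward(xs, train=True)
        logits = z @ W.value.T + b.value
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        loss = -np.log(np.clip(p[np.arange(len(ys)), ys], 1e-12, None)).mean()
        if not np.isfinite(loss):
            raise FinetuneDiverged("non-finite loss during full fine-tuning")
        g = (p - onehot) / len(ys)
        model.zero_grad()
        W.grad[...] = g.T @ z
        b.grad[...] = g.sum(axis=0)
        model.backward(g @ W.value)
        opt.step()
    z = model.forward(xs, train=False)
    support_acc = float(((z @ W.value.T + b.value).argmax(axis=1) == ys).mean())
    zq = model.forward(pool_images[episode.query_indices], train=False)
    logits_q = zq @ W.value.T + b.value
    logits_q = logits_q - logits_q.max(axis=1, keepdims=True)
    e = np.exp(logits_q)
    return {
        "pred": logits_q.argmax(axis=1),
        "probs": e / e.sum(axis=1, keepdims=True),
        "support_accuracy": support_acc,
        "true": episode.query_labels,
    }
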