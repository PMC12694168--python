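"""Prototypical-network classification and episodic training.

A prototypical network classifies a query embedding by Euclidean distance
to class prototypes, each prototype being the arithmetic mean of that
class's support embeddings:

    p_c = (1/|S_c|) sum_{x in S_c} f_theta(x)
    P(y=c | x) = exp(-d(f_theta(x), p_c)) / sum_c' exp(-d(f_theta(x), p_c'))

Training minimizes the negative log-likelihood of query labels over
randomly sampled N-way K-shot episodes; gradients flow through both the
query embeddings and the prototypes (hence the support embeddings).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from protoshot.episodes import Episode, EpisodeSpec, sample_episode
from protoshot.nn import Adam, SimpleCNNEmbed
from protoshot.splits import augment

log = logging.getLogger(__name__)

_EPS_PROB = 1e-12
_EPS_DIST = 1e-12


class TrainingDiverged(RuntimeError):
    """Raised when the episodic loss becomes non-finite."""


@dataclass(frozen=True)
class BackboneConfig:
    """Embedding-network configuration.

    ``simple_cnn`` is the fully implemented backbone: ``n_blocks`` blocks of
    [3x3 conv, batch norm, ReLU, 2x2 max-pool], global average pooling, and
    a linear projection to ``embed_dim``. Other kinds (``resnet18``,
    ``vit_small``) are plug-in hooks: register a factory with
    :func:`register_backbone` that returns an object with the same
    ``forward/backward/params`` surface.
    """

    kind: str = "simple_cnn"
    n_blocks: int = 3
    channels: tuple[int, ...] = (16, 32, 64)
    embed_dim: int = 64
    image_size: int = 96
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Adam episodic training schedule.

    ``episode_batch`` episodes are accumulated (gradient averaged) per
    optimizer step; ``episodes_per_epoch`` episodes are consumed per epoch.
    """

    learning_rate: float = 1e-4
    epochs: int = 50
    episodes_per_epoch: int = 16
    episode_batch: int = 16
    seed: int = 42

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


_BACKBONE_REGISTRY: dict[str, Callable] = {}


def register_backbone(kind: str, factory: Callable) -> None:
    """Register a plug-in backbone factory: factory(cfg, seed) -> model."""
    _BACKBONE_REGISTRY[kind] = factory


def build_backbone(cfg: BackboneConfig, seed: int = 0):
    if cfg.kind == "simple_cnn":
        return SimpleCNNEmbed(
            image_size=cfg.image_size,
            n_blocks=cfg.n_blocks,
            channels=cfg.channels,
            embed_dim=cfg.embed_dim,
            seed=seed,
        )
    if cfg.kind in _BACKBONE_REGISTRY:
        return _BACKBONE_REGISTRY[cfg.kind](cfg, seed)
    raise ValueError(
        f"backbone kind {cfg.kind!r} is not built in; register a plug-in "
        "factory with register_backbone()"
    )


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def embed(backbone, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Embed images (N, H, W) -> (N, embed_dim), eval mode, batched."""
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    out = [
        backbone.forward(images[i:i + batch_size], train=False)
        for i in range(0, len(images), batch_size)
    ]
    return np.concatenate(out, axis=0)


def compute_prototypes(
    embeddings: np.ndarray, labels: Sequence[int], n_way: int
) -> np.ndarray:
    """Per-class mean of support embeddings -> (n_way, embed_dim)."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    protos = np.empty((n_way, embeddings.shape[1]))
    for c in range(n_way):
        sel = labels == c
        if not sel.any():
            raise ValueError(f"class {c} has no support embeddings")
        protos[c] = embeddings[sel].mean(axis=0)
    return protos


def euclidean_distance(z: np.ndarray, p: np.ndarray) -> float:
    """L2 norm of (z - p)."""
    z, p = np.asarray(z, dtype=np.float64), np.asarray(p, dtype=np.float64)
    if z.shape != p.shape:
        raise ValueError(f"length mismatch: {z.shape} vs {p.shape}")
    return float(np.linalg.norm(z - p))


def pairwise_distances(queries: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """(Q, D) x (C, D) -> (Q, C) Euclidean distance matrix."""
    q = np.asarray(queries, dtype=np.float64)
    p = np.asarray(prototypes, dtype=np.float64)
    if q.shape[1] != p.shape[1]:
        raise ValueError(f"dim mismatch: {q.shape[1]} vs {p.shape[1]}")
    diff = q[:, None, :] - p[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def posterior_from_distances(d: np.ndarray) -> np.ndarray:
    """Softmax over negated distances, row-wise, max-shift stabilized."""
    d = np.asarray(d, dtype=np.float64)
    s = -d
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def nll_loss(
    probabilities: np.ndarray, labels: Sequence[int], reduction: str = "mean"
) -> float:
    """Negative log-likelihood of the true labels.

    ``reduction='mean'`` (default) averages over queries so the loss scale
    is independent of episode size; ``'sum'`` matches the literal
    accumulated form. Zero probabilities are clamped at 1e-12 with a
    warning.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    p_true = probabilities[np.arange(len(labels)), labels]
    if (p_true <= 0).any():
        warnings.warn("zero probability at true label; clamping at 1e-12")
        p_true = np.clip(p_true, _EPS_PROB, None)
    total = float(-np.log(p_true).sum())
    if reduction == "mean":
        return total / len(labels)
    if reduction == "sum":
        return total
    raise ValueError(f"unknown reduction {reduction!r}")


def classify_queries(
    prototypes: np.ndarray, query_embeddings: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-prototype labels (ties -> lowest local label) + posteriors."""
    d = pairwise_distances(query_embeddings, prototypes)
    return d.argmin(axis=1), posterior_from_distances(d)


# ---------------------------------------------------------------------------
# episodic training
# ---------------------------------------------------------------------------

def _episode_loss_and_grad(
    z: np.ndarray,
    support_labels: np.ndarray,
    query_labels: np.ndarray,
    n_way: int,
    k_shot: int,
) -> tuple[float, float, np.ndarray]:
    """Loss, query accuracy and dL/dz for one episode.

    ``z`` stacks support embeddings first, then queries. Mean reduction
    over queries.
    """
    n_support = len(support_labels)
    zs, zq = z[:n_support], z[n_support:]
    protos = compute_prototypes(zs, support_labels, n_way)
    diff = zq[:, None, :] - protos[None, :, :]          # (Q, C, D)
    d = np.sqrt((diff ** 2).sum(axis=2))
    probs = posterior_from_distances(d)
    loss = nll_loss(probs, query_labels)
    acc = float((d.argmin(axis=1) == query_labels).mean())

    nq = len(query_labels)
    dd = -probs                                        # logits are -d
    dd[np.arange(nq), query_labels] += 1.0
    dd /= nq                                            # dL/dd (Q, C)
    unit = diff / (d[:, :, None] + _EPS_DIST)
    dzq = (dd[:, :, None] * unit).sum(axis=1)
    dproto = -(dd[:, :, None] * unit).sum(axis=0)       # (C, D)
    dzs = dproto[support_labels] / k_shot
    return loss, acc, np.concatenate([dzs, dzq], axis=0)


def train_protonet(
    pool_images: np.ndarray,
    pool_labels: Sequence[int],
    episode_spec: EpisodeSpec,
    backbone_cfg: BackboneConfig,
    train_cfg: TrainConfig,
    brightness: float = 0.1,
) -> tuple[object, pd.DataFrame]:
    """Episodic training (Adam); returns (backbone, training curve).

    The curve has one row per epoch: ``epoch, mean_loss,
    mean_episode_accuracy``. Three seeded RNG streams are derived from
    ``train_cfg.seed``: weight init, episode sampling, and augmentation.
    Support-set flip/brightness augmentation is applied only when
    ``episode_spec.augment_support`` is true.
    """
    pool_images = np.asarray(pool_images)
    pool_labels = np.asarray(pool_labels, dtype=int)
    model = build_backbone(backbone_cfg, seed=train_cfg.seed)
    opt = Adam(model.params(), lr=train_cfg.learning_rate)
    sample_spec = EpisodeSpec(
        n_way=episode_spec.n_way,
        k_shot=episode_spec.k_shot,
        q_query=episode_spec.q_query,
        n_episodes=train_cfg.epochs * train_cfg.episodes_per_epoch,
        seed=train_cfg.seed,
        augment_support=episode_spec.augment_support,
    )
    history = []
    counter = 0
    for epoch in range(train_cfg.epochs):
        losses, accs = [], []
        done = 0
        while done < train_cfg.episodes_per_epoch:
            batch = min(train_cfg.episode_batch, train_cfg.episodes_per_epoch - done)
            model.zero_grad()
            for _ in range(batch):
                ep = sample_episode(pool_labels, sample_spec, counter)
                idx = np.concatenate([ep.support_indices, ep.query_indices])
                imgs = pool_images[idx]
                if episode_spec.augment_support:
                    arng = np.random.default_rng(
                        np.random.SeedSequence([train_cfg.seed, 37, counter])
                    )
                    imgs = imgs.copy()
                    for i in range(len(ep.support)):
                        imgs[i] = augment(imgs[i], arng, brightness=brightness)
                z = model.forward(imgs, train=True)
                loss, acc, dz = _episode_loss_and_grad(
                    z, ep.support_labels, ep.query_labels,
                    episode_spec.n_way, episode_spec.k_shot,
                )
                if not np.isfinite(loss):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch}, episode {counter}"
                    )
                model.backward(dz / batch)
                losses.append(loss)
                accs.append(acc)
                counter += 1
            opt.step()
            done += batch
        history.append((epoch, float(np.mean(losses)), float(np.mean(accs))))
        log.info("epoch %d: loss %.4f acc %.3f", *history[-1])
    curve = pd.DataFrame(history, columns=["epoch", "mean_loss", "mean_episode_accuracy"])
    return model, curve


def evaluate_protonet(
    model,
    pool_images: np.ndarray,
    pool_labels: Sequence[int],
    episode_spec: EpisodeSpec,
) -> list[dict]:
    """Evaluate over ``episode_spec.n_episodes`` episodes.

    The pool is embedded once (evaluation embeddings are augmentation-free
    and the backbone is frozen), then each episode is pure index math.
    Returns per-episode dicts: accuracy, true/predicted labels, posterior
    rows, and the episode's global class ids.
    """
    pool_labels = np.asarray(pool_labels, dtype=int)
    z_pool = embed(model, np.asarray(pool_images))
    results = []
    for i in range(episode_spec.n_episodes):
        ep = sample_episode(pool_labels, episode_spec, i)
        protos = compute_prototypes(
            z_pool[ep.support_indices], ep.support_labels, episode_spec.n_way
        )
        pred, probs = classify_queries(protos, z_pool[ep.query_indices])
        true = ep.query_labels
        results.append(
            {
                "accuracy": float((pred == true).mean()),
                "true": true,
                "pred": pred,
                "probs": probs,
                "class_ids": ep.class_ids,
            }
        )
    return results


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, cfg: BackboneConfig, seed: int, path: str | Path) -> None:
    """Weights + config + seed provenance in one .npz."""
    meta = json.dumps({"config": cfg.__dict__ | {"channels": list(cfg.channels)},
                       "seed": seed})
    np.savez(path, __meta__=np.array(meta), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[object, BackboneConfig, int]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg_d = meta["config"]
    cfg_d["channels"] = tuple(cfg_d["channels"])
    cfg = BackboneConfig(**cfg_d)
    model = build_backbone(cfg, seed=meta["seed"])
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model, cfg, meta["seed"]
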