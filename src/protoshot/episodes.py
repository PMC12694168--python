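"""N-way K-shot episode sampling.

An episode is a self-contained classification task: ``n_way`` classes
drawn from the pool, ``k_shot`` labeled support items and ``q_query``
held-out query items per class, sampled without replacement so support
and query never share an item. Episode ``i`` is a pure function of
``(spec.seed, i)`` via counter-based substreams, so streams can be
consumed out of order or in parallel without changing any episode.

Episode-local labels are ``0..n_way-1`` in the order classes were drawn;
``class_ids`` maps them back to global class indices for confusion
matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np


@dataclass(frozen=True)
class EpisodeSpec:
    n_way: int = 4
    k_shot: int = 5
    q_query: int = 5
    n_episodes: int = 1000
    seed: int = 0
    augment_support: bool = False

    def __post_init__(self) -> None:
        if self.k_shot < 1 or self.q_query < 1 or self.n_way < 2:
            raise ValueError("need n_way >= 2, k_shot >= 1, q_query >= 1")
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")


@dataclass
class Episode:
    """One sampled task; items are integer indices into the pool."""

    class_ids: list[int]                 # global class per local label
    support: list[tuple[int, int]]       # (pool index, local label)
    query: list[tuple[int, int]]

    @property
    def support_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.support], dtype=int)

    @property
    def query_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.query], dtype=int)

    @property
    def support_labels(self) -> np.ndarray:
        return np.array([l for _, l in self.support], dtype=int)

    @property
    def query_labels(self) -> np.ndarray:
        return np.array([l for _, l in self.query], dtype=int)


def sample_episode(
    pool_labels: Sequence[int] | np.ndarray,
    spec: EpisodeSpec,
    episode_index: int,
) -> Episode:
    """Sample episode ``episode_index`` from items labeled ``pool_labels``.

    Fully determined by ``(spec.seed, episode_index)``.
    """
    labels = np.asarray(pool_labels, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23, episode_index]))
    available = np.unique(labels)
    if spec.n_way > len(available):
        raise ValueError(
            f"n_way={spec.n_way} but only {len(available)} classes in pool"
        )
    chosen = rng.choice(available, size=spec.n_way, replace=False)
    need = spec.k_shot + spec.q_query
    support, query = [], []
    for local, cls in enumerate(chosen):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < need:
            raise ValueError(
                f"class {int(cls)} has {len(idx)} items, episode needs "
                f"{need} (k_shot={spec.k_shot} + q_query={spec.q_query})"
            )
        picked = rng.choice(idx, size=need, replace=False)
        support.extend((int(i), local) for i in picked[: spec.k_shot])
        query.extend((int(i), local) for i in picked[spec.k_shot:])
    return Episode(class_ids=[int(c) for c in chosen], support=support, query=query)


def episode_stream(
    pool_labels: Sequence[int] | np.ndarray, spec: EpisodeSpec
) -> Iterator[Episode]:
    """Yield exactly ``spec.n_episodes`` episodes (counter-based, so episode
    i never depends on whether earlier episodes were consumed)."""
    for i in range(spec.n_episodes):
        yield sample_episode(pool_labels, spec, i)


def episode_to_json(episode: Episode, paths: Sequence[str] | None = None) -> str:
    """Serialize for audit/replay; with ``paths`` the item refs are stored
    as paths instead of bare pool indices."""
    ref = (lambda i: paths[i]) if paths is not None else (lambda i: i)
    return json.dumps(
        {
            "class_ids": episode.class_ids,
            "support": [[ref(i), l] for i, l in episode.support],
            "query": [[ref(i), l] for i, l in episode.query],
        }
    )


def episode_from_json(s: str, paths: Sequence[str] | None = None) -> Episode:
    d = json.loads(s)
    if paths is not None:
        lookup = {p: i for i, p in enumerate(paths)}
        conv = lambda r: lookup[r]
    else:
        conv = int
    return Episode(
        class_ids=[int(c) for c in d["class_ids"]],
        support=[(conv(r), int(l)) for r, l in d["support"]],
        query=[(conv(r), int(l)) for r, l in d["query"]],
    )
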