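"""Prompt-ensemble zero-shot classification over an embedding provider.

A provider pairs an image encoder and a text encoder that map into one
shared embedding space. Each class is represented by the L2-normalized
mean of its selected prompt embeddings; an image is assigned to the class
whose text embedding has the highest cosine similarity with the image
embedding. No parameters are ever updated (true zero-shot).

Prompt selection follows a cosine-margin protocol: from a pool of
candidate prompts per class, each candidate is scored by the mean margin
sim(image, prompt) - max over competing classes of sim(image, t[c']) on
validation images of its class, and the top five candidates are averaged
into the final class embedding.

The bundled :class:`SyntheticProvider` emulates a perfectly pre-trained
encoder pair on phantom data: images embed near their class anchor with
configurable dispersion, and a prompt embeds at an angle from its class
anchor controlled by a quality in [0, 1] (1 = exactly the anchor,
0 = orthogonal). It exists so the zero-shot computation -- which is
provider-agnostic -- can be exercised and tested without any pre-trained
weights; a real vision-language checkpoint can be dropped in behind the
same two-method surface.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from protoshot.phantoms import (
    CLASS_NAMES,
    EmbeddingSimSpec,
    Phantom,
    class_anchors,
)

# Handcrafted default prompt bank (radiology-flavoured phrasings).
DEFAULT_PROMPTS: dict[str, list[str]] = {
    "normal": [
        "An MRI of a healthy brain.",
        "No visible tumours in this scan.",
        "Axial T1-weighted MRI slice with intact bilateral hemispheric symmetry.",
        "A normal brain MRI without focal lesions.",
        "Healthy brain parenchyma on MRI.",
    ],
    "glioma": [
        "An MRI showing a glioma tumour.",
        "Malignant glioma present.",
        "Intra-parenchymal mass with infiltrative margins on axial MRI.",
        "A brain MRI with a glioma exhibiting mass effect.",
        "T1-weighted MRI of a malignant glioma.",
    ],
    "meningioma": [
        "A benign meningioma tumour seen in this MRI.",
        "Well-defined meningioma mass.",
        "Extra-axial dural-based mass adjacent to the skull on MRI.",
        "A meningioma at the cerebral convexity on axial MRI.",
        "T1-weighted MRI of a well-circumscribed meningioma.",
    ],
    "pituitary": [
        "A pituitary tumour pressing on the optic chiasm.",
        "Enlargement of pituitary gland in MRI.",
        "Sellar and suprasellar mass on axial MRI.",
        "A pituitary adenoma in the sella turcica.",
        "T1-weighted MRI of a pituitary tumour.",
    ],
}

_CLASS_KEYWORDS = {
    "normal": ("normal", "healthy", "no visible tumour", "without focal",
               "no tumour", "symmetry", "intact"),
    "glioma": ("glioma", "intra-parenchymal", "infiltrative", "malignant"),
    "meningioma": ("meningioma", "extra-axial", "dural", "convexity"),
    "pituitary": ("pituitary", "sellar", "sella", "adenoma", "optic chiasm"),
}


@runtime_checkable
class EmbeddingProvider(Protocol):
    descriptor: str

    def image_encode(self, image) -> np.ndarray: ...

    def text_encode(self, prompt: str) -> np.ndarray: ...


@dataclass
class PromptBank:
    """Candidate and selected prompts per class + averaged class embeddings.

    ``class_embeddings`` (built by :func:`build_class_embeddings`) is an
    array aligned with ``classes`` order; each row is the L2-normalized
    mean of the class's selected prompt embeddings.
    """

    candidates: dict[str, list[str]]
    selected: dict[str, list[str]] | None = None
    class_embeddings: np.ndarray | None = None
    margins: dict[str, list[float]] | None = None
    classes: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        if self.selected is not None:
            for cls, sel in self.selected.items():
                extra = set(sel) - set(self.candidates.get(cls, []))
                if extra:
                    raise ValueError(f"selected prompts not in candidates for {cls!r}: {extra}")

    def save(self, path: str | Path) -> None:
        d = {
            cls: {
                "candidates": self.candidates[cls],
                "selected": (self.selected or {}).get(cls, []),
            }
            for cls in self.classes
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PromptBank":
        d = json.loads(Path(path).read_text())
        return cls(
            candidates={c: d[c]["candidates"] for c in d},
            selected={c: d[c]["selected"] for c in d if d[c]["selected"]} or None,
        )


def default_prompt_bank() -> PromptBank:
    """The five handcrafted prompts per class, all selected."""
    cands = {c: list(v) for c, v in DEFAULT_PROMPTS.items()}
    return PromptBank(candidates=cands, selected={c: list(v) for c, v in cands.items()})


@dataclass
class ZeroShotPrediction:
    similarities: np.ndarray  # per class, in bank order
    predicted: int
    margin: float             # top minus runner-up similarity


# ---------------------------------------------------------------------------
# synthetic provider
# ---------------------------------------------------------------------------

def _hash_rng(*parts: str) -> np.random.Generator:
    h = hashlib.sha256("\x1f".join(parts).encode()).digest()
    return np.random.default_rng(np.frombuffer(h[:16], dtype=np.uint32))


class SyntheticProvider:
    """Deterministic stand-in encoder pair over the simulated anchor space.

    ``prompt_table`` optionally maps prompt -> (class_name, quality) to
    plant a known prompt-quality ordering; prompts not in the table are
    assigned to a class by keyword and given ``default_quality`` with a
    small deterministic per-prompt jitter.
    """

    def __init__(
        self,
        sim_spec: EmbeddingSimSpec | None = None,
        prompt_table: dict[str, tuple[str, float]] | None = None,
        default_quality: float = 0.85,
        classes: tuple[str, ...] = CLASS_NAMES,
    ) -> None:
        self.sim_spec = sim_spec or EmbeddingSimSpec()
        self.anchors = class_anchors(self.sim_spec)
        self.prompt_table = dict(prompt_table or {})
        self.default_quality = default_quality
        self.classes = classes
        self.descriptor = (
            f"synthetic(dim={self.sim_spec.dim}, seed={self.sim_spec.seed}, "
            f"noise_sd={self.sim_spec.noise_sd})"
        )

    def state_hash(self) -> str:
        return hashlib.sha256(self.anchors.tobytes()).hexdigest()

    def image_encode(self, image) -> np.ndarray:
        """Embed a Phantom near its class anchor (deterministic per item).

        The phantom's identity (patient, slice) seeds the dispersion, so
        re-encoding the same item always gives the same vector.
        """
        if not isinstance(image, Phantom):
            raise TypeError(
                "SyntheticProvider.image_encode expects a Phantom; real image "
                "arrays require a trained vision encoder plug-in"
            )
        rng = _hash_rng("img", image.patient_id, str(image.slice_index), str(image.label))
        v = self.anchors[image.label] + self.sim_spec.noise_sd * rng.standard_normal(
            self.sim_spec.dim
        )
        n = np.linalg.norm(v)
        return v / n if n > 0 else self.anchors[image.label]

    def _prompt_class_quality(self, prompt: str) -> tuple[int, float]:
        if prompt in self.prompt_table:
            cls_name, quality = self.prompt_table[prompt]
            return self.classes.index(cls_name), float(quality)
        low = prompt.lower()
        for ci, cls_name in enumerate(self.classes):
            if any(k in low for k in _CLASS_KEYWORDS[cls_name]):
                jitter = _hash_rng("q", prompt).uniform(-0.05, 0.05)
                return ci, float(np.clip(self.default_quality + jitter, 0.0, 1.0))
        raise ValueError(f"cannot infer a class for prompt {prompt!r}")

    def text_encode(self, prompt: str) -> np.ndarray:
        ci, quality = self._prompt_class_quality(prompt)
        anchor = self.anchors[ci]
        # deterministic off-anchor direction, orthogonalized against anchor
        d = _hash_rng("txt", prompt).standard_normal(self.sim_spec.dim)
        d -= (d @ anchor) * anchor
        d /= np.linalg.norm(d)
        angle = (1.0 - quality) * math.pi / 2
        return math.cos(angle) * anchor + math.sin(angle) * d


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def cosine_similarity(v: np.ndarray, t: np.ndarray) -> float:
    """v . t / (||v|| ||t||); undefined (error) for zero vectors."""
    v, t = np.asarray(v, dtype=np.float64), np.asarray(t, dtype=np.float64)
    nv, nt = np.linalg.norm(v), np.linalg.norm(t)
    if nv == 0 or nt == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(v @ t / (nv * nt))


def build_class_embeddings(provider: EmbeddingProvider, bank: PromptBank) -> PromptBank:
    """Fill ``bank.class_embeddings``: normalized mean of selected prompts."""
    selected = bank.selected or bank.candidates
    rows = []
    for cls in bank.classes:
        prompts = selected.get(cls, [])
        if not prompts:
            raise ValueError(f"no selected prompts for class {cls!r}")
        embs = np.stack([provider.text_encode(p) for p in prompts])
        mean = embs.mean(axis=0)
        n = np.linalg.norm(mean)
        if n == 0:
            raise ValueError(f"degenerate (zero) mean embedding for class {cls!r}")
        rows.append(mean / n)
    bank.class_embeddings = np.stack(rows)
    return bank


def classify_zero_shot(
    provider: EmbeddingProvider, bank: PromptBank, image
) -> ZeroShotPrediction:
    """Cosine-similarity argmax over class embeddings; ties -> lowest index."""
    if bank.class_embeddings is None:
        raise ValueError("PromptBank has no class embeddings; call build_class_embeddings")
    v = provider.image_encode(image)
    if v.shape[0] != bank.class_embeddings.shape[1]:
        raise ValueError(
            f"provider dimension {v.shape[0]} != bank dimension "
            f"{bank.class_embeddings.shape[1]}"
        )
    sims = np.array([cosine_similarity(v, t) for t in bank.class_embeddings])
    pred = int(sims.argmax())
    runner = np.partition(sims, -2)[-2] if len(sims) > 1 else -1.0
    return ZeroShotPrediction(similarities=sims, predicted=pred,
                              margin=float(sims[pred] - runner))


def prompt_margin(
    provider: EmbeddingProvider,
    prompt: str,
    prompt_class: str,
    validation_items: Sequence,
    validation_labels: Sequence[int],
    bank: PromptBank,
    leave_one_out: bool = False,
) -> float:
    """Mean cosine-similarity margin of one candidate prompt.

    For each validation image of the prompt's class:
    margin = sim(image, prompt embedding)
             - max over competing classes c' of sim(image, t[c']).
    Competing class embeddings t[c'] come from the bank's selected
    (default) prompts; with ``leave_one_out`` they are rebuilt from each
    competitor's full candidate pool instead.
    """
    ci = bank.classes.index(prompt_class)
    labels = np.asarray(validation_labels, dtype=int)
    items = [it for it, l in zip(validation_items, labels) if l == ci]
    if not items:
        raise ValueError(f"no validation items for class {prompt_class!r}")
    if leave_one_out:
        comp_bank = PromptBank(candidates=bank.candidates, classes=bank.classes)
        comp_bank = build_class_embeddings(provider, comp_bank)
    else:
        comp_bank = bank if bank.class_embeddings is not None else build_class_embeddings(
            provider, bank
        )
    t_comp = comp_bank.class_embeddings
    t_prompt = provider.text_encode(prompt)
    margins = []
    for item in items:
        v = provider.image_encode(item)
        own = cosine_similarity(v, t_prompt)
        best_comp = max(
            cosine_similarity(v, t_comp[cj])
            for cj in range(len(bank.classes))
            if cj != ci
        )
        margins.append(own - best_comp)
    return float(np.mean(margins))


def select_prompts(
    provider: EmbeddingProvider,
    candidates: dict[str, list[str]],
    validation_items: Sequence,
    validation_labels: Sequence[int],
    top_n: int = 5,
    leave_one_out: bool = False,
) -> PromptBank:
    """Pick the ``top_n`` candidates per class by mean margin (descending;
    ties keep candidate order) and build the averaged class embeddings."""
    base = default_prompt_bank()
    bank = PromptBank(candidates=candidates, classes=base.classes)
    ref_bank = build_class_embeddings(provider, default_prompt_bank())
    selected: dict[str, list[str]] = {}
    margins: dict[str, list[float]] = {}
    for cls in bank.classes:
        pool = candidates.get(cls, [])
        if len(pool) < top_n:
            raise ValueError(
                f"class {cls!r} has {len(pool)} candidates, need >= {top_n}"
            )
        m = np.array([
            prompt_margin(provider, p, cls, validation_items, validation_labels,
                          ref_bank, leave_one_out=leave_one_out)
            for p in pool
        ])
        order = np.argsort(-m, kind="stable")[:top_n]
        selected[cls] = [pool[i] for i in sorted(order)]
        margins[cls] = m.tolist()
    out = PromptBank(candidates=candidates, selected=selected, margins=margins,
                     classes=bank.classes)
    return build_class_embeddings(provider, out)


def visual_prototype_zero_shot(
    image_encode,
    support_items: Sequence,
    support_labels: Sequence[int],
    test_items: Sequence,
    n_classes: int = len(CLASS_NAMES),
) -> tuple[np.ndarray, np.ndarray]:
    """Visual-only zero-shot baseline: cosine similarity to normalized mean
    support embeddings per class (no text guidance).

    Returns (predicted labels, similarity matrix items x classes).
    """
    labels = np.asarray(support_labels, dtype=int)
    embs = np.stack([image_encode(it) for it in support_items])
    protos = []
    for c in range(n_classes):
        sel = labels == c
        if not sel.any():
            raise ValueError(f"class {c} missing from support set")
        mean = embs[sel].mean(axis=0)
        n = np.linalg.norm(mean)
        if n == 0:
            raise ValueError(f"degenerate zero prototype for class {c}")
        protos.append(mean / n)
    protos = np.stack(protos)
    test_embs = [image_encode(it) for it in test_items]
    sims = np.stack([[cosine_similarity(v, p) for p in protos] for v in test_embs])
    return sims.argmax(axis=1), sims
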