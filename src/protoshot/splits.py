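"""Manifests, three-way non-overlapping splits, preprocessing, augmentation.

A manifest is a pandas DataFrame with columns
``path, class, patient_id, slice_index, split`` where split is one of
``fsl_train`` (episodic training), ``fsl_test`` (episodic evaluation),
``zsl_eval`` (zero-shot evaluation) or ``unassigned``.

Patient-level splitting confines every slice of a patient to a single
split, which is the guard against near-duplicate leakage between episodic
training and evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from protoshot.phantoms import CLASS_NAMES, Phantom, zscore

log = logging.getLogger(__name__)

SPLITS = ("fsl_train", "fsl_test", "zsl_eval")
MANIFEST_COLUMNS = ["path", "class", "patient_id", "slice_index", "split"]


@dataclass(frozen=True)
class SplitConfig:
    """Requested split sizes (totals across classes) and assignment policy.

    Exactly one of ``counts`` / ``fractions`` must be given. Splits are
    class-balanced to the extent the counts allow (largest-remainder
    rounding otherwise).
    """

    counts: Mapping[str, int] | None = None
    fractions: Mapping[str, float] | None = None
    seed: int = 0
    patient_level: bool = True

    def __post_init__(self) -> None:
        if (self.counts is None) == (self.fractions is None):
            raise ValueError("give exactly one of counts or fractions")
        keys = set(self.counts or self.fractions)
        if not keys <= set(SPLITS):
            raise ValueError(f"unknown split names {keys - set(SPLITS)}")
        if self.fractions is not None and sum(self.fractions.values()) > 1 + 1e-9:
            raise ValueError("fractions must sum to <= 1")


def manifest_from_phantoms(phantoms: Sequence[Phantom]) -> pd.DataFrame:
    """Manifest for an in-memory phantom pool (synthetic ``mem://`` paths)."""
    rows = [
        (
            f"mem://{p.patient_id}/s{p.slice_index}",
            CLASS_NAMES[p.label],
            p.patient_id,
            p.slice_index,
            "unassigned",
        )
        for p in phantoms
    ]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"path": str, "class": str, "patient_id": str})
    missing = set(MANIFEST_COLUMNS) - {"split"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if "split" not in df.columns:
        df["split"] = "unassigned"
    _validate_manifest(df)
    return df


def save_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


def _validate_manifest(df: pd.DataFrame) -> None:
    dup = df["path"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate paths in manifest: {df['path'][dup].tolist()[:5]}")
    bad = set(df["class"]) - set(CLASS_NAMES)
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}")


def _per_class_quota(total: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` across classes as evenly as counts allow."""
    base, rem = divmod(total, n_classes)
    quota = np.full(n_classes, base, dtype=int)
    if rem:
        quota[rng.permutation(n_classes)[:rem]] += 1
    return quota


def assign_splits(manifest: pd.DataFrame, cfg: SplitConfig) -> pd.DataFrame:
    """Assign records to the three disjoint splits, reproducibly.

    Returns a new manifest; records beyond the requested counts keep the
    ``unassigned`` tag. With ``patient_level`` every patient lands in
    exactly one split; the per-class quota of a split must then be
    realizable as a union of whole patients, otherwise the offending
    patient and the shortfall are named in the error.
    """
    _validate_manifest(manifest)
    df = manifest.copy()
    n = len(df)
    if cfg.counts is not None:
        counts = dict(cfg.counts)
        if sum(counts.values()) > n:
            raise ValueError(f"requested {sum(counts.values())} records, only {n} available")
    else:
        counts = {s: int(round(f * n)) for s, f in cfg.fractions.items()}

    patient_level = cfg.patient_level
    if patient_level and ("patient_id" not in df.columns or df["patient_id"].isna().any()
                          or (df["patient_id"].astype(str) == "").any()):
        log.warning("patient_id missing for some records; degrading to slice-level split")
        patient_level = False

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]))
    df["split"] = "unassigned"
    classes = [c for c in CLASS_NAMES if (df["class"] == c).any()]
    quotas = {s: _per_class_quota(c, len(classes), rng) for s, c in counts.items()}

    for ci, cls in enumerate(classes):
        cls_idx = df.index[df["class"] == cls].to_numpy()
        if patient_level:
            patients = sorted(df.loc[cls_idx, "patient_id"].unique())
            order = rng.permutation(len(patients))
            queue = [patients[i] for i in order]
            for split in counts:
                need = int(quotas[split][ci])
                while need > 0:
                    if not queue:
                        raise ValueError(
                            f"class {cls!r}: not enough patients to fill split "
                            f"{split!r} (short {need} records)"
                        )
                    pid = queue.pop()
                    rows = df.index[(df["class"] == cls) & (df["patient_id"] == pid)]
                    if len(rows) > need:
                        raise ValueError(
                            f"patient {pid!r} has {len(rows)} slices but split "
                            f"{split!r} class {cls!r} needs only {need} more; "
                            "make per-class counts a multiple of slices_per_patient"
                        )
                    df.loc[rows, "split"] = split
                    need -= len(rows)
        else:
            order = rng.permutation(len(cls_idx))
            pos = 0
            for split in counts:
                need = int(quotas[split][ci])
                if pos + need > len(cls_idx):
                    raise ValueError(
                        f"class {cls!r}: {len(cls_idx) - pos} records left, "
                        f"split {split!r} needs {need}"
                    )
                df.loc[cls_idx[order[pos:pos + need]], "split"] = split
                pos += need
    return df


def verify_no_leakage(manifest: pd.DataFrame) -> list[str]:
    """Return violations: paths duplicated anywhere, or (with patient IDs)
    patients whose records straddle more than one assigned split.

    Empty list == clean partition.
    """
    violations: list[str] = []
    dup_paths = manifest["path"][manifest["path"].duplicated(keep=False)].unique()
    for p in dup_paths:
        splits = sorted(manifest.loc[manifest["path"] == p, "split"].unique())
        violations.append(f"path {p!r} appears in multiple records (splits {splits})")
    assigned = manifest[manifest["split"].isin(SPLITS)]
    if "patient_id" in manifest.columns:
        spread = assigned.groupby("patient_id")["split"].nunique()
        for pid in spread.index[spread > 1]:
            splits = sorted(assigned.loc[assigned["patient_id"] == pid, "split"].unique())
            violations.append(f"patient {pid!r} appears in splits {splits}")
    return violations


def preprocess(image: np.ndarray, target_size: int) -> np.ndarray:
    """Bicubic resize to ``target_size`` square, then z-score normalize.

    A zero-variance (constant) input cannot be normalized; it maps to the
    all-zero array with a logged warning rather than dividing by zero.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("preprocess expects a nonempty 2D array")
    if image.shape != (target_size, target_size):
        image = _sk_resize(
            image, (target_size, target_size), order=3,
            mode="edge", anti_aliasing=False, preserve_range=True,
        )
    sd = image.std()
    if sd <= 1e-12 * max(1.0, abs(float(image.mean()))):  # constant up to fp jitter
        log.warning("zero-variance image; returning all-zero array")
        return np.zeros_like(image)
    return (image - image.mean()) / sd


def augment(
    image: np.ndarray,
    rng: np.random.Generator,
    enabled: bool = True,
    flip_prob: float = 0.5,
    brightness: float = 0.1,
) -> np.ndarray:
    """Horizontal flip (probability ``flip_prob``) + uniform brightness
    offset in [-brightness, +brightness]; identity when disabled."""
    if not enabled:
        return image
    out = image
    if flip_prob > 0 and rng.uniform() < flip_prob:
        out = out[:, ::-1]
    if brightness > 0:
        out = out + rng.uniform(-brightness, brightness)
    elif out is image:
        out = image.copy()
    return out
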