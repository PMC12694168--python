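"""Synthetic brain-MRI phantom generation.

Produces 2D grayscale head phantoms across the four study classes
(normal, glioma, meningioma, pituitary) with ground-truth lesion masks,
synthetic patient structure, and deterministic counter-based seeding so
that item ``i`` of a dataset is identical no matter in which order items
are generated.

Class-conditional lesion geometry encodes the radiological priors the
classifier is expected to recover:

* glioma       -- large, irregular-bordered lesion inside the inner
                  parenchymal disc (infiltrative margins);
* meningioma   -- mid-sized smooth lesion in a peripheral annulus
                  adjacent to the simulated skull rim (extra-axial);
* pituitary    -- small lesion confined to a central-inferior sellar box;
* normal       -- no lesion.

The classes therefore differ in lesion location, size and border texture,
mirroring clinical presentation (pituitary adenomas are small and midline,
gliomas bulky and infiltrative, meningiomas dural-based).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

CLASS_NAMES: tuple[str, ...] = ("normal", "glioma", "meningioma", "pituitary")
NORMAL, GLIOMA, MENINGIOMA, PITUITARY = range(4)

# head geometry as fractions of image_size (row = y, inferior is +y)
_HEAD_AY = 0.44  # vertical semi-axis
_HEAD_AX = 0.38  # horizontal semi-axis
_RIM_INNER = 0.92  # skull rim occupies elliptical radius (0.92, 1.0]

# class location priors (elliptical radius rho is 1.0 at the rim)
_GLIOMA_RHO_MAX = 0.55       # lesion centers inside the parenchymal core
_MENINGIOMA_RHO = (0.74, 0.86)
_SELLAR_X = (0.44, 0.56)     # fractions of image_size
_SELLAR_Y = (0.58, 0.72)

# class size priors, lesion mean radius as fraction of image_size
_RADIUS_RANGE = {
    GLIOMA: (0.10, 0.16),
    MENINGIOMA: (0.055, 0.09),
    PITUITARY: (0.04, 0.06),  # macroadenoma scale, resolvable after pooling
}


@dataclass(frozen=True)
class PhantomSpec:
    """Configuration of the phantom generator.

    Parameters
    ----------
    image_size : pixels per side of the square image (>= 32).
    classes : the four class names in fixed order.
    lesion_contrast : additive intensity offset of lesion vs background,
        in raw (pre-normalization) units where the head interior is ~0.5.
    noise_sd : additive Gaussian noise scale in the same raw units.
    slices_per_patient : slices each synthetic patient contributes.
    seed : master seed; expands into per-phantom substreams.
    """

    image_size: int = 96
    classes: tuple[str, ...] = CLASS_NAMES
    lesion_contrast: float = 0.8
    noise_sd: float = 0.05
    slices_per_patient: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.classes) != CLASS_NAMES:
            raise ValueError(
                f"classes must be exactly {CLASS_NAMES} in this order, "
                f"got {tuple(self.classes)}"
            )
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.slices_per_patient < 1:
            raise ValueError("slices_per_patient must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Phantom:
    """One generated slice: normalized image + label + ground-truth mask."""

    image: np.ndarray
    label: int
    lesion_mask: np.ndarray
    patient_id: str
    slice_index: int


@dataclass(frozen=True)
class EmbeddingSimSpec:
    """Synthetic embedding space emulating a shared image/text encoder.

    Class anchors are unit vectors with equal pairwise angular separation
    ``anchor_separation`` (radians, in (0, pi/2]); samples are drawn around
    an anchor with isotropic dispersion ``noise_sd`` and re-normalized.
    """

    dim: int = 512
    n_classes: int = 4
    anchor_separation: float = math.pi / 3
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.anchor_separation <= math.pi / 2 + 1e-12:
            raise ValueError("anchor_separation must be in (0, pi/2] radians")
        if self.dim < self.n_classes + 1:
            raise ValueError("dim must be >= n_classes + 1")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grids(size: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    return y, x


def elliptical_radius(size: int) -> np.ndarray:
    """Elliptical radius field: 1.0 on the skull rim, 0 at head center."""
    y, x = _grids(size)
    cy = cx = (size - 1) / 2.0
    return np.sqrt(
        ((y - cy) / (_HEAD_AY * size)) ** 2 + ((x - cx) / (_HEAD_AX * size)) ** 2
    )


def sellar_box(size: int) -> tuple[float, float, float, float]:
    """(x_lo, x_hi, y_lo, y_hi) of the central-inferior sellar region, pixels."""
    return (
        _SELLAR_X[0] * size,
        _SELLAR_X[1] * size,
        _SELLAR_Y[0] * size,
        _SELLAR_Y[1] * size,
    )


def location_prior(spec: PhantomSpec, label: int) -> np.ndarray:
    """Boolean mask of where the class's lesion centroid may fall.

    Margins are slightly generous relative to the center-placement regions
    because centroid jitter (irregular glioma borders, rim clipping) moves
    the mask centroid a little off the drawn center.
    """
    size = spec.image_size
    rho = elliptical_radius(size)
    if label == NORMAL:
        return np.zeros((size, size), dtype=bool)
    if label == GLIOMA:
        return rho <= _GLIOMA_RHO_MAX + 0.12
    if label == MENINGIOMA:
        return (rho >= _MENINGIOMA_RHO[0] - 0.12) & (rho <= 1.0)
    if label == PITUITARY:
        y, x = _grids(size)
        x_lo, x_hi, y_lo, y_hi = sellar_box(size)
        pad = 0.02 * size
        return (
            (x >= x_lo - pad) & (x <= x_hi + pad)
            & (y >= y_lo - pad) & (y <= y_hi + pad)
        )
    raise ValueError(f"unknown label {label!r}; expected 0..3")


def _lesion_center(label: int, size: int, rng: np.random.Generator) -> tuple[float, float]:
    cy = cx = (size - 1) / 2.0
    if label == GLIOMA:
        # uniform over the inner parenchymal ellipse via rejection-free polar draw
        rho = _GLIOMA_RHO_MAX * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
    elif label == MENINGIOMA:
        rho = rng.uniform(*_MENINGIOMA_RHO)
        theta = rng.uniform(0, 2 * math.pi)
    elif label == PITUITARY:
        x_lo, x_hi, y_lo, y_hi = sellar_box(size)
        return rng.uniform(y_lo, y_hi), rng.uniform(x_lo, x_hi)
    else:
        raise ValueError(f"unknown label {label!r}; expected 0..3")
    return (
        cy + rho * _HEAD_AY * size * math.sin(theta),
        cx + rho * _HEAD_AX * size * math.cos(theta),
    )


def _lesion_params(label: int, size: int, rng: np.random.Generator) -> dict:
    """Draw per-patient lesion geometry; shared by all slices of a patient."""
    lo, hi = _RADIUS_RANGE[label]
    r = rng.uniform(lo, hi) * size
    aspect = rng.uniform(0.75, 1.3)
    angle = rng.uniform(0, math.pi)
    cy, cx = _lesion_center(label, size, rng)
    params = {"cy": cy, "cx": cx, "ry": r * aspect, "rx": r / aspect, "angle": angle}
    if label == GLIOMA:
        # irregular infiltrative border: low-order angular perturbation
        params["fourier"] = [
            (k, rng.uniform(-0.16, 0.16), rng.uniform(0, 2 * math.pi))
            for k in range(2, 6)
        ]
    return params


def _rasterize_lesion(size: int, params: dict) -> np.ndarray:
    y, x = _grids(size)
    dy, dx = y - params["cy"], x - params["cx"]
    ca, sa = math.cos(params["angle"]), math.sin(params["angle"])
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    rho = np.sqrt((u / params["rx"]) ** 2 + (v / params["ry"]) ** 2)
    boundary = np.ones_like(rho)
    for k, amp, phase in params.get("fourier", []):
        theta = np.arctan2(v, u)
        boundary = boundary + amp * np.cos(k * theta + phase)
    mask = rho <= np.maximum(boundary, 0.2)
    # lesions live inside the skull: clip to head interior
    mask &= elliptical_radius(size) < _RIM_INNER
    return mask


def _background(size: int) -> np.ndarray:
    rho = elliptical_radius(size)
    img = np.zeros((size, size), dtype=np.float64)
    interior = rho < _RIM_INNER
    img[interior] = 0.45 + 0.12 * (1.0 - rho[interior] ** 2)
    rim = (rho >= _RIM_INNER) & (rho <= 1.0)
    img[rim] = 0.95
    return img


def zscore(image: np.ndarray) -> np.ndarray:
    """Normalize to zero mean, unit variance (all-zero if constant)."""
    sd = image.std()
    if sd == 0:
        return np.zeros_like(image, dtype=np.float64)
    return (image - image.mean()) / sd


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _substream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: order-independent, restart-stable."""
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def generate_phantom(
    spec: PhantomSpec,
    label: int,
    rng: np.random.Generator,
    *,
    patient_id: str = "P0",
    slice_index: int = 0,
    base_params: dict | None = None,
) -> Phantom:
    """Generate one phantom slice.

    ``base_params`` carries the per-patient lesion geometry; when given, the
    slice applies a small positional/size jitter to it so slices of one
    patient are correlated (which makes patient-level leakage detectable).
    """
    if label not in (NORMAL, GLIOMA, MENINGIOMA, PITUITARY):
        raise ValueError(f"unknown label {label!r}; expected 0..3")
    size = spec.image_size
    if label == NORMAL:
        mask = np.zeros((size, size), dtype=bool)
    else:
        params = dict(base_params) if base_params else _lesion_params(label, size, rng)
        if base_params is not None:
            jit = 0.01 * size
            params["cy"] += rng.uniform(-jit, jit)
            params["cx"] += rng.uniform(-jit, jit)
            scale = 1.0 + rng.uniform(-0.06, 0.06)
            params["ry"] *= scale
            params["rx"] *= scale
        mask = _rasterize_lesion(size, params)
        if not mask.any():  # extreme jitter pushed lesion outside; recenter
            params["cy"], params["cx"] = _lesion_center(label, size, rng)
            mask = _rasterize_lesion(size, params)
    img = _background(size)
    img[mask] += spec.lesion_contrast
    img = gaussian_filter(img, sigma=1.0)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return Phantom(
        image=zscore(img),
        label=label,
        lesion_mask=mask,
        patient_id=patient_id,
        slice_index=slice_index,
    )


def generate_dataset(spec: PhantomSpec, n_per_class: int) -> list[Phantom]:
    """Balanced phantom pool: ``n_per_class`` slices per class.

    Each synthetic patient contributes ``spec.slices_per_patient`` slices
    that share one (jittered) lesion geometry. Fully determined by
    ``spec.seed`` via counter-based substreams.
    """
    spp = spec.slices_per_patient
    if n_per_class < spp:
        raise ValueError("n_per_class must be >= slices_per_patient")
    if n_per_class % spp != 0:
        raise ValueError(
            f"n_per_class={n_per_class} is not divisible by "
            f"slices_per_patient={spp}; adjust one of them"
        )
    phantoms: list[Phantom] = []
    n_patients = n_per_class // spp
    for label in range(len(spec.classes)):
        for p in range(n_patients):
            pid = f"{spec.classes[label][:4].upper()}{p:04d}"
            base = None
            if label != NORMAL:
                base = _lesion_params(
                    label, spec.image_size, _substream(spec.seed, 11, label, p)
                )
            for s in range(spp):
                rng = _substream(spec.seed, 13, label, p, s)
                phantoms.append(
                    generate_phantom(
                        spec, label, rng,
                        patient_id=pid, slice_index=s, base_params=base,
                    )
                )
    return phantoms


# ---------------------------------------------------------------------------
# synthetic embedding space
# ---------------------------------------------------------------------------

def class_anchors(spec: EmbeddingSimSpec) -> np.ndarray:
    """Unit anchors with equal pairwise angle ``anchor_separation``.

    Construction: a_i = cos(phi) * u + sin(phi) * e_i with orthonormal
    {u, e_1..e_C}; then <a_i, a_j> = cos(phi)^2, so phi =
    arccos(sqrt(cos(separation))) realizes the requested angle exactly.
    """
    rng = _substream(spec.seed, 17)
    m = rng.standard_normal((spec.dim, spec.n_classes + 1))
    q, _ = np.linalg.qr(m)
    u, basis = q[:, -1], q[:, : spec.n_classes]
    phi = math.acos(math.sqrt(max(math.cos(spec.anchor_separation), 0.0)))
    anchors = math.cos(phi) * u[:, None] + math.sin(phi) * basis
    return (anchors / np.linalg.norm(anchors, axis=0)).T  # (n_classes, dim)


def generate_class_embeddings(
    spec: EmbeddingSimSpec, label: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n unit vectors dispersed around the class anchor."""
    if not 0 <= label < spec.n_classes:
        raise ValueError(f"label {label} out of range 0..{spec.n_classes - 1}")
    if n < 1:
        raise ValueError("n must be >= 1")
    anchor = class_anchors(spec)[label]
    v = anchor[None, :] + spec.noise_sd * rng.standard_normal((n, spec.dim))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def write_dataset(phantoms: Sequence[Phantom], spec: PhantomSpec, out_dir: str | Path) -> Path:
    """Write phantoms as 8-bit PNGs + float cache + manifest CSV.

    PNGs are min-max rescaled for storage; the normalized float arrays are
    cached in ``arrays.npz`` keyed by relative path. Masks go alongside with
    a ``_mask`` suffix. Returns the manifest path.
    """
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, arrays = [], {}
    for ph in phantoms:
        cls = spec.classes[ph.label]
        sub = out / cls
        sub.mkdir(exist_ok=True)
        stem = f"{ph.patient_id}_s{ph.slice_index}"
        rel = f"{cls}/{stem}.png"
        lo, hi = ph.image.min(), ph.image.max()
        scaled = (ph.image - lo) / (hi - lo) if hi > lo else np.zeros_like(ph.image)
        Image.fromarray((scaled * 255).astype(np.uint8)).save(out / rel)
        Image.fromarray((ph.lesion_mask * 255).astype(np.uint8)).save(
            sub / f"{stem}_mask.png"
        )
        arrays[rel] = ph.image.astype(np.float32)
        rows.append((rel, cls, ph.patient_id, ph.slice_index, "unassigned"))
    np.savez_compressed(out / "arrays.npz", **arrays)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "class", "patient_id", "slice_index", "split"])
        w.writerows(rows)
    return manifest
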