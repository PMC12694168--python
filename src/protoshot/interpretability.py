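"""Grad-CAM saliency for the metric classifier + lesion localization scoring.

Grad-CAM weights a convolutional layer's feature maps by the spatial
average of the class-score gradient, rectifies the weighted sum, and
upsamples it to input size. A prototype classifier has no logit, so a
class score must be chosen; three are provided:

* ``neg_distance`` -- -d(z, p_c), monotone in the posterior (default);
* ``posterior``    -- the distance-softmax probability of the class;
* ``proto_logit``  -- z . (p_c - mean_c' p_c'), the exact linear
  discriminant of the nearest-prototype rule (argmin distance ==
  argmax z.p_c - ||p_c||^2/2, so the class-dependent, feature-dependent
  part of the score is this dot product).

Two weighting schemes are available: the classical channel-averaged
weights, and element-wise gradient weighting (as in HiResCAM), which
preserves the spatial sign structure of the gradient. With a
global-average-pooled metric head the channel-averaged form can cancel
to an all-zero map for classes whose evidence is encoded by feature
suppression; quantitative localization scoring therefore defaults to
the element-wise form on the first (highest-resolution) block with mild
Gaussian smoothing -- see :data:`LOCALIZATION_CAM`.

Because the phantom generator provides ground-truth lesion masks, the
qualitative "does the model look at the tumor?" question becomes a
measurable one: peak-in-mask, IoU of the thresholded map against the
mask, and centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as _sk_resize

from protoshot.protonet import posterior_from_distances

#: Grad-CAM configuration used for quantitative lesion localization.
LOCALIZATION_CAM = dict(
    score="proto_logit", weighting="elementwise", target_layer=0, smooth_sigma=2.0
)


@dataclass
class SaliencyMap:
    map: np.ndarray          # (H, W) in [0, 1] (max-normalized), >= 0
    target_class: int
    target_layer: int


@dataclass
class LocalizationScore:
    peak_in_mask: bool
    iou: float
    centroid_distance: float


def gradcam(
    model,
    image: np.ndarray,
    target_class: int,
    prototypes: np.ndarray,
    target_layer: int = -1,
    score: str = "neg_distance",
    weighting: str = "channel",
    smooth_sigma: float = 0.0,
) -> SaliencyMap:
    """Grad-CAM map for one image against a prototype set.

    ``target_layer`` indexes the backbone's convolutional blocks (default
    last); ``score`` selects the class score (see module docstring);
    ``weighting='channel'`` is classical Grad-CAM (spatially averaged
    channel weights), ``'elementwise'`` keeps per-location gradients;
    ``smooth_sigma`` optionally Gaussian-smooths the upsampled map.
    """
    n_blocks = len(model.blocks)
    layer = target_layer if target_layer >= 0 else n_blocks + target_layer
    if not 0 <= layer < n_blocks:
        raise ValueError(f"target_layer {target_layer} outside 0..{n_blocks - 1}")
    prototypes = np.asarray(prototypes, dtype=np.float64)
    if not 0 <= target_class < len(prototypes):
        raise ValueError(f"no prototype for class {target_class}")

    z = model.forward(np.asarray(image)[None], train=False)  # (1, D)
    dz = np.zeros_like(z)
    if score == "neg_distance":
        diff = z[0] - prototypes[target_class]
        dist = np.linalg.norm(diff)
        if dist > 0:
            dz[0] = -diff / dist
    elif score == "posterior":
        d_all = np.linalg.norm(z[0][None, :] - prototypes, axis=1)
        p = posterior_from_distances(d_all)
        for j in range(len(prototypes)):
            dj = d_all[j]
            if dj == 0:
                continue
            unit = (z[0] - prototypes[j]) / dj
            # dP_c/dd_j = P_c (P_j - delta_jc)
            dz[0] += p[target_class] * (p[j] - (j == target_class)) * unit
    elif score == "proto_logit":
        dz[0] = prototypes[target_class] - prototypes.mean(axis=0)
    else:
        raise ValueError(f"unknown score {score!r}")

    model.zero_grad()
    model.backward(dz)
    acts = model.block_activations[layer][0]       # (C, h, w)
    grads = model.block_gradients[layer][0]
    if weighting == "channel":
        weights = grads.mean(axis=(1, 2))
        cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    elif weighting == "elementwise":
        cam = np.maximum((acts * grads).sum(axis=0), 0.0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    size = model.image_size
    cam = _sk_resize(cam.astype(np.float64), (size, size), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    if smooth_sigma > 0:
        cam = gaussian_filter(cam, smooth_sigma)
        cam = np.maximum(cam, 0.0)
    m = cam.max()
    if m > 0:
        cam = cam / m
    return SaliencyMap(map=cam, target_class=int(target_class), target_layer=layer)


def localization_score(
    saliency: SaliencyMap | np.ndarray,
    mask: np.ndarray,
    threshold: float = 0.5,
) -> LocalizationScore:
    """Score a saliency map against a ground-truth lesion mask.

    peak_in_mask: is the map's argmax inside the mask; IoU between the
    region {map >= threshold * max} and the mask; Euclidean distance
    between the two region centroids (the peak stands in for an empty
    thresholded region).
    """
    cam = saliency.map if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    mask = np.asarray(mask).astype(bool)
    if cam.shape != mask.shape:
        raise ValueError(f"shape mismatch: map {cam.shape} vs mask {mask.shape}")
    if not mask.any():
        raise ValueError(
            "empty lesion mask (normal class); use symmetry diagnostics "
            "instead of localization scoring"
        )
    peak = np.unravel_index(int(cam.argmax()), cam.shape)
    region = cam >= threshold * cam.max() if cam.max() > 0 else np.zeros_like(mask)
    inter = np.logical_and(region, mask).sum()
    union = np.logical_or(region, mask).sum()
    iou = float(inter / union) if union else 0.0
    mask_c = np.array(ndimage.center_of_mass(mask))
    region_c = np.array(ndimage.center_of_mass(region)) if region.any() else np.array(peak, float)
    return LocalizationScore(
        peak_in_mask=bool(mask[peak]),
        iou=iou,
        centroid_distance=float(np.linalg.norm(mask_c - region_c)),
    )


def umap_projection(
    embeddings: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    plot_path: str | None = None,
) -> tuple[np.ndarray, float]:
    """Seeded 2D UMAP of embeddings + silhouette score of the projection.

    The silhouette (by label, on the 2D coordinates) quantifies how
    cleanly classes cluster in the projection. Optionally writes a
    scatter plot.
    """
    import umap
    from sklearn.metrics import silhouette_score

    embeddings = np.asarray(embeddings)
    labels = np.asarray(labels)
    if len(embeddings) < 10:
        raise ValueError("need >= 10 embeddings for a projection")
    reducer = umap.UMAP(n_components=2, random_state=seed)
    coords = reducer.fit_transform(embeddings)
    sil = float(silhouette_score(coords, labels)) if len(np.unique(labels)) > 1 else 0.0
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lbl in np.unique(labels):
            sel = labels == lbl
            ax.scatter(coords[sel, 0], coords[sel, 1], s=8, label=str(lbl))
        ax.legend(fontsize=7)
        ax.set_title(f"UMAP (silhouette {sil:.2f})")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return coords, sil


def saliency_overlay_png(
    image: np.ndarray, saliency: SaliencyMap, path: str
) -> None:
    """Write an image + heatmap overlay PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(image, cmap="gray")
    ax.imshow(saliency.map, cmap="jet", alpha=0.4)
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.savefig(path, dpi=120)
    plt.close(fig)
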