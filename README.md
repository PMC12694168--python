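# protoshot

Few-shot versus zero-shot learning for four-way brain-MRI tumor
classification (normal / glioma / meningioma / pituitary), benchmarked
end-to-end on synthetic phantoms with ground-truth lesion masks.

Annotated medical imaging data is scarce, and the two main
data-efficient answers make very different bets: **few-shot metric
learning** adapts from a handful of labeled examples per class, while
**zero-shot vision–language classification** uses no labels at all,
comparing image embeddings to text-prompt embeddings. This package
implements both protocols — and the naive fine-tuning comparator between
them — as a reproducible pipeline for researchers studying data-efficient
classification, with a phantom generator standing in for patient data so
that every claim can be scored against known ground truth.

## What is implemented

* **Phantom generator** — head-shaped 2D slices with class-conditional
  lesion geometry (intra-parenchymal glioma, rim-adjacent meningioma,
  sellar pituitary), synthetic patients with correlated slices,
  ground-truth masks, z-score normalization, counter-based seeding.
* **Patient-level splits** — three disjoint subsets (episodic train,
  episodic test, zero-shot eval) with full leakage auditing.
* **Prototypical network** — episodes are N-way K-shot tasks; class
  prototypes are mean support embeddings
  `p_c = |S_c|⁻¹ Σ_{x∈S_c} f_θ(x)`, queries are classified by
  `P(y=c|x) ∝ exp(−‖f_θ(x) − p_c‖₂)`, trained by episodic NLL with Adam.
  The CNN encoder and its optimizer are implemented in numpy with
  hand-verified gradients (this is a torch-free stack).
* **Zero-shot prompt ensemble** — class embedding = normalized mean of
  selected prompt embeddings, cosine-similarity argmax, and the
  cosine-margin protocol that selects the best 5 of 20 candidate prompts
  per class on a validation split. Providers are pluggable; a synthetic
  provider with planted prompt quality ships for testing.
* **Baselines** — per-episode fine-tuning of a linear head on the
  support set alone, and a visual-prototype zero-shot classifier without
  text guidance.
* **Evaluation** — per-episode accuracy/precision/recall/F1, mean ± SD
  over episodes and seeds, seeded percentile-bootstrap CIs, row-normalized
  confusion matrices, macro one-vs-rest AUC (rank statistic).
* **Interpretability** — Grad-CAM for the metric classifier (several
  class-score and weighting variants), quantitative lesion-localization
  scoring (peak-in-mask, IoU, centroid distance) against the generator's
  masks, and UMAP projections with silhouette scores.

See `docs/methods.md` for the model details, parameter defaults and
design rationale.

## Worked example

Run the full comparison at desk scale (≈ 3 minutes on one CPU):

```bash
protoshot run-all --seed 42 --out runs/demo
```

This generates 480 phantoms, splits them patient-level, trains the
prototypical network episodically, evaluates all models, and writes
`runs/demo/report.json` plus a comparison table. A typical table at the
default (standard-difficulty) condition:

| model                   | accuracy (mean ± SD) | notes                          |
|-------------------------|----------------------|--------------------------------|
| protonet (K=5)          | 0.80 ± 0.08          | episodic metric learning       |
| finetune_head_baseline  | 0.60 ± 0.09          | per-episode supervised head    |
| visual_prototype_zsl    | 0.58                 | cosine to support prototypes   |
| prompt_ensemble_zsl     | 0.90                 | synthetic provider (oracle-ish)|

Read the rows as *orderings under matched conditions*, not clinical
accuracies: episodic metric learning beats per-episode fine-tuning by
≈ 20 accuracy points and beats the text-free visual-prototype baseline,
reproducing the qualitative hierarchy expected for data-efficient
classifiers. (The prompt-ensemble row uses the synthetic embedding
provider, which encodes phantom classes by construction — it validates
the zero-shot computation, not vision–language transfer.)

Library use mirrors the CLI:

```python
import numpy as np
from protoshot import (PhantomSpec, generate_dataset, EpisodeSpec,
                       BackboneConfig, TrainConfig, train_protonet,
                       evaluate_protonet)

pool = generate_dataset(PhantomSpec(lesion_contrast=1.2, noise_sd=0.03, seed=0), 40)
X = np.stack([p.image for p in pool]); y = np.array([p.label for p in pool])
model, curve = train_protonet(
    X, y, EpisodeSpec(k_shot=5, q_query=5, n_episodes=1, seed=0),
    BackboneConfig(),
    TrainConfig(learning_rate=1e-3, epochs=10, episodes_per_epoch=10,
                episode_batch=2, seed=0))
results = evaluate_protonet(model, X, y, EpisodeSpec(k_shot=5, n_episodes=100, seed=1))
print(np.mean([r["accuracy"] for r in results]))   # ≈ 0.97 on this easy pool
```

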