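# Methods

`protoshot` benchmarks data-efficient paradigms for four-way brain-MRI
tumor classification — few-shot metric learning against zero-shot
prompt-embedding classification — on a fully synthetic phantom study, so
that every claim the package makes is checkable against ground truth it
generated itself.

## The phantom generator

Each phantom is a 2D grayscale "axial slice": a head-shaped ellipse
(interior intensity ≈ 0.45–0.57 with a mild radial gradient), a bright
elliptical skull rim, an optional lesion, Gaussian smoothing (σ = 1 px),
additive Gaussian noise, and finally z-score normalization (zero mean,
unit variance — exactly, since the normalization is the last step).

The four classes differ in lesion geometry, mirroring the radiological
priors of the tumor types:

| class      | location prior                         | radius (× image size) | border |
|------------|----------------------------------------|-----------------------|--------|
| normal     | no lesion                              | —                     | —      |
| glioma     | inner parenchymal disc (ρ ≤ 0.55)      | 0.10–0.16             | irregular (low-order Fourier perturbation) |
| meningioma | peripheral annulus (ρ ∈ 0.74–0.86), abutting the rim | 0.055–0.09 | smooth |
| pituitary  | central-inferior sellar box            | 0.04–0.06             | smooth |

The size priors are part of the class definition, not a free dial: they
reflect clinical presentation (bulky infiltrative gliomas, mid-sized
dural-based meningiomas, small midline adenomas — the pituitary range is
macroadenoma scale, chosen so the lesion remains resolvable after three
2× poolings of the encoder). Location priors are what Grad-CAM is later
asked to recover.

Patients: each synthetic patient contributes `slices_per_patient`
(default 4) slices that share one lesion geometry with ±1 px positional
and ±6 % size jitter. Slices of one patient are therefore strongly
correlated — which is precisely what makes patient-level splitting
matter and slice-level leakage measurable.

Seeding: one master seed expands into per-phantom substreams through
`SeedSequence([seed, stream, label, patient, slice])`, so item *i* is
bit-identical regardless of generation order or process restarts.

What the generator does **not** emulate: MR physics (TR/TE, coil
inhomogeneity, bias fields), skull-stripping artifacts, 3D anatomy,
pathology heterogeneity (edema, necrosis, enhancement rings), or
inter-scanner variation. Passing tests therefore demonstrate that the
*algorithms* behave as specified on data with known structure — not that
any accuracy figure transfers to clinical MRI.

### Study conditions

Two named conditions are used throughout tests and the acceptance
script:

* **well-separated** — `lesion_contrast = 1.2`, `noise_sd = 0.03`: the
  near-noiseless regime for learning-recovery checks (the episodically
  trained network must exceed 0.90 held-out episode accuracy) and for
  saliency localization;
* **standard difficulty** — `lesion_contrast = 0.6`, `noise_sd = 0.15`:
  the regime for the model comparison. On near-noiseless phantoms even a
  randomly initialized frozen encoder saturates (cosine-to-prototype
  accuracy ≳ 0.9), so model ordering there carries no information; 0.6 /
  0.15 is the mildest setting of a three-point difficulty sweep that is
  clearly off that ceiling. It is the default of the experiment runner.

## Few-shot model

The embedding network is a compact CNN: three blocks of
[3×3 conv → batch norm → ReLU → 2×2 max-pool] with (16, 32, 64)
channels, global average pooling, and a linear projection to a 64-d
embedding. The layer library (convolution via im2col, batch norm,
pooling, Adam) is implemented in numpy with hand-written backward
passes, each verified against central finite differences in the test
suite; the explicit backward chain is also what exposes internal feature
maps and their gradients to Grad-CAM. Tie-breaks: max-pool routes the
gradient to the first maximal element of each window; nearest-prototype
classification breaks exact distance ties toward the lowest episode-local
label.

An episode is a 4-way K-shot task: K support and 5 query images per
class, sampled without replacement; episode *i* is a pure function of
(seed, *i*). Class prototypes are arithmetic means of support
embeddings; queries are classified by softmax over negated Euclidean
distances (max-shift stabilized), trained with mean-per-query negative
log-likelihood. Mean (not sum) reduction keeps the loss scale
independent of episode size; the literal summed form is a flag.

Training defaults follow the headline protocol (Adam, lr 1e-4, 50
epochs, 16-episode batches, K ∈ {1, 5, 10}, 5 queries per class, 1000
evaluation episodes). The desk-scale schedule used by the tests and the
acceptance script is lr 1e-3, 10 epochs × 10 episodes, gradient
averaged over 2 episodes per step — about 85 s per seed on one CPU —
with evaluation over 100–300 episodes; the package reports mean ± SD
across episodes and seeds either way. Support-set flip/brightness
augmentation is off for evaluation episodes and optional for training
(the conservative reading; both behaviors are flags). Divergence (NaN
loss) aborts with a diagnostic rather than continuing.

Backbone kinds other than `simple_cnn` (a residual or transformer
encoder) are plug-in hooks: any object with the same
`forward/backward/params` surface can be registered; nothing in this
package downloads weights.

## Zero-shot model

Zero-shot classification is provider-agnostic: an `EmbeddingProvider`
pairs an image encoder and a text encoder into one space. Each class is
the L2-normalized mean of its selected prompt embeddings
(mean-then-normalize; normalization is applied to the final comparison
vectors); prediction is the cosine-similarity argmax, with no parameter
updates anywhere on the path.

Prompt selection: from 20 candidate prompts per class, each candidate is
scored by its mean cosine margin on validation images of its class —
similarity to the candidate's own embedding minus the best competing
class embedding — and the top five are averaged. Competitors during
selection are the classes' default-prompt embeddings (a leave-one-out
variant is a flag); the margin of a candidate is judged against a fixed
reference bank so that candidate order cannot influence its own
competition.

The bundled `SyntheticProvider` emulates a perfectly pre-trained encoder
pair: class anchors are unit vectors at equal pairwise angle (default
60°), images embed near their class anchor with isotropic dispersion,
and a prompt embeds at an angle from its class anchor controlled by a
quality in [0, 1]. It exists so the zero-shot computation and the
selection protocol can be tested with planted ground truth (known prompt
quality order, controllable class overlap); it is labelled synthetic in
its descriptor and is not a trained model.

## Baselines

* **Per-episode fine-tuning**: a fresh linear softmax head trained on
  the episode's 20 support embeddings only (frozen encoder; features are
  standardized on the support set for conditioning — query features use
  the support statistics, so no query leakage). Full joint fine-tuning
  of the backbone per episode exists behind a flag.
* **Visual-prototype zero-shot**: cosine similarity to normalized mean
  support embeddings, no text guidance.

Both baselines use a randomly initialized frozen CNN as the generic
visual feature extractor. No pre-trained weights exist in this stack;
the synthetic anchor provider would be a label oracle and cannot serve
as a fair visual encoder.

## Evaluation statistics

Per episode: accuracy, per-class precision/recall/F1 (0-with-flag on
empty denominators), confusion counts. Aggregate: mean and sample SD
(ddof = 1) over episodes; seeded percentile bootstrap (default 1000
resamples) for the CI; pooled row-normalized confusion matrices (zero
rows stay zero, flagged); macro one-vs-rest AUC via the tie-aware
Mann–Whitney rank statistic (ties count ½; classes absent from the truth
are skipped and flagged). Prototype-network scores for AUC are posterior
probabilities; zero-shot scores are cosine similarities. Cross-seed
reports carry mean ± SD, the maximum deviation, and a consistency flag
(default tolerance 0.02 absolute accuracy).

The bootstrap is validated by simulation: over 1000 replications of 200
episode accuracies drawn from a Beta(8, 2), the 95 % percentile CI
covers the true mean within 95 % ± 2 %, and mean CI width shrinks as
1/√E between 100 and 400 episodes.

## Saliency and localization

`gradcam` computes class-activation maps for the metric classifier. A
prototype classifier has no logit, so the class score is configurable:

* `neg_distance` (API default): −‖z − p_c‖;
* `posterior`: the distance-softmax probability;
* `proto_logit`: z · (p_c − mean of prototypes) — the exact linear
  discriminant of the nearest-prototype rule, since argmin distance ≡
  argmax (z · p_c − ‖p_c‖²/2).

Weighting is either classical channel-averaged Grad-CAM or element-wise
gradient weighting (HiResCAM-style). With a global-average-pooled metric
head the channel-averaged form can cancel to an all-zero map for classes
whose evidence is suppression-coded — measured on trained phantoms it
peaks inside the lesion for only ≈ 0.55 of cases. Quantitative
localization therefore uses the documented `LOCALIZATION_CAM`
configuration — `proto_logit` score, element-wise weighting, first
(highest-resolution) block, σ = 2 px Gaussian smoothing of the
upsampled map — which peaks inside the ground-truth mask for ≥ 0.9 of
correctly classified lesion phantoms while keeping true-class IoU above
wrong-class IoU. Maps are ReLU-rectified, bilinearly upsampled, and
max-normalized to [0, 1]; the IoU threshold defaults to 0.5 of the map
maximum.

UMAP projections of embeddings are reporting plumbing; the silhouette
score by class label quantifies the "partial clustering" such plots are
usually asked to show.

## Splits and leakage

Manifests are CSV (`path,class,patient_id,slice_index,split`). The
three-way partition (`fsl_train` / `fsl_test` / `zsl_eval`) is
class-balanced with largest-remainder rounding, seeded, and — by
default — patient-level: each patient's slices land in exactly one
split, which requires per-class split quotas to be unions of whole
patients (violations name the patient and shortfall). `verify_no_leakage`
cross-tabulates paths and patients against splits and returns every
violation; manifests without patient IDs degrade to slice-level
assignment with a logged warning. The experiment runner additionally
records which items each stage touched and refuses to write a report if
any stage strayed outside its assigned split.

## Known limitations

* The phantom classes are separable by design; absolute accuracies here
  say nothing about clinical MRI, only orderings and contracts do.
* The synthetic embedding provider encodes the true class of a phantom
  by construction; it validates the zero-shot *computation*, not
  vision–language transfer.
* The numpy backbone is desk-scale: single CPU, 96-px inputs, minutes
  of training. It is not a platform for large backbones.
* No significance testing between models is performed; reports carry
  mean ± SD and bootstrap CIs only.
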