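"""Zero-shot classification, prompt margins, selection, visual baseline."""

import numpy as np
import pytest

from protoshot.phantoms import (
    CLASS_NAMES,
    EmbeddingSimSpec,
    PhantomSpec,
    class_anchors,
    generate_dataset,
)
from protoshot.zeroshot import (
    PromptBank,
    SyntheticProvider,
    build_class_embeddings,
    classify_zero_shot,
    cosine_similarity,
    default_prompt_bank,
    prompt_margin,
    select_prompts,
    visual_prototype_zero_shot,
)


@pytest.fixture(scope="module")
def provider():
    return SyntheticProvider(EmbeddingSimSpec(noise_sd=0.2, seed=5))


@pytest.fixture(scope="module")
def phantom_items():
    ds = generate_dataset(PhantomSpec(seed=33), 20)
    return ds, np.array([p.label for p in ds])


# --- cosine --------------------------------------------------------------


def test_cosine_trivial_values():
    v = np.array([1.0, 2.0, 3.0])
    assert cosine_similarity(v, v) == pytest.approx(1.0)
    assert cosine_similarity(v, -v) == pytest.approx(-1.0)
    assert cosine_similarity(np.array([1.0, 0.0]), np.array([0.0, 5.0])) == 0.0


def test_cosine_zero_vector_rejected():
    with pytest.raises(ValueError, match="zero"):
        cosine_similarity(np.zeros(3), np.ones(3))


# --- class embeddings ----------------------------------------------------


def test_single_prompt_class_embedding_is_normalized_embedding(provider):
    bank = PromptBank(
        candidates={c: [f"An MRI showing a {c} tumour." if c != "normal"
                        else "An MRI of a healthy brain."] for c in CLASS_NAMES},
    )
    bank = build_class_embeddings(provider, bank)
    for ci, cls in enumerate(CLASS_NAMES):
        e = provider.text_encode(bank.candidates[cls][0])
        assert np.allclose(bank.class_embeddings[ci], e / np.linalg.norm(e))


def test_class_embedding_matches_mean_then_normalize_oracle(provider):
    prompts = default_prompt_bank()
    bank = build_class_embeddings(provider, prompts)
    for ci, cls in enumerate(CLASS_NAMES):
        embs = np.stack([provider.text_encode(p) for p in prompts.selected[cls]])
        mean = sum(e for e in embs) / len(embs)
        assert np.allclose(bank.class_embeddings[ci], mean / np.linalg.norm(mean),
                           atol=1e-9)


def test_empty_selection_rejected(provider):
    bank = PromptBank(candidates={c: [] for c in CLASS_NAMES})
    with pytest.raises(ValueError, match="no selected prompts"):
        build_class_embeddings(provider, bank)


# --- classification ------------------------------------------------------


def test_anchor_image_classified_with_high_similarity(phantom_items):
    """Noise-free provider: image at class-2 anchor must hit class 2."""
    prov = SyntheticProvider(EmbeddingSimSpec(noise_sd=0.0, seed=5))
    bank = build_class_embeddings(prov, default_prompt_bank())
    ds, _ = phantom_items
    item = next(p for p in ds if p.label == 2)
    pred = classify_zero_shot(prov, bank, item)
    assert pred.predicted == 2
    assert pred.similarities[2] == max(pred.similarities)


def test_tie_broken_to_lowest_class():
    from protoshot.zeroshot import ZeroShotPrediction
    sims = np.array([0.5, 0.9, 0.9, 0.1])
    assert int(sims.argmax()) == 1  # numpy argmax takes first maximum


def test_predictions_match_brute_force_cosine_scan(provider, phantom_items):
    ds, labels = phantom_items
    bank = build_class_embeddings(provider, default_prompt_bank())
    subset = ds[:200] if len(ds) >= 200 else ds
    for item in subset:
        pred = classify_zero_shot(provider, bank, item)
        v = provider.image_encode(item)
        sims = [float(v @ t / (np.linalg.norm(v) * np.linalg.norm(t)))
                for t in bank.class_embeddings]
        assert pred.predicted == int(np.argmax(sims))
        assert np.allclose(pred.similarities, sims, atol=1e-12)


def test_image_scale_invariance(provider, phantom_items):
    """Scaling an image embedding by a positive constant never changes
    the prediction (cosine similarity is scale-free)."""
    ds, _ = phantom_items
    bank = build_class_embeddings(provider, default_prompt_bank())

    class Scaled:
        descriptor = "scaled"
        def image_encode(self, item):
            return 17.3 * provider.image_encode(item)
        def text_encode(self, p):
            return provider.text_encode(p)

    for item in ds[:20]:
        assert (classify_zero_shot(provider, bank, item).predicted
                == classify_zero_shot(Scaled(), bank, item).predicted)


def test_no_parameter_mutation_during_classification(provider, phantom_items):
    ds, _ = phantom_items
    bank = build_class_embeddings(provider, default_prompt_bank())
    before = provider.state_hash()
    for item in ds[:10]:
        classify_zero_shot(provider, bank, item)
    assert provider.state_hash() == before


def test_accuracy_limits_in_noise(phantom_items):
    """noise_sd -> 0 gives perfect zero-shot accuracy; huge noise -> chance."""
    ds, labels = phantom_items
    clean = SyntheticProvider(EmbeddingSimSpec(noise_sd=0.0, seed=5))
    bank = build_class_embeddings(clean, default_prompt_bank())
    preds = [classify_zero_shot(clean, bank, p).predicted for p in ds]
    assert np.mean(np.array(preds) == labels) == 1.0

    noisy = SyntheticProvider(EmbeddingSimSpec(noise_sd=100.0, seed=5))
    bank_n = build_class_embeddings(noisy, default_prompt_bank())
    preds_n = np.array([classify_zero_shot(noisy, bank_n, p).predicted for p in ds])
    acc = np.mean(preds_n == labels)
    assert abs(acc - 0.25) < 0.15  # 80 items, generous sampling band


# --- margins and selection -----------------------------------------------


def test_anchor_prompt_margin_is_one_with_orthogonal_competitors():
    """Prompt at the class anchor, orthogonal anchors, zero noise:
    margin = 1 - 0 = 1."""
    spec = EmbeddingSimSpec(noise_sd=0.0, anchor_separation=np.pi / 2, seed=8)
    table = {f"perfect {c}": (c, 1.0) for c in CLASS_NAMES}
    prov = SyntheticProvider(spec, prompt_table=table)
    ds = generate_dataset(PhantomSpec(seed=4), 8)
    labels = [p.label for p in ds]
    bank = build_class_embeddings(prov, PromptBank(
        candidates={c: [f"perfect {c}"] for c in CLASS_NAMES},
        selected={c: [f"perfect {c}"] for c in CLASS_NAMES},
    ))
    m = prompt_margin(prov, "perfect glioma", "glioma", ds, labels, bank)
    assert m == pytest.approx(1.0, abs=1e-9)


def test_competitor_identical_prompt_margin_nonpositive(provider, phantom_items):
    """A 'glioma' prompt that is actually the meningioma class embedding
    can never beat the meningioma competitor."""
    ds, labels = phantom_items
    table = {"imposter": ("glioma", 1.0)}
    spec = EmbeddingSimSpec(noise_sd=0.1, seed=5)
    prov = SyntheticProvider(spec, prompt_table={"imposter": ("meningioma", 1.0)})
    bank = build_class_embeddings(prov, default_prompt_bank())
    m = prompt_margin(prov, "imposter", "glioma", ds, labels, bank)
    assert m <= 0


def test_margin_ranking_recovers_planted_quality_order(phantom_items):
    """20 candidates with planted quality: empirical margin ranking matches
    the planted ranking (Spearman rho >= 0.9)."""
    from scipy.stats import spearmanr

    ds, labels = phantom_items
    qualities = np.linspace(0.05, 0.95, 20)
    table = {f"glioma candidate {i}": ("glioma", q) for i, q in enumerate(qualities)}
    prov = SyntheticProvider(EmbeddingSimSpec(noise_sd=0.1, seed=6), prompt_table=table)
    bank = build_class_embeddings(prov, default_prompt_bank())
    margins = [
        prompt_margin(prov, f"glioma candidate {i}", "glioma", ds, labels, bank)
        for i in range(20)
    ]
    rho = spearmanr(margins, qualities).statistic
    assert rho >= 0.9


def test_select_prompts_recovers_planted_best(phantom_items):
    ds, labels = phantom_items
    table = {}
    candidates = {}
    rng = np.random.default_rng(0)
    planted_good = {}
    for cls in CLASS_NAMES:
        names = [f"{cls} cand {i}" for i in range(20)]
        good = set(rng.choice(20, size=5, replace=False))
        for i, nm in enumerate(names):
            table[nm] = (cls, 0.9 if i in good else 0.3)
        candidates[cls] = names
        planted_good[cls] = {names[i] for i in good}
    prov = SyntheticProvider(EmbeddingSimSpec(noise_sd=0.05, seed=7), prompt_table=table)
    bank = select_prompts(prov, candidates, ds, labels, top_n=5)
    for cls in CLASS_NAMES:
        assert set(bank.selected[cls]) == planted_good[cls]


def test_select_all_candidates_when_topn_equals_pool(provider, phantom_items):
    ds, labels = phantom_items
    cands = {c: list(default_prompt_bank().candidates[c]) for c in CLASS_NAMES}
    bank = select_prompts(provider, cands, ds, labels, top_n=5)
    for c in CLASS_NAMES:
        assert sorted(bank.selected[c]) == sorted(cands[c])


def test_select_prompts_deterministic(provider, phantom_items):
    ds, labels = phantom_items
    cands = {c: list(default_prompt_bank().candidates[c]) for c in CLASS_NAMES}
    a = select_prompts(provider, cands, ds, labels, top_n=3)
    b = select_prompts(provider, cands, ds, labels, top_n=3)
    assert a.selected == b.selected


def test_too_few_candidates_rejected(provider, phantom_items):
    ds, labels = phantom_items
    with pytest.raises(ValueError, match="candidates"):
        select_prompts(provider, {c: ["one"] for c in CLASS_NAMES}, ds, labels)


# --- visual prototype baseline -------------------------------------------


def test_visual_prototype_identity_support(provider, phantom_items):
    """Support embeddings all equal to u for a class; a test item embedding
    u must land in that class with similarity 1."""
    spec = EmbeddingSimSpec(noise_sd=0.0, seed=5)
    prov = SyntheticProvider(spec)
    ds, labels = phantom_items
    support = sum(([p for p in ds if p.label == c][:5] for c in range(4)), [])
    sup_labels = [p.label for p in support]
    test_items = [p for p in ds if p.label == 1][:3]
    pred, sims = visual_prototype_zero_shot(
        prov.image_encode, support, sup_labels, test_items
    )
    assert np.all(pred == 1)
    assert sims[:, 1] == pytest.approx(1.0, abs=1e-9)


def test_visual_prototype_matches_brute_force(provider, phantom_items):
    ds, labels = phantom_items
    support = sum(([p for p in ds if p.label == c][:5] for c in range(4)), [])
    sup_labels = np.array([p.label for p in support])
    tests = ds[:40]
    pred, sims = visual_prototype_zero_shot(
        provider.image_encode, support, sup_labels, tests
    )
    embs = np.stack([provider.image_encode(p) for p in support])
    protos = np.stack([
        (lambda m: m / np.linalg.norm(m))(embs[sup_labels == c].mean(axis=0))
        for c in range(4)
    ])
    for item, p in zip(tests, pred):
        v = provider.image_encode(item)
        ref = [float(v @ t) / (np.linalg.norm(v) * np.linalg.norm(t)) for t in protos]
        assert p == int(np.argmax(ref))


def test_visual_prototype_missing_class_rejected(provider, phantom_items):
    ds, _ = phantom_items
    support = [p for p in ds if p.label == 0][:5]
    with pytest.raises(ValueError, match="missing"):
        visual_prototype_zero_shot(provider.image_encode, support,
                                   [0] * 5, ds[:2])


# --- bias diagnostic -----------------------------------------------------


def test_prompt_bank_near_centroid_induces_class_bias(phantom_items):
    """A class bank whose prompts sit near the global image centroid
    over-attracts predictions to that class (column-sum diagnostic)."""
    ds, labels = phantom_items
    spec = EmbeddingSimSpec(noise_sd=0.6, seed=9)
    prov = SyntheticProvider(spec)
    # biased bank: class-3 embedding replaced by the mean image direction
    bank = build_class_embeddings(prov, default_prompt_bank())
    imgs = np.stack([prov.image_encode(p) for p in ds])
    centroid = imgs.mean(axis=0)
    biased = bank.class_embeddings.copy()
    biased[3] = centroid / np.linalg.norm(centroid)
    bank.class_embeddings = biased
    preds = np.array([classify_zero_shot(prov, bank, p).predicted for p in ds])
    counts = np.bincount(preds, minlength=4)
    assert counts[3] == counts.max()
    assert counts[3] > len(ds) / 4  # systematic over-prediction of class 3
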