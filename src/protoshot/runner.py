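"""End-to-end experiment orchestration.

Reproduces the full comparison protocol on synthetic phantoms:
generate -> manifest/split (patient-level) -> episodic prototypical-network
training -> K-sweep episodic evaluation -> per-episode fine-tuning
baseline -> prompt-ensemble zero-shot + visual-prototype baseline ->
aggregate reports -> Grad-CAM localization -> UMAP projection ->
comparison table.

Every stage draws its items from an explicit split of the manifest; the
indices each stage touches are recorded in an access audit that is
checked against the split assignment before the report is written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from protoshot.episodes import EpisodeSpec, sample_episode
from protoshot.evaluation import (
    AggregateReport,
    aggregate,
    episode_metrics,
    multi_seed_summary,
    report_to_dict,
)
from protoshot.finetune import FinetuneConfig, finetune_episode
from protoshot.interpretability import (
    LOCALIZATION_CAM,
    gradcam,
    localization_score,
    umap_projection,
)
from protoshot.phantoms import (
    CLASS_NAMES,
    EmbeddingSimSpec,
    PhantomSpec,
    generate_dataset,
)
from protoshot.protonet import (
    BackboneConfig,
    TrainConfig,
    build_backbone,
    compute_prototypes,
    embed,
    evaluate_protonet,
    save_checkpoint,
    train_protonet,
)
from protoshot.splits import SplitConfig, assign_splits, manifest_from_phantoms, verify_no_leakage
from protoshot.zeroshot import (
    SyntheticProvider,
    build_class_embeddings,
    classify_zero_shot,
    default_prompt_bank,
    visual_prototype_zero_shot,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one experiment.

    Desk-scale defaults: 96-px phantoms, 40 slices/class/split, a short
    Adam schedule, 100 evaluation episodes per K in {1, 5, 10}.
    """

    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        lesion_contrast=0.6, noise_sd=0.15))
    n_per_class_per_split: int = 40
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=1e-3, epochs=10, episodes_per_epoch=10, episode_batch=2))
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    embedding_sim: EmbeddingSimSpec = field(default_factory=lambda: EmbeddingSimSpec(
        noise_sd=0.3))
    k_shots: tuple[int, ...] = (1, 5, 10)
    k_shot_train: int = 5
    q_query: int = 5
    n_eval_episodes: int = 100
    n_baseline_episodes: int = 100
    n_gradcam_cases: int = 60
    seeds: tuple[int, ...] = (42,)
    provider: str = "synthetic"
    out_dir: str = "runs/experiment"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("phantom", PhantomSpec), ("backbone", BackboneConfig),
            ("train", TrainConfig), ("finetune", FinetuneConfig),
            ("embedding_sim", EmbeddingSimSpec),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for f_ in ("classes", "channels"):
                    if f_ in sub and isinstance(sub[f_], list):
                        sub[f_] = tuple(sub[f_])
                d[key] = typ(**sub)
        for f_ in ("k_shots", "seeds"):
            if f_ in d and isinstance(d[f_], list):
                d[f_] = tuple(d[f_])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land does not change them
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _phantom_spec_with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    return dataclasses.replace(spec, seed=seed)


def build_pools(cfg: RunConfig, seed: int):
    """Generate the phantom pool, split it patient-level, audit leakage."""
    spec = _phantom_spec_with_seed(cfg.phantom, seed)
    n = cfg.n_per_class_per_split
    phantoms = generate_dataset(spec, 3 * n)
    manifest = manifest_from_phantoms(phantoms)
    split_cfg = SplitConfig(
        counts={"fsl_train": 4 * n, "fsl_test": 4 * n, "zsl_eval": 4 * n},
        seed=seed, patient_level=True,
    )
    manifest = assign_splits(manifest, split_cfg)
    violations = verify_no_leakage(manifest)
    if violations:
        raise StageError("split", RuntimeError(f"leakage: {violations[:3]}"))
    images = np.stack([p.image for p in phantoms])
    labels = np.array([p.label for p in phantoms])
    idx = {s: manifest.index[manifest["split"] == s].to_numpy() for s in
           ("fsl_train", "fsl_test", "zsl_eval")}
    return phantoms, manifest, images, labels, idx


def run_experiment(cfg: RunConfig) -> Path:
    """Run the full comparison; returns the experiment directory.

    Writes: resolved config, manifest, checkpoints, per-model aggregate
    reports (JSON), comparison table (CSV), normalized confusion matrices
    (CSV), Grad-CAM localization scores (CSV), UMAP coordinates, and a
    top-level report.json stamped with the config hash and seeds.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    audit: dict[str, list[str]] = {}
    report: dict = {"config_hash": cfg.config_hash(), "seeds": list(cfg.seeds)}

    per_seed_reports: dict[int, AggregateReport] = {}
    comparison_rows = []
    stage = "generate"
    try:
        for seed in cfg.seeds:
            stage = "generate"
            phantoms, manifest, images, labels, idx = build_pools(cfg, seed)
            if seed == cfg.seeds[0]:
                from protoshot.splits import save_manifest
                save_manifest(manifest, out / "manifest.csv")

            stage = "train-fsl"
            train_cfg = dataclasses.replace(cfg.train, seed=seed)
            ep_train = EpisodeSpec(
                k_shot=cfg.k_shot_train, q_query=cfg.q_query,
                n_episodes=1, seed=seed, augment_support=True,
            )
            model, curve = train_protonet(
                images[idx["fsl_train"]], labels[idx["fsl_train"]],
                ep_train, cfg.backbone, train_cfg,
            )
            audit.setdefault("train-fsl", []).extend(
                manifest.loc[idx["fsl_train"], "path"]
            )
            curve.to_csv(out / f"training_curve_seed{seed}.csv", index=False)
            save_checkpoint(model, cfg.backbone, seed, out / f"checkpoint_seed{seed}.npz")

            stage = "eval-fsl"
            k_reports = {}
            for k in cfg.k_shots:
                ep_eval = EpisodeSpec(
                    k_shot=k, q_query=cfg.q_query,
                    n_episodes=cfg.n_eval_episodes, seed=seed + 1000,
                )
                res = evaluate_protonet(
                    model, images[idx["fsl_test"]], labels[idx["fsl_test"]], ep_eval
                )
                mets = [episode_metrics(r["true"], r["pred"], 4) for r in res]
                scores = np.concatenate([r["probs"] for r in res])
                truth = np.concatenate([r["true"] for r in res])
                k_reports[k] = aggregate(mets, seed=seed, scores=scores,
                                         score_labels=truth)
            audit.setdefault("eval-fsl", []).extend(
                manifest.loc[idx["fsl_test"], "path"]
            )
            per_seed_reports[seed] = k_reports[cfg.k_shot_train]
            if seed == cfg.seeds[0]:
                for k, rep in k_reports.items():
                    comparison_rows.append(
                        {"model": f"protonet_simple_cnn_k{k}", **_row(rep)}
                    )
                    np.savetxt(out / f"confusion_protonet_k{k}.csv",
                               rep.confusion_normalized, delimiter=",")
                report["protonet_by_k"] = {
                    int(k): report_to_dict(r) for k, r in k_reports.items()
                }

        seed0 = cfg.seeds[0]
        phantoms, manifest, images, labels, idx = build_pools(cfg, seed0)
        from protoshot.protonet import load_checkpoint
        model, _, _ = load_checkpoint(out / f"checkpoint_seed{seed0}.npz")

        stage = "eval-baseline"
        fresh = build_backbone(cfg.backbone, seed=seed0 + 7)  # untrained encoder
        z_fresh = embed(fresh, images[idx["fsl_test"]])
        ft_cfg = dataclasses.replace(cfg.finetune, seed=seed0)
        ep_base = EpisodeSpec(k_shot=cfg.k_shot_train, q_query=cfg.q_query,
                              n_episodes=cfg.n_baseline_episodes, seed=seed0 + 2000)
        ft_mets, vp_mets = [], []
        test_labels = labels[idx["fsl_test"]]
        for i in range(ep_base.n_episodes):
            e = sample_episode(test_labels, ep_base, i)
            r = finetune_episode(fresh, images[idx["fsl_test"]], e, ft_cfg,
                                 pool_embeddings=z_fresh)
            ft_mets.append(episode_metrics(r["true"], r["pred"], 4))
            vp_pred, _ = visual_prototype_zero_shot(
                lambda j: z_fresh[j], list(e.support_indices),
                e.support_labels, list(e.query_indices),
            )
            vp_mets.append(episode_metrics(e.query_labels, vp_pred, 4))
        audit.setdefault("eval-baseline", []).extend(
            manifest.loc[idx["fsl_test"], "path"]
        )
        ft_rep, vp_rep = aggregate(ft_mets, seed=seed0), aggregate(vp_mets, seed=seed0)
        comparison_rows.append({"model": "finetune_head_baseline", **_row(ft_rep)})
        comparison_rows.append({"model": "visual_prototype_zsl", **_row(vp_rep)})
        report["finetune_baseline"] = report_to_dict(ft_rep)
        report["visual_prototype_zsl"] = report_to_dict(vp_rep)

        stage = "eval-zeroshot"
        provider = SyntheticProvider(
            dataclasses.replace(cfg.embedding_sim, seed=seed0)
        )
        bank = build_class_embeddings(provider, default_prompt_bank())
        zs_items = [phantoms[i] for i in idx["zsl_eval"]]
        zs_true = np.array([p.label for p in zs_items])
        preds, sims = [], []
        for p in zs_items:
            pr = classify_zero_shot(provider, bank, p)
            preds.append(pr.predicted)
            sims.append(pr.similarities)
        preds, sims = np.array(preds), np.stack(sims)
        audit.setdefault("eval-zeroshot", []).extend(
            manifest.loc[idx["zsl_eval"], "path"]
        )
        zs_met = episode_metrics(zs_true, preds, 4)
        zs_rep = aggregate([zs_met], seed=seed0, scores=sims, score_labels=zs_true)
        pd.DataFrame({
            "path": manifest.loc[idx["zsl_eval"], "path"].to_numpy(),
            "true": zs_true, "predicted": preds,
            **{f"sim_{c}": sims[:, c] for c in range(4)},
        }).to_csv(out / "zeroshot_predictions.csv", index=False)
        comparison_rows.append({"model": "prompt_ensemble_zsl", **_row(zs_rep)})
        report["prompt_ensemble_zsl"] = report_to_dict(zs_rep)
        np.savetxt(out / "confusion_zeroshot.csv", zs_rep.confusion_normalized,
                   delimiter=",")

        stage = "gradcam"
        protos = compute_prototypes(
            embed(model, images[idx["fsl_train"]]), labels[idx["fsl_train"]], 4
        )
        rows = []
        lesion_cases = [phantoms[i] for i in idx["fsl_test"]
                        if phantoms[i].label != 0][: cfg.n_gradcam_cases]
        for p in lesion_cases:
            sm = gradcam(model, p.image, p.label, protos, **LOCALIZATION_CAM)
            sc = localization_score(sm, p.lesion_mask)
            rows.append({
                "path": f"mem://{p.patient_id}/s{p.slice_index}",
                "class": CLASS_NAMES[p.label], "peak_in_mask": sc.peak_in_mask,
                "iou": sc.iou, "centroid_dist": sc.centroid_distance,
            })
        cam_df = pd.DataFrame(rows)
        cam_df.to_csv(out / "gradcam_localization.csv", index=False)
        report["gradcam_peak_in_mask_rate"] = float(cam_df["peak_in_mask"].mean())
        report["gradcam_mean_iou"] = float(cam_df["iou"].mean())

        stage = "report"
        z_test = embed(model, images[idx["fsl_test"]])
        _, sil = umap_projection(z_test, labels[idx["fsl_test"]], seed=seed0,
                                 plot_path=str(out / "umap.png"))
        report["umap_silhouette"] = sil
        if len(cfg.seeds) >= 2:
            report["multi_seed"] = multi_seed_summary(per_seed_reports)

        # split-access audit: every stage stayed inside its assigned split
        split_paths = {s: set(manifest.loc[manifest["split"] == s, "path"])
                       for s in ("fsl_train", "fsl_test", "zsl_eval")}
        expected = {"train-fsl": "fsl_train", "eval-fsl": "fsl_test",
                    "eval-baseline": "fsl_test", "eval-zeroshot": "zsl_eval"}
        audit_ok = {
            st: set(paths) <= split_paths[expected[st]]
            for st, paths in audit.items() if st in expected
        }
        if not all(audit_ok.values()):
            raise RuntimeError(f"split access audit failed: {audit_ok}")
        report["split_access_audit"] = {k: bool(v) for k, v in audit_ok.items()}

        table = pd.DataFrame(comparison_rows)
        table.to_csv(out / "comparison_table.csv", index=False)
        report["comparison_table"] = comparison_rows
        (out / "report.json").write_text(json.dumps(report, indent=2))
    except StageError:
        raise
    except Exception as exc:  # partial outputs stay on disk for debugging
        raise StageError(stage, exc) from exc
    return out


def _row(rep: AggregateReport) -> dict:
    return {
        "accuracy_mean": rep.mean_accuracy,
        "accuracy_sd": rep.sd_accuracy,
        "ci_low": rep.ci_low,
        "ci_high": rep.ci_high,
        "precision": float(np.mean(rep.precision)),
        "recall": float(np.mean(rep.recall)),
        "f1": float(np.mean(rep.f1)),
        "auc": rep.macro_auc,
    }
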