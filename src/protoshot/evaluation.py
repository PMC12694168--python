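"""Episode-level and aggregate evaluation statistics.

Per-episode: accuracy, per-class precision/recall/F1, confusion counts.
Aggregate: mean +- sample SD over episodes, seeded percentile-bootstrap
confidence interval, pooled row-normalized confusion matrix, macro
one-vs-rest AUC, and cross-seed consistency summaries.

Conventions: sample SD uses ddof=1; the bootstrap is the percentile
method over episode accuracies; AUC is the tie-aware Mann-Whitney rank
statistic, macro-averaged over classes present in the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support


@dataclass
class EpisodeMetrics:
    accuracy: float
    precision: np.ndarray          # per class
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray          # counts, rows = true
    zero_division_flags: np.ndarray  # classes whose P or R had a 0 denominator


@dataclass
class AggregateReport:
    mean_accuracy: float
    sd_accuracy: float | None      # None for a single episode (undefined)
    ci_level: float
    ci_low: float | None
    ci_high: float | None
    confusion_normalized: np.ndarray
    zero_rows: np.ndarray          # true classes never observed
    macro_auc: float | None
    n_episodes: int
    precision: np.ndarray | None = None   # episode-averaged per class
    recall: np.ndarray | None = None
    f1: np.ndarray | None = None


def episode_metrics(
    true: Sequence[int], pred: Sequence[int], n_way: int
) -> EpisodeMetrics:
    """Standard multiclass metrics for one episode.

    Precision/recall with an empty denominator are reported as 0 and
    flagged rather than propagating NaN.
    """
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if len(true) != len(pred):
        raise ValueError("label vectors differ in length")
    for v in (true, pred):
        if ((v < 0) | (v >= n_way)).any():
            raise ValueError(f"labels outside 0..{n_way - 1}")
    labels = np.arange(n_way)
    prec, rec, f1, _ = precision_recall_fscore_support(
        true, pred, labels=labels, zero_division=0
    )
    conf = _sk_confusion(true, pred, labels=labels)
    flags = (conf.sum(axis=0) == 0) | (conf.sum(axis=1) == 0)
    return EpisodeMetrics(
        accuracy=float((true == pred).mean()),
        precision=prec, recall=rec, f1=f1, confusion=conf,
        zero_division_flags=flags,
    )


def normalize_confusion(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize (per true class); zero rows stay zero and are flagged.

    Returns (normalized matrix, zero-row flags).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    out = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return out, zero


def macro_auc_ovr(
    scores: np.ndarray, true: Sequence[int]
) -> tuple[float | None, np.ndarray]:
    """Macro one-vs-rest AUC via the tie-aware Mann-Whitney rank statistic.

    ``scores`` is (n_items, n_classes); class c's AUC compares the class-c
    score of class-c items against all others (ties count 0.5). Classes
    absent from the truth (or covering all items) are skipped and flagged.
    Returns (macro AUC or None if no class is scoreable, skip flags).
    """
    scores = np.asarray(scores, dtype=np.float64)
    true = np.asarray(true, dtype=int)
    if scores.ndim != 2 or len(true) != scores.shape[0]:
        raise ValueError("scores must be (n_items, n_classes) matching labels")
    n_classes = scores.shape[1]
    aucs, skipped = [], np.zeros(n_classes, dtype=bool)
    for c in range(n_classes):
        pos = true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            skipped[c] = True
            continue
        ranks = rankdata(scores[:, c])  # average ranks handle ties as 0.5
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    return (float(np.mean(aucs)) if aucs else None), skipped


def bootstrap_ci(
    values: np.ndarray, ci_level: float = 0.95, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 2:
        raise ValueError("need >= 2 values for a bootstrap CI")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 47]))
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot_means = values[idx].mean(axis=1)
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(boot_means, [alpha, 1 - alpha])
    return float(lo), float(hi)


def aggregate(
    metrics: Sequence[EpisodeMetrics],
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    scores: np.ndarray | None = None,
    score_labels: Sequence[int] | None = None,
) -> AggregateReport:
    """Aggregate per-episode metrics.

    Mean and sample SD (ddof=1) of episode accuracy; seeded percentile
    bootstrap over episodes for the CI; pooled row-normalized confusion.
    With a single episode the SD is undefined and the CI skipped. Macro
    AUC is computed from ``scores`` / ``score_labels`` (pooled across
    episodes) when provided.
    """
    if not metrics:
        raise ValueError("no episodes to aggregate")
    accs = np.array([m.accuracy for m in metrics])
    mean = float(accs.mean())
    if len(accs) >= 2:
        sd = float(accs.std(ddof=1))
        ci_low, ci_high = bootstrap_ci(accs, ci_level, n_boot, seed)
    else:
        sd = ci_low = ci_high = None
    pooled = np.sum([m.confusion for m in metrics], axis=0)
    norm, zero_rows = normalize_confusion(pooled)
    auc = None
    if scores is not None and score_labels is not None:
        auc, _ = macro_auc_ovr(scores, score_labels)
    return AggregateReport(
        mean_accuracy=mean, sd_accuracy=sd, ci_level=ci_level,
        ci_low=ci_low, ci_high=ci_high,
        confusion_normalized=norm, zero_rows=zero_rows,
        macro_auc=auc, n_episodes=len(metrics),
        precision=np.mean([m.precision for m in metrics], axis=0),
        recall=np.mean([m.recall for m in metrics], axis=0),
        f1=np.mean([m.f1 for m in metrics], axis=0),
    )


def multi_seed_summary(
    reports: Mapping[int, AggregateReport], tolerance: float = 0.02
) -> dict:
    """Cross-seed mean +- SD of accuracy, max deviation from the mean, and
    a consistency flag (max deviation <= tolerance)."""
    if len(reports) < 2:
        raise ValueError("need reports from >= 2 seeds")
    accs = np.array([r.mean_accuracy for r in reports.values()])
    mean = float(accs.mean())
    max_dev = float(np.abs(accs - mean).max())
    return {
        "per_seed": {int(s): float(r.mean_accuracy) for s, r in reports.items()},
        "mean_accuracy": mean,
        "sd_accuracy": float(accs.std(ddof=1)),
        "max_deviation": max_dev,
        "consistent": bool(max_dev <= tolerance),
        "tolerance": tolerance,
    }


def report_to_dict(report: AggregateReport) -> dict:
    """JSON-ready view of an AggregateReport."""
    return {
        "n_episodes": report.n_episodes,
        "accuracy_mean": report.mean_accuracy,
        "accuracy_sd": report.sd_accuracy,
        "ci_level": report.ci_level,
        "ci_low": report.ci_low,
        "ci_high": report.ci_high,
        "macro_auc": report.macro_auc,
        "precision": None if report.precision is None else report.precision.tolist(),
        "recall": None if report.recall is None else report.recall.tolist(),
        "f1": None if report.f1 is None else report.f1.tolist(),
        "confusion_normalized": report.confusion_normalized.tolist(),
    }


def save_report(report: AggregateReport, path: str | Path, name: str = "model") -> None:
    """Write the aggregate as JSON plus a one-row CSV next to it."""
    import json

    p = Path(path)
    p.write_text(json.dumps({name: report_to_dict(report)}, indent=2))
    row = {
        "model": name,
        "accuracy_mean": report.mean_accuracy,
        "accuracy_sd": report.sd_accuracy,
        "ci_low": report.ci_low,
        "ci_high": report.ci_high,
        "precision": None if report.precision is None else float(np.mean(report.precision)),
        "recall": None if report.recall is None else float(np.mean(report.recall)),
        "f1": None if report.f1 is None else float(np.mean(report.f1)),
        "auc": report.macro_auc,
    }
    pd.DataFrame([row]).to_csv(p.with_suffix(".csv"), index=False)
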