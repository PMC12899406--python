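"""Metrics, interpretability extraction and experiment drivers.

Classification quality is reported as a confusion matrix with accuracy and
macro-averaged precision/recall/F1 (unweighted means of per-class values;
classes absent from the ground truth contribute 0).  Interpretability
summaries aggregate the per-sample attention weights of both branches and
the gate's modality weights, overall and per action.  Experiment drivers
cover the ablation grid (single modality, no action context, concatenation
fusion, full) and the gating-temperature sweep.  The Fisher discriminant
ratio — between-group variance of group means over mean within-group
variance — quantifies class separability of scalar features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .cwt import ScalogramDataset
from .network import AmwfnetModel, GateConfig, ModelConfig, N_CLASSES
from .training import TrainConfig, train_two_stage

__all__ = [
    "EvalReport", "AttentionSummary", "compute_metrics", "extract_attention",
    "ablation_suite", "ABLATION_VARIANTS", "temperature_sweep",
    "fisher_discriminant_ratio", "gate_entropy",
]

ABLATION_VARIANTS = ("semg_only", "kine_only", "no_action", "no_gating", "full")


@dataclass
class EvalReport:
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_recall: np.ndarray
    n: int

    def stratified(self, y_true, y_pred, classes) -> "EvalReport":
        """Sub-report restricted to samples whose true label is in ``classes``."""
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        mask = np.isin(y_true, list(classes))
        return compute_metrics(y_true[mask], y_pred[mask],
                               n_classes=self.confusion.shape[0])

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class_recall": self.per_class_recall.tolist(),
            "n": self.n,
        }


@dataclass
class AttentionSummary:
    emg_overall: np.ndarray          # (8,)
    kine_overall: np.ndarray         # (3,)
    emg_per_action: np.ndarray       # (18, 8), NaN rows for absent actions
    kine_per_action: np.ndarray      # (18, 3)
    gate_overall: np.ndarray | None  # (2,) or None for gateless variants


def compute_metrics(y_true, y_pred, n_classes: int = N_CLASSES) -> EvalReport:
    """Confusion matrix (rows = true) and macro metrics.

    Macro averages divide by ``n_classes``; classes absent from ``y_true``
    contribute 0, keeping small-sample behaviour deterministic.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.arange(n_classes)
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class_recall = np.where(conf.sum(axis=1) > 0,
                                    np.diag(conf) / np.maximum(conf.sum(axis=1), 1),
                                    0.0)
    return EvalReport(
        confusion=conf,
        accuracy=float((y_true == y_pred).mean()),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        per_class_recall=per_class_recall,
        n=int(y_true.size),
    )


def extract_attention(model, ds: ScalogramDataset, batch_size: int = 64
                      ) -> AttentionSummary:
    """Capture and aggregate per-sample attention and gate weights."""
    model.eval()
    alphas_e, alphas_k, gates = [], [], []
    for i in range(0, len(ds), batch_size):
        sl = slice(i, i + batch_size)
        model.forward(ds.X[sl], ds.actions[sl])
        att = model.last_attention
        if "alpha_emg" not in att and "alpha_kine" not in att:
            raise ValueError("model exposes no attention weights")
        if "alpha_emg" in att:
            alphas_e.append(att["alpha_emg"])
        if "alpha_kine" in att:
            alphas_k.append(att["alpha_kine"])
        if "gate" in att:
            gates.append(att["gate"])

    def _aggregate(chunks, n_ch):
        if not chunks:
            return np.full(n_ch, np.nan), np.full((18, n_ch), np.nan)
        A = np.concatenate(chunks)
        per_action = np.full((18, n_ch), np.nan)
        for a in range(1, 19):
            mask = ds.actions == a
            if mask.any():
                per_action[a - 1] = A[mask].mean(axis=0)
        return A.mean(axis=0), per_action

    emg_overall, emg_pa = _aggregate(alphas_e, 8)
    kine_overall, kine_pa = _aggregate(alphas_k, 3)
    gate_overall = np.concatenate(gates).mean(axis=0) if gates else None
    return AttentionSummary(emg_overall, kine_overall, emg_pa, kine_pa, gate_overall)


def _variant_config(variant: str, base: ModelConfig) -> ModelConfig:
    from dataclasses import replace

    if variant == "full":
        return base
    if variant == "semg_only":
        return replace(base, use_kine=False)
    if variant == "kine_only":
        return replace(base, use_emg=False)
    if variant == "no_action":
        return replace(base, use_action=False)
    if variant == "no_gating":
        return replace(base, fusion="concat")
    raise ValueError(f"unknown ablation variant {variant!r}; "
                     f"choose from {ABLATION_VARIANTS}")


def _predict(model, ds: ScalogramDataset, batch_size: int = 64) -> np.ndarray:
    model.eval()
    preds = []
    for i in range(0, len(ds), batch_size):
        sl = slice(i, i + batch_size)
        preds.append(model.forward(ds.X[sl], ds.actions[sl]).argmax(axis=1))
    return np.concatenate(preds)


def ablation_suite(passive, active, test_ds: ScalogramDataset,
                   cfg: TrainConfig | None = None,
                   base_config: ModelConfig | None = None,
                   variants=ABLATION_VARIANTS, seed: int = 0) -> list[dict]:
    """Train and evaluate each architecture variant on the same data.

    Each variant differs from the full model only in the named component.
    Returns one JSON-ready record per variant with metrics on ``test_ds``.
    """
    cfg = cfg or TrainConfig()
    base = base_config or ModelConfig()
    results = []
    for variant in variants:
        model = AmwfnetModel(_variant_config(variant, base), seed=seed)
        train_two_stage(model, passive, active, cfg)
        report = compute_metrics(test_ds.labels, _predict(model, test_ds))
        results.append({
            "variant": variant,
            "seed": seed,
            "accuracy": report.accuracy,
            "macro_f1": report.macro_f1,
            "report": report.to_dict(),
        })
    return results


def gate_entropy(w: np.ndarray) -> float:
    """Shannon entropy (nats) of a modality-weight vector."""
    w = np.asarray(w, dtype=np.float64)
    w = np.clip(w, 1e-12, 1.0)
    return float(-(w * np.log(w)).sum())


def temperature_sweep(passive, active, test_ds: ScalogramDataset,
                      taus, cfg: TrainConfig | None = None,
                      base_config: ModelConfig | None = None,
                      seed: int = 0) -> list[dict]:
    """One run per gating temperature; reports metrics and converged gate weights."""
    from dataclasses import replace

    cfg = cfg or TrainConfig()
    base = base_config or ModelConfig()
    rows = []
    for tau in taus:
        if tau <= 0:
            raise ValueError("temperature values must be positive")
        config = replace(base, gate=GateConfig(
            feature_dim=base.gate.feature_dim,
            hidden_dim=base.gate.hidden_dim, tau=float(tau)))
        model = AmwfnetModel(config, seed=seed)
        train_two_stage(model, passive, active, cfg)
        report = compute_metrics(test_ds.labels, _predict(model, test_ds))
        summary = extract_attention(model, test_ds)
        rows.append({
            "tau": float(tau),
            "seed": seed,
            "accuracy": report.accuracy,
            "macro_f1": report.macro_f1,
            "w_emg": float(summary.gate_overall[0]),
            "w_kine": float(summary.gate_overall[1]),
            "gate_entropy": gate_entropy(summary.gate_overall),
        })
    return rows


def fisher_discriminant_ratio(values, groups) -> float:
    """Between-group variance of group means over mean within-group variance.

    Both terms weight groups by their sample count; within-group variances
    use ddof = 1.  Groups with fewer than 2 samples are rejected; a zero
    within-group variance yields +inf (perfectly separated degenerate case).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    ns, means, variances = [], [], []
    for g in uniq:
        sel = values[groups == g]
        if sel.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        ns.append(sel.size)
        means.append(sel.mean())
        variances.append(sel.var(ddof=1))
    ns = np.array(ns, dtype=float)
    means = np.array(means)
    variances = np.array(variances)
    grand = float(np.sum(ns * means) / ns.sum())
    between = float(np.sum(ns * (means - grand) ** 2) / ns.sum())
    within = float(np.sum(ns * variances) / ns.sum())
    if within == 0.0:
        return float("inf")
    return between / within
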