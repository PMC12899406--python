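"""Subject-wise data handling, augmentation-based class balancing, and the
two-stage training protocol.

Subjects are partitioned 60/20/20 into train/validation/test before any
augmentation, so no individual contributes trials to more than one
partition.  Training-partition class balancing generates synthetic
minority-score trials via amplitude scaling (one factor per modality),
synchronized time warping (a single factor resamples both streams) and
modality-specific Gaussian noise; jerk is never perturbed directly but
recomputed from the augmented velocity chain.

Training runs in two stages: warm-up on robot-guided passive trials
(lr 1e-3), then fine-tuning of the same weights on active voluntary trials
(lr 5e-4), both with AdamW (weight decay 1e-4), batch 32, gradient
clipping at global norm 1.0 and early stopping on validation loss with
patience 10.  Per-epoch history records losses, accuracies and the mean
gate weights for trajectory plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .cwt import ScalogramDataset
from .network import AmwfnetModel
from .preprocess import FilterSpec, smooth_kinematic, _differentiate
from .synthetic import TrialRecord

__all__ = [
    "SplitSpec", "AugmentationConfig", "TrainConfig",
    "subject_split", "apply_split", "assert_no_leakage",
    "augment_trial", "balance_training_set",
    "train_stage", "train_two_stage",
]


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.6
    val: float = 0.2
    test: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("split fractions must be positive")


@dataclass(frozen=True)
class AugmentationConfig:
    amplitude_scale_range: tuple[float, float] = (0.9, 1.1)
    time_warp_range: tuple[float, float] = (0.9, 1.1)
    noise_sigma_emg: float = 0.05
    noise_sigma_kine: float = 0.005


@dataclass(frozen=True)
class TrainConfig:
    stage1_lr: float = 1e-3
    stage1_epochs: int = 100
    stage2_lr: float = 5e-4
    stage2_epochs: int = 100
    weight_decay: float = 1e-4
    batch_size: int = 32
    clip_norm: float = 1.0
    patience: int = 10
    seed: int = 0


def subject_split(manifest: pd.DataFrame, spec: SplitSpec | None = None,
                  stratify: bool = False) -> dict[str, set]:
    """Partition subjects into disjoint train/val/test sets.

    Validation and test sizes are floored, so rounding remainders go to the
    training partition (40 subjects -> 24/8/8).  With ``stratify=True`` the
    split is drawn within each score stratum (requires a ``score`` column),
    guaranteeing — when a stratum has at least 3 subjects — that every
    impairment level is represented in validation and test.
    """
    spec = spec or SplitSpec()
    subjects = sorted(set(manifest["subject_id"]))
    if len(subjects) < 5:
        raise ValueError(f"need at least 5 subjects to split, got {len(subjects)}")
    rng = np.random.default_rng(spec.seed)

    def _partition(group: list, guarantee: bool) -> tuple[set, set, set]:
        order = list(rng.permutation(sorted(group)))
        n = len(order)
        n_val = int(np.floor(spec.val * n))
        n_test = int(np.floor(spec.test * n))
        if guarantee and n >= 3:
            n_val, n_test = max(1, n_val), max(1, n_test)
        return (set(order[:n_test]), set(order[n_test:n_test + n_val]),
                set(order[n_test + n_val:]))

    split = {"train": set(), "val": set(), "test": set()}
    if stratify:
        if "score" not in manifest.columns:
            raise ValueError("stratified split requires a 'score' manifest column")
        by_subject = manifest.drop_duplicates("subject_id")
        for score in sorted(by_subject["score"].unique()):
            group = list(by_subject.loc[by_subject["score"] == score, "subject_id"])
            te, va, tr = _partition(group, guarantee=True)
            split["test"] |= te
            split["val"] |= va
            split["train"] |= tr
    else:
        split["test"], split["val"], split["train"] = _partition(subjects, False)
    assert_no_leakage(split)
    return split


def apply_split(trials: list[TrialRecord], split: dict[str, set]) -> None:
    """Tag each trial with its subject's partition (in place)."""
    lookup = {sid: name for name, sids in split.items() for sid in sids}
    for tr in trials:
        if tr.subject_id not in lookup:
            raise KeyError(f"subject {tr.subject_id} missing from split")
        tr.partition = lookup[tr.subject_id]


def assert_no_leakage(split: dict[str, set]) -> None:
    """Raise if any subject appears in more than one partition."""
    for a in ("train", "val", "test"):
        for b in ("train", "val", "test"):
            if a < b and split[a] & split[b]:
                raise AssertionError(
                    f"subject leakage between {a} and {b}: {split[a] & split[b]}")


def _resample(x: np.ndarray, factor: float) -> np.ndarray:
    """Linear-interpolation time warp to round(T * factor) samples."""
    n = x.shape[-1]
    m = max(3, int(round(n * factor)))
    old = np.linspace(0.0, 1.0, n)
    new = np.linspace(0.0, 1.0, m)
    if x.ndim == 1:
        return np.interp(new, old, x)
    return np.stack([np.interp(new, old, row) for row in x])


def augment_trial(trial: TrialRecord, cfg: AugmentationConfig | None = None,
                  rng: np.random.Generator | None = None, *,
                  warp: float | None = None, scale_emg: float | None = None,
                  scale_kine: float | None = None,
                  filter_spec: FilterSpec | None = None) -> TrialRecord:
    """Return an augmented copy of a training trial.

    One amplitude factor per modality, one shared time-warp factor applied
    synchronously to both streams, then modality-specific Gaussian noise on
    sEMG, velocity and acceleration.  Jerk is recomputed by differentiating
    the augmented (noise-bearing) acceleration — never noise-injected.
    """
    cfg = cfg or AugmentationConfig()
    rng = rng or np.random.default_rng(0)
    if trial.partition != "train":
        raise ValueError(
            f"augmentation is restricted to the training partition "
            f"(trial partition: {trial.partition!r})")

    def _draw(value, lo, hi, name):
        if value is None:
            return float(rng.uniform(lo, hi))
        if not lo <= value <= hi:
            raise ValueError(f"{name}={value} outside configured range [{lo}, {hi}]")
        return float(value)

    warp = _draw(warp, *cfg.time_warp_range, "warp")
    scale_emg = _draw(scale_emg, *cfg.amplitude_scale_range, "scale_emg")
    scale_kine = _draw(scale_kine, *cfg.amplitude_scale_range, "scale_kine")

    out = trial.copy()
    out.emg = scale_emg * _resample(trial.emg, warp)
    out.velocity = scale_kine * _resample(trial.velocity, warp)
    if cfg.noise_sigma_emg > 0:
        out.emg = out.emg + cfg.noise_sigma_emg * rng.standard_normal(out.emg.shape)
    vel = out.velocity
    if cfg.noise_sigma_kine > 0:
        vel = vel + cfg.noise_sigma_kine * rng.standard_normal(vel.shape)
    out.velocity = vel

    # kinematic chain from the augmented velocity; acceleration receives its
    # own sensor-noise term, jerk only inherits it through differentiation
    from .preprocess import KinematicChannels  # local import avoids cycle at import time

    fs = trial.kine_fs
    v_s = smooth_kinematic(vel, fs, filter_spec)
    acc = smooth_kinematic(_differentiate(v_s, fs), fs, filter_spec)
    if cfg.noise_sigma_kine > 0:
        acc = acc + cfg.noise_sigma_kine * rng.standard_normal(acc.shape)
    jerk = smooth_kinematic(_differentiate(acc, fs), fs, filter_spec)
    out.kinematics = KinematicChannels(velocity=v_s, acceleration=acc, jerk=jerk, fs=fs)
    out.augmented = True
    return out


def balance_training_set(trials: list[TrialRecord],
                         cfg: AugmentationConfig | None = None,
                         rng: np.random.Generator | None = None,
                         target: int | None = None) -> list[TrialRecord]:
    """Augment minority scores until per-score counts reach the majority.

    Only training-partition trials may be passed; validation and test data
    stay unaugmented by construction.
    """
    rng = rng or np.random.default_rng(0)
    for tr in trials:
        if tr.partition != "train":
            raise ValueError(
                "balance_training_set received a non-training trial "
                f"(partition {tr.partition!r}); validation/test sets must stay raw")
    by_score: dict[int, list[TrialRecord]] = {}
    for tr in trials:
        by_score.setdefault(tr.score, []).append(tr)
    goal = target if target is not None else max(len(v) for v in by_score.values())
    out = list(trials)
    for score, group in sorted(by_score.items()):
        need = goal - len(group)
        for i in range(need):
            out.append(augment_trial(group[i % len(group)], cfg, rng))
    return out


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _evaluate(model: AmwfnetModel, ds: ScalogramDataset, batch_size: int = 64
              ) -> tuple[float, float]:
    model.eval()
    losses, correct = [], 0
    for i in range(0, len(ds), batch_size):
        sl = slice(i, i + batch_size)
        logits = model.forward(ds.X[sl], ds.actions[sl])
        loss, _ = nn.softmax_cross_entropy(logits, ds.labels[sl])
        losses.append(loss * (min(i + batch_size, len(ds)) - i))
        correct += int((logits.argmax(axis=1) == ds.labels[sl]).sum())
    return float(np.sum(losses) / len(ds)), correct / len(ds)


def train_stage(model: AmwfnetModel, train_ds: ScalogramDataset,
                val_ds: ScalogramDataset, lr: float, epochs: int,
                cfg: TrainConfig, rng: np.random.Generator,
                stop_fn=None) -> list[dict]:
    """One optimization stage with early stopping; restores best-val weights.

    ``stop_fn(record)`` may end the stage early (e.g. when a target
    validation accuracy is reached in a recovery experiment).
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("empty dataset passed to train_stage")
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_loss, best_state, since_best = np.inf, model.state_dict(), 0
    for epoch in range(epochs):
        model.train(True)
        ep_loss, ep_correct, gate_sum, n_batches = 0.0, 0, np.zeros(2), 0
        for idx in _iter_batches(len(train_ds), cfg.batch_size, rng):
            logits = model.forward(train_ds.X[idx], train_ds.actions[idx])
            loss, dlogits = nn.softmax_cross_entropy(logits, train_ds.labels[idx])
            model.zero_grad()
            model.backward(dlogits)
            nn.clip_grad_norm(model.parameters(), cfg.clip_norm)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == train_ds.labels[idx]).sum())
            if "gate" in model.last_attention:
                gate_sum += model.last_attention["gate"].mean(axis=0)
            n_batches += 1
        val_loss, val_acc = _evaluate(model, val_ds)
        record = {
            "epoch": epoch,
            "train_loss": ep_loss / len(train_ds),
            "train_acc": ep_correct / len(train_ds),
            "val_loss": val_loss,
            "val_acc": val_acc,
        }
        if n_batches and gate_sum.any():
            record["w_emg"] = float(gate_sum[0] / n_batches)
            record["w_kine"] = float(gate_sum[1] / n_batches)
        history.append(record)
        if val_loss < best_loss - 1e-6:
            best_loss, best_state, since_best = val_loss, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        if stop_fn is not None and stop_fn(record):
            best_state = model.state_dict()
            break
    model.load_state_dict(best_state)
    return history


def train_two_stage(model: AmwfnetModel,
                    passive: tuple[ScalogramDataset, ScalogramDataset],
                    active: tuple[ScalogramDataset, ScalogramDataset],
                    cfg: TrainConfig | None = None,
                    stop_fn=None) -> dict[str, list[dict]]:
    """Warm-up on passive data, then fine-tune the same weights on active data."""
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    hist1 = train_stage(model, passive[0], passive[1], cfg.stage1_lr,
                        cfg.stage1_epochs, cfg, rng)
    hist2 = train_stage(model, active[0], active[1], cfg.stage2_lr,
                        cfg.stage2_epochs, cfg, rng, stop_fn=stop_fn)
    return {"stage1": hist1, "stage2": hist2}
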