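"""Synthetic cohort generator.

The study protocol records 8-channel surface EMG (1 kHz) and end-effector
speed (500 Hz) while subjects perform 18 robot-guided planar reaching
actions (3 directions x 3 distances x reach/return), each trial labelled
with an FMA-UE elbow sub-score in {0, 1, 2}.  The clinical recordings are
private; this module generates cohorts of :class:`TrialRecord` with the
statistical structure the downstream analysis assumes:

* movement-locked sEMG bursts whose agonist amplitude grows and whose
  antagonist co-activation shrinks with the functional score,
* bell-shaped (minimum-jerk-like) speed profiles whose peak speed grows
  and whose 3-8 Hz tremor ripple shrinks with the score,
* subject-level gain heterogeneity, a passive (robot-guided) and an
  active (voluntary) acquisition stage, and optional class imbalance.

Everything is deterministic given the cohort seed: per-trial random
streams are keyed by (seed, subject, action, trial index, stage) so that
cohorts are extensible without reshuffling, and the score enters only
through deterministic multiplicative effects (``class_effect_size = 0``
switches the class signal off without touching the noise draws).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "MUSCLES",
    "CohortSpec",
    "TrialRecord",
    "enumerate_actions",
    "action_info",
    "simulate_trial",
    "simulate_cohort",
]

#: Electrode sites in channel order: flexor carpi radialis, extensor carpi
#: radialis, flexor carpi ulnaris, brachioradialis, extensor carpi ulnaris,
#: biceps brachii, triceps brachii long head, triceps brachii lateral head.
MUSCLES = ("FCR", "ECR", "FCU", "BR", "ECU", "BB", "TBL", "TBLa")

# channel indices acting as agonists for each movement phase
_FLEXORS = (0, 2, 3, 5)       # FCR, FCU, BR, BB
_EXTENSORS = (1, 4, 6, 7)     # ECR, ECU, TBL, TBLa

# fixed per-muscle balance between fragmented-burst and tonic-spastic
# impairment structure (1 = purely fragmented, 0 = purely tonic); distal
# wrist muscles lean tonic, proximal movers lean fragmented
_FRAG_SUSCEPTIBILITY = (0.35, 0.30, 0.40, 0.75, 0.25, 0.85, 0.80, 0.70)

_DISTANCE_NAMES = ("Near", "Mid", "Far")
_STAGES = ("passive", "active")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``n_subjects_per_group`` counts subjects in each of the two clinical
    groups (stroke-like carrying scores 0/1, healthy-like carrying score 2).
    ``class_effect_size`` scales how strongly the score modulates burst
    amplitude, co-activation, peak speed and tremor; 0 removes the class
    signal entirely.  ``class_counts`` optionally fixes the total number of
    trials per score to emulate clinical class imbalance.
    ``informative_emg_channels`` / ``informative_modalities`` restrict where
    the class signal is planted (used by interpretability-recovery tests).
    """

    n_subjects_per_group: int = 5
    trials_per_action: int = 2
    class_effect_size: float = 1.0
    emg_fs: float = 1000.0
    kine_fs: float = 500.0
    trial_duration: float = 3.0
    class_counts: Mapping[int, int] | None = None
    seed: int = 0
    informative_emg_channels: Sequence[int] | None = None
    informative_modalities: frozenset[str] = frozenset({"emg", "kine"})

    def __post_init__(self) -> None:
        if self.emg_fs <= 2 * 450.0:
            raise ValueError("emg_fs must exceed 900 Hz (2 x 450 Hz band edge)")
        if self.kine_fs <= 2 * 50.0:
            raise ValueError("kine_fs must exceed 100 Hz (2 x 50 Hz band edge)")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.trials_per_action < 1:
            raise ValueError("trials_per_action must be >= 1")


@dataclass
class TrialRecord:
    """One segmented movement trial with its metadata.

    ``emg`` is an (8, T_e) array in arbitrary mV-scale units at ``emg_fs``;
    ``velocity`` is a length-T_k speed trace at ``kine_fs``.  ``kinematics``
    (velocity/acceleration/jerk after conditioning) is attached by the
    preprocessing step; ``partition`` by the subject-wise split.
    """

    subject_id: str
    action_id: int
    parity: int
    score: int
    emg: np.ndarray
    velocity: np.ndarray
    stage: str = "active"
    emg_fs: float = 1000.0
    kine_fs: float = 500.0
    trial_index: int = 0
    kinematics: object | None = None
    partition: str | None = None
    augmented: bool = False

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.emg.ndim != 2 or self.emg.shape[0] != 8:
            raise ValueError(f"emg must have exactly 8 rows, got {self.emg.shape}")
        if not 1 <= self.action_id <= 18:
            raise ValueError(f"action_id must be in 1..18, got {self.action_id}")
        if self.parity != (1 - self.action_id % 2):
            raise ValueError("parity must be 0 for odd action IDs, 1 for even")
        if self.score not in (0, 1, 2):
            raise ValueError(f"score must be in {{0,1,2}}, got {self.score}")
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}")

    def copy(self) -> "TrialRecord":
        out = replace(self)
        out.emg = self.emg.copy()
        out.velocity = self.velocity.copy()
        return out


def enumerate_actions() -> list[tuple[int, float, str, int]]:
    """Enumerate the 18-action grid as (action_id, direction_deg, distance, parity).

    Direction-major, distance-minor indexing: IDs 1-6 are the 45 deg
    direction, 7-12 are 90 deg, 13-18 are 135 deg.  Within a direction,
    targets run Near -> Mid -> Far; the odd ID of each pair is the
    reach-out (extension, parity 0) phase and the even ID the return
    (flexion, parity 1) phase.
    """
    grid = []
    for action_id in range(1, 19):
        direction = 45.0 * ((action_id - 1) // 6 + 1)
        distance = _DISTANCE_NAMES[((action_id - 1) % 6) // 2]
        parity = 1 - action_id % 2
        grid.append((action_id, direction, distance, parity))
    return grid


def action_info(action_id: int) -> tuple[float, int, int]:
    """Return (direction_deg, distance_level 1..3, parity) for one action ID."""
    if not 1 <= int(action_id) <= 18:
        raise ValueError(f"action_id must be in 1..18, got {action_id}")
    action_id = int(action_id)
    direction = 45.0 * ((action_id - 1) // 6 + 1)
    distance_level = ((action_id - 1) % 6) // 2 + 1
    parity = 1 - action_id % 2
    return direction, distance_level, parity


def _subject_key(subject_id: str) -> int:
    return zlib.crc32(str(subject_id).encode("utf8"))


def _trial_rng(spec: CohortSpec, subject_id: str, action_id: int,
               trial_index: int, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [int(spec.seed), _subject_key(subject_id), int(action_id),
         int(trial_index), _STAGES.index(stage)]
    )
    return np.random.default_rng(ss)


def _subject_rng(spec: CohortSpec, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), _subject_key(subject_id), 10_007])
    )


def _minimum_jerk_bump(u: np.ndarray) -> np.ndarray:
    """Bell-shaped speed profile on [0, 1], peak 1 at u = 0.5 (zero outside)."""
    b = 16.0 * u**2 * (1.0 - u) ** 2
    return np.where((u >= 0) & (u <= 1), b, 0.0)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: tuple[float, float] = (25.0, 440.0)) -> np.ndarray:
    """Unit-variance noise confined to ``band`` (default safely inside 20-450)."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / (np.std(y) + 1e-12)


def _parity_skew(u: np.ndarray, parity: int) -> np.ndarray:
    """Skew the normalized movement time axis by motion phase.

    Reaching out (parity 0) accelerates quickly and decelerates into the
    target (speed peak early); the return (parity 1) is more ballistic
    (peak late).  The skew applies identically to every channel, so the
    phase is readable from any single scalogram.
    """
    g = 0.75 if parity == 0 else 1.3
    inside = (u >= 0) & (u <= 1)
    return np.where(inside, np.clip(u, 0.0, 1.0) ** g, u)


def _fragmented_profile(u: np.ndarray, centers: np.ndarray,
                        widths: np.ndarray, amps: np.ndarray) -> np.ndarray:
    """Sum of sub-movement bumps (movement decomposition), peak-normalized."""
    prof = np.zeros_like(u)
    for c, w, a in zip(centers, widths, amps):
        prof += a * _minimum_jerk_bump((u - c) / w + 0.5)
    m = prof.max()
    return prof / m if m > 0 else prof


def simulate_trial(spec: CohortSpec, subject_id: str, action_id: int, score: int,
                   trial_index: int = 0, stage: str = "active") -> TrialRecord:
    """Simulate one trial for (subject, action, score).

    Deterministic given (spec.seed, subject_id, action_id, trial_index,
    stage).  The score modulates, scaled by ``spec.class_effect_size``:
    agonist burst amplitude (up with score), antagonist co-activation
    (down with score), peak speed (up) and tremor-band ripple (down).
    During the passive stage the robot guides the arm: kinematics are
    near-normative and voluntary sEMG is strongly reduced.
    """
    if score not in (0, 1, 2):
        raise ValueError(f"score must be in {{0,1,2}}, got {score}")
    direction, distance_level, parity = action_info(action_id)
    if stage not in _STAGES:
        raise ValueError(f"stage must be one of {_STAGES}")

    rng = _trial_rng(spec, subject_id, action_id, trial_index, stage)
    srng = _subject_rng(spec, subject_id)
    subj_gain_e = np.exp(0.15 * srng.standard_normal())
    subj_gain_k = np.exp(0.10 * srng.standard_normal())

    effect = float(spec.class_effect_size)
    passive = stage == "passive"
    # Robot guidance normalizes kinematics almost completely, but spastic
    # co-activation and altered muscle state remain visible in passively
    # moved limbs, so the sEMG class signal is only partially suppressed.
    emg_stage = 0.6 if passive else 1.0
    kine_stage = 0.1 if passive else 1.0

    emg_on = "emg" in spec.informative_modalities
    kine_on = "kine" in spec.informative_modalities

    # class-effect saturation: score-specific asymptotes keep the three
    # scores separated at any effect size; zero effect switches them off
    sat = 1.0 - np.exp(-effect)

    T_e = int(round(spec.trial_duration * spec.emg_fs))
    T_k = int(round(spec.trial_duration * spec.kine_fs))

    # ---- kinematics: minimum-jerk-like speed bump + tremor + sensor noise
    k_sat = sat * kine_stage if kine_on else 0.0
    t_k = np.arange(T_k) / spec.kine_fs
    move_start = 0.12 * spec.trial_duration
    # impaired movements take longer (movement-time prolongation)
    move_dur = spec.trial_duration * 0.42 * (0.75 + 0.15 * distance_level) \
        * (1.0 + (0.5, 0.25, 0.0)[score] * k_sat)
    move_dur = min(move_dur, 0.85 * spec.trial_duration)
    u_k = _parity_skew((t_k - move_start) / move_dur, parity)
    base_speed = 0.30 * (0.6 + 0.2 * distance_level)
    peak_speed = base_speed * subj_gain_k * (1.0 + 0.35 * (score - 1) * k_sat)
    bump = _minimum_jerk_bump(u_k)

    # movement decomposition: impaired reaches fragment into sub-movements
    # (drawn unconditionally so the noise stream is score-independent)
    centers = np.array([0.22, 0.52, 0.80]) + 0.03 * rng.standard_normal(3)
    widths = np.array([0.38, 0.34, 0.30]) * np.exp(0.10 * rng.standard_normal(3))
    sub_amps = rng.uniform(0.7, 1.0, 3)
    frag_k = _fragmented_profile(u_k, centers, widths, sub_amps)
    lam_k = (0.9, 0.45, 0.0)[score] * k_sat
    shape_k = (1.0 - lam_k) * bump + lam_k * frag_k
    velocity = peak_speed * shape_k

    tremor_freq = rng.uniform(3.0, 8.0)
    tremor_phase = rng.uniform(0, 2 * np.pi)
    tremor_amp = 0.12 * base_speed * (0.25 + (2.6, 1.2, 0.0)[score] * k_sat)
    velocity = velocity + tremor_amp * shape_k * np.sin(
        2 * np.pi * tremor_freq * t_k + tremor_phase
    )
    velocity = velocity + 0.004 * base_speed * rng.standard_normal(T_k)

    # ---- sEMG: band-limited carriers x movement-locked envelopes
    t_e = np.arange(T_e) / spec.emg_fs
    u_e = _parity_skew((t_e - move_start) / move_dur, parity)
    env_bump = _minimum_jerk_bump(u_e)

    agonists = _FLEXORS if parity == 1 else _EXTENSORS
    e_sat_all = sat * emg_stage if emg_on else 0.0
    drive = 0.35 if passive else 1.0
    frag_e = _fragmented_profile(u_e, centers, widths, sub_amps)
    plateau = np.clip(3.0 * env_bump, 0.0, 1.0)  # tonic window for spasticity

    # Which muscle is agonist swaps with the movement phase and shows up as a
    # co-activation amplitude ratio; the *structural* impairment signatures
    # (burst fragmentation vs tonic spastic activity, spectral slowing) sit
    # on fixed per-muscle susceptibilities, distal muscles being the more
    # spasticity-prone.  Score level controls their strength.
    lam_score = (0.9, 0.45, 0.0)[score]
    tonic_score = (0.85, 0.45, 0.0)[score]
    beta_score = (0.85, 0.45, 0.0)[score]

    emg = np.empty((8, T_e))
    for ch in range(8):
        if spec.informative_emg_channels is None:
            e_sat = e_sat_all
        else:
            e_sat = e_sat_all if ch in spec.informative_emg_channels else 0.0
        is_agonist = ch in agonists
        if is_agonist:
            amp = 0.9 * (1.0 + 0.40 * (score - 1) * e_sat)
        else:
            amp = 0.40 * (1.0 + (1.2, 0.6, 0.0)[score] * e_sat)
        w_frag = _FRAG_SUSCEPTIBILITY[ch]
        lam_e = lam_score * e_sat * w_frag
        tonic = tonic_score * e_sat * (1.0 - w_frag)
        env_shape = (1.0 - lam_e - tonic) * env_bump + lam_e * frag_e \
            + tonic * plateau
        # mild task dependence so the action context carries information
        amp *= 1.0 + 0.10 * np.cos(direction / 45.0 + 0.7 * ch) \
            + 0.05 * (distance_level - 2)
        amp *= drive * subj_gain_e * np.exp(0.05 * rng.standard_normal())
        # impairment tilts the carrier spectrum toward low frequencies
        beta = beta_score * e_sat
        broad = _bandlimited_noise(rng, T_e, spec.emg_fs)
        low = _bandlimited_noise(rng, T_e, spec.emg_fs, band=(25.0, 120.0))
        carrier = np.sqrt(max(1.0 - beta**2, 0.0)) * broad + beta * low
        envelope = 0.08 + amp * env_shape
        emg[ch] = envelope * carrier  # unit-scale amplitude convention

    return TrialRecord(
        subject_id=subject_id, action_id=action_id, parity=parity, score=score,
        emg=emg, velocity=velocity, stage=stage,
        emg_fs=spec.emg_fs, kine_fs=spec.kine_fs, trial_index=trial_index,
    )


def _cohort_subjects(spec: CohortSpec) -> list[tuple[str, int]]:
    """(subject_id, score) pairs: stroke-like carry scores 0/1 (2:3 ratio),
    healthy-like carry score 2."""
    n = spec.n_subjects_per_group
    n_severe = max(1, int(round(0.4 * n))) if n > 1 else 1
    subjects = []
    for i in range(n):
        score = 0 if i < n_severe else 1
        subjects.append((f"S{i + 1:02d}", score))
    for i in range(n):
        subjects.append((f"H{i + 1:02d}", 2))
    return subjects


def simulate_cohort(spec: CohortSpec) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Simulate a full cohort; returns (trials, manifest).

    Every subject contributes passive- and active-stage trials across all
    18 actions.  With ``class_counts`` set, the per-score trial totals are
    distributed as evenly as possible over that score's
    (subject, action, stage) slots; a count that cannot give every slot at
    least the actions grid once per stage is rejected as infeasible.
    """
    subjects = _cohort_subjects(spec)
    per_score_subjects: dict[int, list[str]] = {0: [], 1: [], 2: []}
    for sid, sc in subjects:
        per_score_subjects[sc].append(sid)

    # trials per (subject, action, stage) slot, per score
    slot_counts: dict[int, list[int]] = {}
    for score in (0, 1, 2):
        n_slots = len(per_score_subjects[score]) * 18 * 2
        if spec.class_counts is None:
            slot_counts[score] = [spec.trials_per_action] * n_slots
        else:
            total = int(spec.class_counts.get(score, 0))
            if n_slots == 0 and total > 0:
                raise ValueError(f"class_counts[{score}] > 0 but no subject carries score {score}")
            if total < n_slots:
                raise ValueError(
                    f"class_counts[{score}]={total} infeasible: needs >= one trial "
                    f"per (subject, action, stage) slot ({n_slots})"
                )
            q, r = divmod(total, n_slots)
            slot_counts[score] = [q + (1 if i < r else 0) for i in range(n_slots)]

    trials: list[TrialRecord] = []
    rows = []
    for score in (0, 1, 2):
        slot = 0
        for sid in per_score_subjects[score]:
            for action_id in range(1, 19):
                for stage in _STAGES:
                    for trial_index in range(slot_counts[score][slot]):
                        tr = simulate_trial(spec, sid, action_id, score,
                                            trial_index=trial_index, stage=stage)
                        trials.append(tr)
                        rows.append({
                            "trial_id": len(trials) - 1,
                            "subject_id": sid,
                            "action_id": action_id,
                            "parity": tr.parity,
                            "score": score,
                            "stage": stage,
                            "trial_index": trial_index,
                        })
                    slot += 1
    manifest = pd.DataFrame(rows)
    return trials, manifest
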