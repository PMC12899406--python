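"""Signal conditioning and label encoding.

sEMG passes a zero-phase cascade of a 50 Hz notch (second-order, Q = 30)
followed by a fourth-order 20-450 Hz Butterworth band-pass.  The recorded
speed trace is numerically differentiated into acceleration and jerk, with
each kinematic channel smoothed by a zero-phase fourth-order 20 Hz
Butterworth low-pass plus a 15 ms Gaussian-weighted moving average.
Labels combine the FMA-UE elbow sub-score s in {0,1,2} with the movement
parity p in {0 extension, 1 flexion} as y = 2s + p.

Zero-phase filtering is realized by forward-backward application with
reflection ("even") padding; differentiation uses central differences with
one-sided differences at the boundaries.  All stages preserve length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, ndimage

from .synthetic import TrialRecord

__all__ = [
    "FilterSpec",
    "KinematicChannels",
    "filter_emg",
    "smooth_kinematic",
    "derive_kinematics",
    "encode_label",
    "decode_label",
    "preprocess_trial",
    "segment_and_label",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    notch_freq: float = 50.0
    notch_q: float = 30.0
    bandpass: tuple[float, float] = (20.0, 450.0)
    bandpass_order: int = 4
    kine_lowpass: float = 20.0
    kine_lowpass_order: int = 4
    gaussian_window: float = 0.015  # seconds

    def validate(self, emg_fs: float | None = None, kine_fs: float | None = None) -> None:
        if emg_fs is not None:
            if self.bandpass[1] >= emg_fs / 2:
                raise ValueError(
                    f"band-pass edge {self.bandpass[1]} Hz >= Nyquist of fs={emg_fs}"
                )
            if self.notch_freq >= emg_fs / 2:
                raise ValueError("notch frequency above Nyquist")
        if kine_fs is not None and self.kine_lowpass >= kine_fs / 2:
            raise ValueError("kinematic low-pass cutoff above Nyquist")
        if not 0 < self.bandpass[0] < self.bandpass[1]:
            raise ValueError("band edges must satisfy 0 < low < high")


@dataclass
class KinematicChannels:
    """Velocity, acceleration and jerk at the kinematic sampling rate."""

    velocity: np.ndarray
    acceleration: np.ndarray
    jerk: np.ndarray
    fs: float = 500.0

    def stack(self) -> np.ndarray:
        return np.stack([self.velocity, self.acceleration, self.jerk])


def _pad_length(n: int, fs: float, edge_freq: float, cycles: float) -> int:
    """Reflection-pad length covering the filter's ring-down, capped at T-1.

    ``cycles`` periods of the critical frequency: ~10 suffices for the
    Butterworth stages; the notch rings for ~2Q cycles.
    """
    return int(min(n - 1, max(9, round(cycles * fs / edge_freq))))


def filter_emg(emg: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase notch + band-pass cascade on an (8, T) sEMG array."""
    spec = spec or FilterSpec()
    spec.validate(emg_fs=fs)
    emg = np.asarray(emg, dtype=np.float64)
    if emg.ndim != 2 or emg.shape[0] != 8:
        raise ValueError(f"expected (8, T) sEMG array, got {emg.shape}")
    n = emg.shape[-1]
    b_n, a_n = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    out = signal.filtfilt(
        b_n, a_n, emg, axis=-1, padtype="even",
        padlen=_pad_length(n, fs, spec.notch_freq, cycles=2 * spec.notch_q))
    sos = signal.butter(spec.bandpass_order, spec.bandpass, btype="bandpass",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(
        sos, out, axis=-1, padtype="even",
        padlen=_pad_length(n, fs, spec.bandpass[0], cycles=10))


def _gaussian_kernel(fs: float, window_s: float) -> np.ndarray:
    # odd-length window spanning ~window_s seconds, sigma = span/6, unit sum
    n = max(3, int(round(window_s * fs)))
    if n % 2 == 0:
        n += 1
    w = signal.windows.gaussian(n, std=n / 6.0)
    return w / w.sum()


def smooth_kinematic(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Two-stage smoothing: zero-phase 20 Hz low-pass then 15 ms Gaussian average."""
    spec = spec or FilterSpec()
    spec.validate(kine_fs=fs)
    sos = signal.butter(spec.kine_lowpass_order, spec.kine_lowpass,
                        btype="lowpass", fs=fs, output="sos")
    x = np.asarray(x, dtype=np.float64)
    padlen = _pad_length(x.shape[-1], fs, spec.kine_lowpass, cycles=10)
    y = signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)
    kern = _gaussian_kernel(fs, spec.gaussian_window)
    return ndimage.convolve1d(y, kern, mode="reflect")


def _differentiate(x: np.ndarray, fs: float) -> np.ndarray:
    # central differences in the interior, one-sided at the boundaries
    return np.gradient(x, 1.0 / fs, edge_order=1)


def derive_kinematics(velocity: np.ndarray, fs: float,
                      spec: FilterSpec | None = None) -> KinematicChannels:
    """Differentiate speed into acceleration and jerk with smoothing.

    Each channel is smoothed before the next differentiation, so jerk is
    the derivative of the smoothed acceleration — the cascade keeps
    higher-order derivatives from amplifying quantization noise.
    """
    velocity = np.asarray(velocity, dtype=np.float64)
    if velocity.ndim != 1:
        raise ValueError("velocity must be a 1-D vector")
    if velocity.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    v = smooth_kinematic(velocity, fs, spec)
    a = smooth_kinematic(_differentiate(v, fs), fs, spec)
    j = smooth_kinematic(_differentiate(a, fs), fs, spec)
    return KinematicChannels(velocity=v, acceleration=a, jerk=j, fs=fs)


def encode_label(s: int, p: int) -> int:
    """Parity label code y = 2s + p (bijection {0,1,2} x {0,1} -> {0..5})."""
    if s not in (0, 1, 2):
        raise ValueError(f"score must be in {{0,1,2}}, got {s}")
    if p not in (0, 1):
        raise ValueError(f"parity must be in {{0,1}}, got {p}")
    return 2 * s + p


def decode_label(y: int) -> tuple[int, int]:
    """Inverse of :func:`encode_label`."""
    if y not in range(6):
        raise ValueError(f"label must be in 0..5, got {y}")
    return y // 2, y % 2


def preprocess_trial(trial: TrialRecord, spec: FilterSpec | None = None) -> TrialRecord:
    """Filter the sEMG and attach derived kinematic channels to a copy."""
    out = trial.copy()
    out.emg = filter_emg(trial.emg, trial.emg_fs, spec)
    out.kinematics = derive_kinematics(trial.velocity, trial.kine_fs, spec)
    return out


def segment_and_label(streams: dict, manifest, *, emg_fs: float = 1000.0,
                      kine_fs: float = 500.0, min_duration: float = 0.25,
                      ) -> list[TrialRecord]:
    """Cut continuous per-(subject, stage) streams into labelled trials.

    ``streams`` maps ``(subject_id, stage)`` to ``{"emg": (8, T_e) array,
    "velocity": (T_k,) array}``.  ``manifest`` rows need subject_id, stage,
    action_id, score and start/end times in seconds.  Segments shorter than
    ``min_duration`` are dropped and logged; overlapping segments within a
    stream are rejected.
    """
    rows = manifest.to_dict("records") if hasattr(manifest, "to_dict") else list(manifest)

    by_stream: dict[tuple, list[dict]] = {}
    for row in rows:
        by_stream.setdefault((row["subject_id"], row["stage"]), []).append(row)

    trials: list[TrialRecord] = []
    for key, seg_rows in by_stream.items():
        if key not in streams:
            raise KeyError(f"no stream for {key}")
        emg = np.asarray(streams[key]["emg"])
        vel = np.asarray(streams[key]["velocity"])
        seg_rows = sorted(seg_rows, key=lambda r: float(r["start"]))
        prev_end = -np.inf
        for row in seg_rows:
            start, end = float(row["start"]), float(row["end"])
            if start < prev_end:
                raise ValueError(f"overlapping segments in stream {key} at t={start}")
            prev_end = end
            if end > emg.shape[1] / emg_fs + 1e-9 or end > vel.size / kine_fs + 1e-9 or start < 0:
                raise ValueError(f"segment [{start}, {end}] outside stream bounds for {key}")
            if end - start < min_duration:
                logger.warning(
                    "dropping segment %s action %s [%0.3f, %0.3f]: below %.3f s minimum",
                    key, row["action_id"], start, end, min_duration,
                )
                continue
            i0, i1 = int(round(start * emg_fs)), int(round(end * emg_fs))
            k0, k1 = int(round(start * kine_fs)), int(round(end * kine_fs))
            trials.append(TrialRecord(
                subject_id=row["subject_id"],
                action_id=int(row["action_id"]),
                parity=1 - int(row["action_id"]) % 2,
                score=int(row["score"]),
                emg=emg[:, i0:i1],
                velocity=vel[k0:k1],
                stage=row["stage"],
                emg_fs=emg_fs, kine_fs=kine_fs,
                trial_index=int(row.get("trial_index", 0)),
            ))
    return trials
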