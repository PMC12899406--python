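"""Continuous-wavelet scalogram construction.

Each preprocessed 1-D channel is transformed with a complex Morlet wavelet
(center frequency omega0 = 6) at scales covering a modality-specific band
(20-450 Hz for sEMG, 0.5-50 Hz for kinematics), then standardized through
the fixed pipeline: power |W|^2 -> log1p -> bilinear resize -> per-plane
min-max normalization to [0, 1].  A trial yields an 11-plane tensor: the
8 muscle scalograms followed by velocity, acceleration and jerk.

Scale-to-frequency mapping uses the Morlet center-frequency relation
f = omega0 * fs / (2 pi a); scales are log-spaced in frequency by default.
Row 0 of every scalogram is the lowest frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from skimage.transform import resize as _sk_resize

from .preprocess import FilterSpec, encode_label, preprocess_trial
from .synthetic import MUSCLES, TrialRecord

__all__ = [
    "MORLET_OMEGA0",
    "CwtSpec",
    "ScalogramTensor",
    "ScalogramDataset",
    "cwt_frequencies",
    "cwt_power",
    "standardize_scalogram",
    "trial_to_tensor",
    "build_dataset",
]

MORLET_OMEGA0 = 6.0
# PyWavelets parametrization: cmorB-C with psi(t) ~ exp(2 pi i C t) exp(-t^2/B);
# the classical Morlet exp(i omega0 t) exp(-t^2/2) is B=2, C=omega0/(2 pi).
_MORLET_CENTER = MORLET_OMEGA0 / (2.0 * np.pi)
_WAVELET = f"cmor2.0-{_MORLET_CENTER!r}"

CHANNEL_NAMES = tuple(MUSCLES) + ("velocity", "acceleration", "jerk")


@dataclass(frozen=True)
class CwtSpec:
    n_scales: int = 128
    emg_band: tuple[float, float] = (20.0, 450.0)
    kine_band: tuple[float, float] = (0.5, 50.0)
    out_size: tuple[int, int] = (128, 128)
    scale_spacing: str = "log"

    def __post_init__(self) -> None:
        for band in (self.emg_band, self.kine_band):
            if not 0 < band[0] < band[1]:
                raise ValueError(f"band edges must satisfy 0 < low < high, got {band}")
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.scale_spacing not in ("log", "linear"):
            raise ValueError("scale_spacing must be 'log' or 'linear'")


@dataclass
class ScalogramTensor:
    """The (11, H, W) normalized time-frequency stack for one trial."""

    data: np.ndarray
    label: int
    action_id: int
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != 11:
            raise ValueError(f"expected 11 planes, got {self.data.shape}")


@dataclass
class ScalogramDataset:
    """Stacked tensors ready for the network: X (N,11,H,W), actions, labels."""

    X: np.ndarray
    actions: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray

    def __len__(self) -> int:
        return self.X.shape[0]


def cwt_frequencies(band: tuple[float, float], n_scales: int,
                    spacing: str = "log") -> np.ndarray:
    """Nominal scale frequencies, ascending (row order of the scalograms)."""
    if spacing == "log":
        return np.geomspace(band[0], band[1], n_scales)
    return np.linspace(band[0], band[1], n_scales)


def cwt_power(x: np.ndarray, fs: float, band: tuple[float, float],
              n_scales: int = 128, spacing: str = "log") -> np.ndarray:
    """Complex-Morlet CWT power |W(a, b)|^2, rows ordered low -> high frequency."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if band[1] >= fs / 2:
        raise ValueError(f"band upper edge {band[1]} Hz exceeds Nyquist of fs={fs}")
    freqs = cwt_frequencies(band, n_scales, spacing)
    scales = _MORLET_CENTER * fs / freqs
    coef, _ = pywt.cwt(x, scales, _WAVELET, sampling_period=1.0 / fs, method="fft")
    return np.abs(coef) ** 2


def standardize_scalogram(power: np.ndarray, out_size: tuple[int, int] = (128, 128)
                          ) -> np.ndarray:
    """log1p -> bilinear resize -> per-plane min-max to [0, 1].

    A constant power matrix (degenerate min-max) maps to all zeros.
    """
    power = np.asarray(power, dtype=np.float64)
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    img = np.log1p(power)
    if img.shape != tuple(out_size):
        img = _sk_resize(img, out_size, order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        return np.zeros(out_size)
    return (img - lo) / (hi - lo)


def trial_to_tensor(trial: TrialRecord, spec: CwtSpec | None = None) -> ScalogramTensor:
    """Build the 11-plane scalogram tensor from a preprocessed trial."""
    spec = spec or CwtSpec()
    if trial.kinematics is None:
        raise ValueError("trial must be preprocessed (kinematics attached) "
                         "before scalogram conversion")
    planes = np.empty((11,) + tuple(spec.out_size), dtype=np.float32)
    for ch in range(8):
        p = cwt_power(trial.emg[ch], trial.emg_fs, spec.emg_band,
                      spec.n_scales, spec.scale_spacing)
        planes[ch] = standardize_scalogram(p, spec.out_size)
    for i, x in enumerate(trial.kinematics.stack()):
        p = cwt_power(x, trial.kine_fs, spec.kine_band,
                      spec.n_scales, spec.scale_spacing)
        planes[8 + i] = standardize_scalogram(p, spec.out_size)
    return ScalogramTensor(
        data=planes,
        label=encode_label(trial.score, trial.parity),
        action_id=trial.action_id,
        subject_id=trial.subject_id,
    )


def build_dataset(trials, spec: CwtSpec | None = None,
                  filter_spec: FilterSpec | None = None,
                  preprocess: bool = True) -> ScalogramDataset:
    """Preprocess + transform a list of trials into a stacked dataset."""
    spec = spec or CwtSpec()
    tensors = []
    for tr in trials:
        if preprocess or tr.kinematics is None:
            tr = preprocess_trial(tr, filter_spec)
        tensors.append(trial_to_tensor(tr, spec))
    X = np.stack([t.data for t in tensors])
    return ScalogramDataset(
        X=X,
        actions=np.array([t.action_id for t in tensors], dtype=np.int64),
        labels=np.array([t.label for t in tensors], dtype=np.int64),
        subjects=np.array([t.subject_id for t in tensors], dtype=object),
    )
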