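"""Hand-crafted-feature and raw-signal baselines.

The classical baselines represent each trial as a 112-dimensional vector:
8 muscles x [RMS, MAV, VAR, WL, ZC, SSC, MDF, MPF] (64 values), 3 kinematic
channels x [mean, std, max, min, median, IQR, RMS, peak-to-peak, jerk
index, spectral arc length] (30 values), and an 18-dim one-hot action
encoding.  An RBF-kernel SVM (C = 10, gamma = 'scale') and a random forest
(300 trees, min_samples_leaf = 2), both class-balanced and fed features
standardized by training-partition statistics, are evaluated under the
same subject-wise split as the network.

The deep baseline is a dual-stream 1-D CNN: per-channel 1-D double-conv
blocks (kernel 9, channels 1->32->64->128->128) replace the 2-D scalogram
encoders while keeping the attention pooling, gated fusion, action one-hot
and classification head identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import nn
from .network import (AttentionPool, GatedFusion, ModelConfig, N_ACTIONS)
from .preprocess import KinematicChannels
from .synthetic import MUSCLES, TrialRecord

__all__ = [
    "EMG_FEATURE_NAMES", "KINEMATIC_FEATURE_NAMES",
    "feature_layout", "emg_features", "kinematic_features",
    "build_feature_vector", "fit_baselines", "DualStream1DCnn",
]

EMG_FEATURE_NAMES = ("RMS", "MAV", "VAR", "WL", "ZC", "SSC", "MDF", "MPF")
KINEMATIC_FEATURE_NAMES = ("mean", "std", "max", "min", "median", "IQR",
                           "RMS", "ptp", "jerk_index", "sparc")
_KINE_CHANNELS = ("velocity", "acceleration", "jerk")


def feature_layout() -> list[str]:
    """The documented 112-entry feature order (name <-> index map)."""
    names = [f"{m}_{f}" for m in MUSCLES for f in EMG_FEATURE_NAMES]
    names += [f"{c}_{f}" for c in _KINE_CHANNELS for f in KINEMATIC_FEATURE_NAMES]
    names += [f"action_{a}" for a in range(1, N_ACTIONS + 1)]
    return names


def emg_features(x: np.ndarray, fs: float, zc_threshold: float = 0.0) -> np.ndarray:
    """Eight per-channel sEMG descriptors.

    Time domain: RMS, mean absolute value, sample variance, waveform length,
    zero crossings and slope-sign changes (both with a configurable deadband
    ``zc_threshold``; the textbook definition uses 0).  Frequency domain:
    median frequency and mean power frequency from a Welch spectrum
    (segment length min(256, T), 50% overlap).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D signal with at least 2 samples")
    rms = float(np.sqrt(np.mean(x**2)))
    mav = float(np.mean(np.abs(x)))
    var = float(np.var(x, ddof=1))
    dx = np.diff(x)
    wl = float(np.sum(np.abs(dx)))
    zc = int(np.sum((x[:-1] * x[1:] < 0)
                    & (np.abs(dx) >= zc_threshold)))
    ddx = dx[:-1] * dx[1:]
    ssc = int(np.sum((ddx < 0)
                     & ((np.abs(dx[:-1]) >= zc_threshold)
                        | (np.abs(dx[1:]) >= zc_threshold))))
    nper = min(256, x.size)
    freqs, psd = welch(x, fs=fs, nperseg=nper, noverlap=nper // 2)
    total = psd.sum()
    if total <= 0:
        mdf = mpf = 0.0
    else:
        cum = np.cumsum(psd)
        mdf = float(freqs[np.searchsorted(cum, total / 2.0)])
        mpf = float(np.sum(freqs * psd) / total)
    return np.array([rms, mav, var, wl, zc, ssc, mdf, mpf])


def _spectral_arc_length(v: np.ndarray, fs: float, cutoff: float = 20.0,
                         pad_factor: int = 4) -> float:
    """Movement-smoothness metric: negative arc length of the normalized
    magnitude spectrum of the speed profile below ``cutoff`` Hz."""
    n = int(2 ** np.ceil(np.log2(v.size * pad_factor)))
    spec = np.abs(np.fft.rfft(v, n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = freqs <= cutoff
    mag = spec[sel] / (spec[sel].max() + 1e-12)
    f_norm = freqs[sel] / cutoff
    return float(-np.sum(np.sqrt(np.diff(f_norm) ** 2 + np.diff(mag) ** 2)))


def kinematic_features(channels: KinematicChannels, fs: float | None = None
                       ) -> np.ndarray:
    """Ten statistics per kinematic channel, 30 values in fixed order.

    The jerk index is the RMS jerk normalized by movement duration and
    peak speed (dimensionless smoothness penalty); the spectral arc length
    is computed on the velocity profile for every channel row's slot using
    that channel's own trace.
    """
    fs = fs or channels.fs
    stacked = channels.stack()
    if stacked.shape[1] < 2:
        raise ValueError("kinematic channels need at least 2 samples")
    duration = stacked.shape[1] / fs
    peak_speed = float(np.max(np.abs(channels.velocity))) + 1e-12
    rms_jerk = float(np.sqrt(np.mean(channels.jerk**2)))
    jerk_index = rms_jerk * duration**2 / peak_speed

    out = []
    for row in stacked:
        q75, q25 = np.percentile(row, [75, 25])
        out.extend([
            float(np.mean(row)), float(np.std(row)), float(np.max(row)),
            float(np.min(row)), float(np.median(row)), float(q75 - q25),
            float(np.sqrt(np.mean(row**2))), float(np.ptp(row)),
            jerk_index, _spectral_arc_length(row, fs),
        ])
    return np.array(out)


def build_feature_vector(trial: TrialRecord) -> np.ndarray:
    """Concatenate sEMG (64) + kinematic (30) + action one-hot (18) = 112."""
    if trial.kinematics is None:
        raise ValueError("trial must be preprocessed before feature extraction")
    emg_block = np.concatenate([emg_features(ch, trial.emg_fs) for ch in trial.emg])
    kine_block = kinematic_features(trial.kinematics, trial.kine_fs)
    action_block = np.zeros(N_ACTIONS)
    action_block[trial.action_id - 1] = 1.0
    return np.concatenate([emg_block, kine_block, action_block])


def fit_baselines(features: np.ndarray, labels: np.ndarray,
                  subjects: np.ndarray, split: dict[str, set],
                  seed: int = 0) -> dict:
    """Fit the SVM and random-forest baselines under a subject-wise split.

    Features are standardized with training-partition statistics; both
    models use class-balanced weighting.  Returns fitted models, test
    predictions and evaluation reports.
    """
    from .evaluation import compute_metrics

    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    masks = {name: np.isin(subjects, list(sids)) for name, sids in split.items()}
    if set(subjects[masks["test"]]) & set(subjects[masks["train"]]):
        raise ValueError("subject leakage: test subjects present in training data")

    mu = features[masks["train"]].mean(axis=0)
    sd = features[masks["train"]].std(axis=0)
    sd[sd == 0] = 1.0
    Z = (features - mu) / sd

    svm = SVC(kernel="rbf", C=10.0, gamma="scale", class_weight="balanced",
              random_state=seed)
    rf = RandomForestClassifier(n_estimators=300, min_samples_leaf=2,
                                class_weight="balanced", random_state=seed,
                                n_jobs=1)
    out: dict = {"standardization": (mu, sd)}
    for name, model in (("svm", svm), ("rf", rf)):
        model.fit(Z[masks["train"]], labels[masks["train"]])
        pred = model.predict(Z[masks["test"]])
        out[name] = {
            "model": model,
            "y_pred": pred,
            "report": compute_metrics(labels[masks["test"]], pred),
        }
    return out


def _make_signal_encoder(rng: np.random.Generator,
                         channels=(1, 32, 64, 128, 128),
                         kernel_len: int = 9) -> nn.Sequential:
    """Four double-conv 1-D blocks + GAP; signals ride as (B, 1, T, 1) images."""
    layers: list[nn.Module] = []
    for cin, cout in zip(channels[:-1], channels[1:]):
        layers += [
            nn.Conv2d(cin, cout, kernel=(1, kernel_len), rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, kernel=(1, kernel_len), rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU(),
            nn.MaxPool2d((1, 2)),
        ]
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


class DualStream1DCnn(nn.Module):
    """Raw-signal baseline mirroring the fusion head of the 2-D network.

    Each of the 8 sEMG and 3 kinematic traces passes a shared per-branch
    1-D encoder; attention pooling, temperature-gated fusion (or plain
    concatenation), the action one-hot and the classifier are identical in
    structure to the scalogram network.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self.encoder_emg = _make_signal_encoder(rng)
        self.encoder_kine = _make_signal_encoder(rng)
        self.att_emg = AttentionPool(cfg.attention, rng)
        self.att_kine = AttentionPool(cfg.attention, rng)
        d = cfg.head.feature_dim
        if cfg.fusion == "gate":
            self.gate = GatedFusion(cfg.gate, rng)
        else:
            self.concat_reduce = nn.Linear(2 * d, d, rng=rng)
        head_in = d + (cfg.head.action_dim if cfg.use_action else 0)
        self.head = nn.Sequential(
            nn.Linear(head_in, cfg.head.hidden_dim, rng=rng),
            nn.ReLU(),
            nn.Dropout(cfg.head.dropout, rng=np.random.default_rng(seed + 1)),
            nn.Linear(cfg.head.hidden_dim, cfg.head.n_classes, rng=rng),
        )
        self.last_attention: dict[str, np.ndarray] = {}

    def _encode(self, encoder: nn.Sequential, streams: np.ndarray) -> np.ndarray:
        b, n, t = streams.shape
        t16 = (t // 16) * 16  # four halvings need a multiple of 16
        if t16 < 16:
            raise ValueError(f"signals too short for four pooling stages: T={t}")
        x = streams[:, :, :t16].reshape(b * n, 1, t16, 1).astype(np.float32)
        return encoder.forward(x).reshape(b, n, -1)

    def forward(self, emg: np.ndarray, kine: np.ndarray, actions: np.ndarray
                ) -> np.ndarray:
        cfg = self.config
        b = emg.shape[0]
        if emg.shape[1] != 8 or kine.shape[1] != 3:
            raise ValueError("expected (B, 8, T_e) sEMG and (B, 3, T_k) kinematics")
        self.last_attention = {}
        F_e = self._encode(self.encoder_emg, emg)
        F_k = self._encode(self.encoder_kine, kine)
        f_emg, a_e = self.att_emg.forward(F_e)
        f_kine, a_k = self.att_kine.forward(F_k)
        self.last_attention["alpha_emg"] = a_e
        self.last_attention["alpha_kine"] = a_k
        if cfg.fusion == "gate":
            fused, w = self.gate.forward(f_emg, f_kine)
            self.last_attention["gate"] = w
        else:
            fused = self.concat_reduce.forward(np.concatenate([f_emg, f_kine], axis=1))
        if cfg.use_action:
            onehot = np.zeros((b, cfg.head.action_dim), dtype=np.float32)
            onehot[np.arange(b), np.asarray(actions).astype(int) - 1] = 1.0
            fused = np.concatenate([fused, onehot], axis=1)
        return self.head.forward(fused)

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.config
        d = cfg.head.feature_dim
        g = self.head.backward(np.asarray(dlogits, dtype=np.float32))[:, :d]
        if cfg.fusion == "gate":
            g_emg, g_kine = self.gate.backward(g)
        else:
            gcat = self.concat_reduce.backward(g)
            g_emg, g_kine = gcat[:, :d], gcat[:, d:]
        for att, enc, gb in ((self.att_emg, self.encoder_emg, g_emg),
                             (self.att_kine, self.encoder_kine, g_kine)):
            gF = att.backward(gb)
            b, n, dd = gF.shape
            enc.backward(gF.reshape(b * n, dd))
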