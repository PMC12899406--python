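"""The action-aware multimodal wavelet fusion network (AMWFNet).

Two structurally identical, weight-independent image encoders consume the
sEMG (8 planes) and kinematic (3 planes) scalogram stacks one plane at a
time through shared weights: four double-conv blocks (3x3 conv + batch
norm + ReLU, twice, then 2x2 max pool) along the channel sequence
1->32->64->128->128, closed by global average pooling into a D = 128
vector per plane.  Channel-wise attention pooling (128->64->1 MLP scores,
softmax over the N planes) collapses each branch to one vector; a gating
MLP (256 hidden) over the concatenated branch vectors produces two logits
whose temperature-scaled softmax (tau, default 2.5) gives the convex
modality weights; the fused vector is concatenated with an 18-dim one-hot
action encoding into a 146-dim composite classified through a
128-hidden/ReLU/dropout-0.3/linear-6 head.

The full default configuration has 1,268,554 trainable parameters
(~1.27 M; ~4.84 MB at 4 bytes each).  Ablation variants (single modality,
concatenation fusion, no action context) are selected via ``ModelConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "EncoderConfig", "AttentionPoolConfig", "GateConfig", "HeadConfig",
    "ModelConfig", "AttentionPool", "GatedFusion", "AmwfnetModel",
    "make_image_encoder", "count_parameters", "architecture_fingerprint",
]

N_ACTIONS = 18
N_CLASSES = 6


@dataclass(frozen=True)
class EncoderConfig:
    channel_sequence: tuple[int, ...] = (1, 32, 64, 128, 128)
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    feature_dim: int = 128


@dataclass(frozen=True)
class AttentionPoolConfig:
    feature_dim: int = 128
    hidden_dim: int = 64


@dataclass(frozen=True)
class GateConfig:
    feature_dim: int = 128
    hidden_dim: int = 256
    tau: float = 2.5

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")


@dataclass(frozen=True)
class HeadConfig:
    feature_dim: int = 128
    action_dim: int = N_ACTIONS
    hidden_dim: int = 128
    dropout: float = 0.3
    n_classes: int = N_CLASSES


@dataclass(frozen=True)
class ModelConfig:
    encoder: EncoderConfig = EncoderConfig()
    attention: AttentionPoolConfig = AttentionPoolConfig()
    gate: GateConfig = GateConfig()
    head: HeadConfig = HeadConfig()
    use_emg: bool = True
    use_kine: bool = True
    use_action: bool = True
    fusion: str = "gate"  # 'gate' | 'concat'

    def __post_init__(self) -> None:
        if not (self.use_emg or self.use_kine):
            raise ValueError("at least one modality must be enabled")
        if self.fusion not in ("gate", "concat"):
            raise ValueError("fusion must be 'gate' or 'concat'")


def make_image_encoder(cfg: EncoderConfig, rng: np.random.Generator) -> nn.Sequential:
    """Four double-conv blocks + GAP; consumes (B, 1, H, W), emits (B, D)."""
    layers: list[nn.Module] = []
    seq = cfg.channel_sequence
    for cin, cout in zip(seq[:-1], seq[1:]):
        layers += [
            nn.Conv2d(cin, cout, cfg.kernel, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, cfg.kernel, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
            nn.MaxPool2d(cfg.pool),
        ]
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


class AttentionPool(nn.Module):
    """Softmax-normalized convex pooling over the N plane features."""

    def __init__(self, cfg: AttentionPoolConfig, rng: np.random.Generator):
        self.mlp = nn.Sequential(
            nn.Linear(cfg.feature_dim, cfg.hidden_dim, rng=rng),
            nn.ReLU(),
            nn.Linear(cfg.hidden_dim, 1, rng=rng),
        )

    def forward(self, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b, n, d = F.shape
        scores = self.mlp.forward(F.reshape(b * n, d)).reshape(b, n)
        alpha = nn.softmax(scores, axis=1)
        pooled = np.einsum("bn,bnd->bd", alpha, F)
        self._cache = (F, alpha)
        return pooled, alpha

    def backward(self, gpooled: np.ndarray) -> np.ndarray:
        F, alpha = self._cache
        b, n, d = F.shape
        galpha = np.einsum("bd,bnd->bn", gpooled, F)
        gscores = alpha * (galpha - (alpha * galpha).sum(axis=1, keepdims=True))
        gF = alpha[:, :, None] * gpooled[:, None, :]
        gF += self.mlp.backward(
            gscores.reshape(b * n, 1).astype(np.float32)).reshape(b, n, d)
        return gF


class GatedFusion(nn.Module):
    """Temperature-softmax convex combination of the two branch vectors."""

    def __init__(self, cfg: GateConfig, rng: np.random.Generator):
        if cfg.tau <= 0:
            raise ValueError("temperature tau must be > 0")
        self.tau = cfg.tau
        out = nn.Linear(cfg.hidden_dim, 2, rng=rng)
        # start near-uniform fusion: tiny output weights keep the initial
        # gate at ~(0.5, 0.5) so neither branch is starved before it has
        # learned anything
        out.weight.value *= 0.01
        self.mlp = nn.Sequential(
            nn.Linear(2 * cfg.feature_dim, cfg.hidden_dim, rng=rng),
            nn.ReLU(),
            out,
        )

    def forward(self, f_emg: np.ndarray, f_kine: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        f_cat = np.concatenate([f_emg, f_kine], axis=1)
        logits = self.mlp.forward(f_cat)
        w = nn.softmax(logits / self.tau, axis=1)
        fused = w[:, :1] * f_emg + w[:, 1:] * f_kine
        self._cache = (f_emg, f_kine, w)
        return fused, w

    def backward(self, gfused: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f_emg, f_kine, w = self._cache
        gw = np.stack([(gfused * f_emg).sum(axis=1),
                       (gfused * f_kine).sum(axis=1)], axis=1)
        glogits = w * (gw - (w * gw).sum(axis=1, keepdims=True)) / self.tau
        gcat = self.mlp.backward(glogits.astype(np.float32))
        d = f_emg.shape[1]
        g_emg = w[:, :1] * gfused + gcat[:, :d]
        g_kine = w[:, 1:] * gfused + gcat[:, d:]
        return g_emg, g_kine


class AmwfnetModel(nn.Module):
    """Full dual-branch model over (B, 11, H, W) scalogram tensors.

    ``forward(x, actions)`` returns the 6 class logits; attention and gate
    weights of the last forward pass are kept in ``last_attention`` for
    interpretability extraction.  ``backward(dlogits)`` propagates through
    every component.  Ablation variants slice only the planes they use.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        if cfg.use_emg:
            self.encoder_emg = make_image_encoder(cfg.encoder, rng)
            self.att_emg = AttentionPool(cfg.attention, rng)
        if cfg.use_kine:
            self.encoder_kine = make_image_encoder(cfg.encoder, rng)
            self.att_kine = AttentionPool(cfg.attention, rng)
        d = cfg.head.feature_dim
        if cfg.use_emg and cfg.use_kine:
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

    # -- branch helpers ----------------------------------------------------
    def _encode(self, encoder: nn.Sequential, planes: np.ndarray) -> np.ndarray:
        b, n, h, w = planes.shape
        if h < 16 or w < 16 or h % 16 or w % 16:
            raise ValueError(f"plane size {(h, w)} must be a multiple of 16 "
                             "(four 2x2 pooling stages)")
        # each plane is an independent 1-channel image; channels-last layout
        feats = encoder.forward(planes.reshape(b * n, h, w, 1))
        return feats.reshape(b, n, -1)

    def forward(self, x: np.ndarray, actions: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        actions = np.asarray(actions)
        if x.ndim != 4 or x.shape[1] != 11:
            raise ValueError(f"expected (B, 11, H, W) input, got {x.shape}")
        if np.any(actions < 1) or np.any(actions > N_ACTIONS):
            raise ValueError("action IDs must be in 1..18")
        cfg = self.config
        b = x.shape[0]
        self.last_attention = {}

        f_emg = f_kine = None
        if cfg.use_emg:
            F_e = self._encode(self.encoder_emg, x[:, :8])
            f_emg, a_e = self.att_emg.forward(F_e)
            self.last_attention["alpha_emg"] = a_e
        if cfg.use_kine:
            F_k = self._encode(self.encoder_kine, x[:, 8:11])
            f_kine, a_k = self.att_kine.forward(F_k)
            self.last_attention["alpha_kine"] = a_k

        if cfg.use_emg and cfg.use_kine:
            if cfg.fusion == "gate":
                fused, w = self.gate.forward(f_emg, f_kine)
                self.last_attention["gate"] = w
            else:
                fused = self.concat_reduce.forward(
                    np.concatenate([f_emg, f_kine], axis=1))
        else:
            fused = f_emg if cfg.use_emg else f_kine

        if cfg.use_action:
            onehot = np.zeros((b, cfg.head.action_dim), dtype=np.float32)
            onehot[np.arange(b), actions.astype(int) - 1] = 1.0
            composite = np.concatenate([fused, onehot], axis=1)
        else:
            composite = fused
        self._b = b
        return self.head.forward(composite)

    def backward(self, dlogits: np.ndarray) -> None:
        cfg = self.config
        d = cfg.head.feature_dim
        gcomposite = self.head.backward(np.asarray(dlogits, dtype=np.float32))
        gfused = gcomposite[:, :d]

        if cfg.use_emg and cfg.use_kine:
            if cfg.fusion == "gate":
                g_emg, g_kine = self.gate.backward(gfused)
            else:
                gcat = self.concat_reduce.backward(gfused)
                g_emg, g_kine = gcat[:, :d], gcat[:, d:]
        else:
            g_emg = gfused if cfg.use_emg else None
            g_kine = gfused if cfg.use_kine else None

        if cfg.use_emg:
            gF = self.att_emg.backward(g_emg)
            b, n, dd = gF.shape
            self.encoder_emg.backward(gF.reshape(b * n, dd))
        if cfg.use_kine:
            gF = self.att_kine.backward(g_kine)
            b, n, dd = gF.shape
            self.encoder_kine.backward(gF.reshape(b * n, dd))


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.value.size for p in model.parameters()))


def architecture_fingerprint(model: AmwfnetModel) -> dict:
    """JSON-serializable summary: component shapes + total parameter count."""
    def shapes(mod: nn.Module) -> list[list[int]]:
        return [list(p.value.shape) for p in mod.parameters()]

    out: dict = {"total_parameters": count_parameters(model)}
    for name in ("encoder_emg", "encoder_kine", "att_emg", "att_kine",
                 "gate", "concat_reduce", "head"):
        if hasattr(model, name):
            out[name] = shapes(getattr(model, name))
    out["config"] = {
        "use_emg": model.config.use_emg,
        "use_kine": model.config.use_kine,
        "use_action": model.config.use_action,
        "fusion": model.config.fusion,
        "tau": model.config.gate.tau,
    }
    return out
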