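"""The permutable feature-fusion synergy network.

One model holds up to three fingerprint-specific subnetworks (FSNs), one per
fingerprint kind (HashTT, MAP4, MACCS). Each FSN

1. encodes both drugs of a pair with a *shared* three-layer Conv1D encoder
   (channel widths 8/16/32, GELU after every layer, length-preserving
   stride-1 convolutions) followed by a flatten + affine projection to a
   common feature width D;
2. encodes the cell line's expression and mutation profiles with two
   separate encoders of the same architecture;
3. stacks the four D-vectors into a 4 x D fusion tensor and passes it
   through two Permute-MLP blocks — a residual MLP along the feature axis,
   a transpose, a residual MLP along the view axis, and a transpose back;
4. flattens, projects (affine, GELU, affine) to the synergy feature, and
   maps it through a two-layer GELU head to a scalar score.

The model's prediction is the arithmetic mean of the per-FSN scores, and
training minimizes the mean squared error of that averaged prediction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import ShapeError
from .nn import Adam, Conv1d, Linear, LayerNorm, Module, Parameter

N_VIEWS = 4  # drug i, drug j, expression, mutation
DEFAULT_FP_LENGTHS = {"hashtt": 1024, "map4": 1024, "maccs": 166}


@dataclass(frozen=True)
class ConvEncoderConfig:
    """Three-layer Conv1D encoder hyperparameters."""

    channels: tuple[int, int, int] = (8, 16, 32)
    kernel: int = 3
    out_dim: int = 128


@dataclass(frozen=True)
class FusionConfig:
    """Permute-MLP fusion hyperparameters (N is fixed at 4 views)."""

    feature_dim: int = 128  # D
    hidden_dim: int = 512  # D-hat of the projection
    out_dim: int = 128  # D-tilde, the synergy-feature width
    n_views: int = N_VIEWS
    n_blocks: int = 2

    def __post_init__(self):
        if self.n_views != N_VIEWS:
            raise ValueError("the fusion stack always holds 4 views")
        if self.n_blocks != 2:
            raise ValueError("the fusion pipeline uses exactly 2 Permute-MLP blocks")


@dataclass(frozen=True)
class ModelConfig:
    """Full network configuration.

    ``kinds`` selects which FSNs exist (ablations drop entries);
    ``use_permute_mlp = False`` replaces both fusion blocks by the identity;
    ``encoder = "ff"`` swaps every Conv1D encoder for an affine+GELU stack of
    the same output width (the lightweight model variant).
    """

    kinds: tuple[str, ...] = ("hashtt", "map4", "maccs")
    fp_lengths: dict = field(default_factory=lambda: dict(DEFAULT_FP_LENGTHS))
    expr_len: int = 64
    mut_len: int = 64
    conv: ConvEncoderConfig = ConvEncoderConfig()
    fusion: FusionConfig = FusionConfig()
    head_hidden: int = 64  # defaults to out_dim / 2
    use_permute_mlp: bool = True
    encoder: str = "conv"  # {"conv", "ff"}
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        # accept plain dicts / lists (YAML configs) for the nested fields
        if isinstance(self.conv, dict):
            d = dict(self.conv)
            if "channels" in d:
                d["channels"] = tuple(d["channels"])
            object.__setattr__(self, "conv", ConvEncoderConfig(**d))
        if isinstance(self.fusion, dict):
            object.__setattr__(self, "fusion", FusionConfig(**self.fusion))
        if not isinstance(self.kinds, tuple):
            object.__setattr__(self, "kinds", tuple(self.kinds))
        if not self.kinds:
            raise ValueError("at least one fingerprint kind is required")
        for kind in self.kinds:
            if kind not in self.fp_lengths:
                raise ValueError(f"no fingerprint length configured for {kind!r}")
        if self.encoder not in ("conv", "ff"):
            raise ValueError("encoder must be 'conv' or 'ff'")
        if self.conv.out_dim != self.fusion.feature_dim:
            raise ValueError("encoder out_dim must equal fusion feature_dim")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinds"] = list(self.kinds)
        d["conv"]["channels"] = list(self.conv.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["kinds"] = tuple(d["kinds"])
        d["conv"] = ConvEncoderConfig(
            channels=tuple(d["conv"]["channels"]),
            kernel=d["conv"]["kernel"],
            out_dim=d["conv"]["out_dim"],
        )
        d["fusion"] = FusionConfig(**d["fusion"])
        return cls(**d)


@dataclass(frozen=True)
class PredictionTriple:
    """Per-FSN synergy scores and their average for one trio.

    For fingerprint-subset ablations, absent heads are ``None`` and ``y_hat``
    averages the remaining ones.
    """

    y_t: float | None  # HashTT head
    y_p: float | None  # MAP4 head
    y_s: float | None  # MACCS head
    y_hat: float

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "PredictionTriple":
        vals = [scores[k] for k in ("hashtt", "map4", "maccs") if k in scores]
        return cls(
            y_t=scores.get("hashtt"),
            y_p=scores.get("map4"),
            y_s=scores.get("maccs"),
            y_hat=float(np.mean(vals)),
        )


class ConvEncoder(Module):
    """Three stride-1 Conv1D layers with GELU, flatten, affine projection to D."""

    def __init__(self, seq_len: int, cfg: ConvEncoderConfig, rng, dtype):
        if seq_len < cfg.kernel:
            raise ShapeError(f"sequence length {seq_len} < kernel {cfg.kernel}")
        self.seq_len = seq_len
        c1, c2, c3 = cfg.channels
        self.conv1 = Conv1d(1, c1, cfg.kernel, rng, dtype)
        self.conv2 = Conv1d(c1, c2, cfg.kernel, rng, dtype)
        self.conv3 = Conv1d(c2, c3, cfg.kernel, rng, dtype)
        self.proj = Linear(seq_len * c3, cfg.out_dim, rng, dtype)

    def feature_map(self, x: Tensor) -> Tensor:
        """The (B, L, k') activation after the third convolution."""
        if x.data.ndim != 2 or x.shape[1] != self.seq_len:
            raise ShapeError(f"expected (batch, {self.seq_len}) input, got {x.shape}")
        h = ag.reshape(x, (x.shape[0], self.seq_len, 1))
        h = ag.gelu(self.conv1(h))
        h = ag.gelu(self.conv2(h))
        h = ag.gelu(self.conv3(h))
        return h

    def __call__(self, x: Tensor) -> Tensor:
        h = self.feature_map(x)
        flat = ag.reshape(h, (x.shape[0], -1))
        return self.proj(flat)


class FeedforwardEncoder(Module):
    """Affine + GELU + affine encoder of matched output width (the "-L" variant)."""

    def __init__(self, seq_len: int, out_dim: int, rng, dtype):
        self.seq_len = seq_len
        self.fc1 = Linear(seq_len, out_dim, rng, dtype)
        self.fc2 = Linear(out_dim, out_dim, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim != 2 or x.shape[1] != self.seq_len:
            raise ShapeError(f"expected (batch, {self.seq_len}) input, got {x.shape}")
        return self.fc2(ag.gelu(self.fc1(x)))


def stack_features(z_di, z_dj, z_e, z_m) -> Tensor:
    """Stack the four view features into the N x D fusion tensor.

    Accepts 1-D vectors (returns 4 x D) or batched (B, D) tensors (returns
    B x 4 x D). Row order is fixed: drug i, drug j, expression, mutation.
    """
    views = [t if isinstance(t, Tensor) else Tensor(np.asarray(t)) for t in (z_di, z_dj, z_e, z_m)]
    dims = {v.shape[-1] for v in views}
    ndims = {v.data.ndim for v in views}
    if len(dims) != 1 or not ndims <= {1, 2}:
        raise ShapeError(f"view features must share their width, got {[v.shape for v in views]}")
    if ndims == {1}:
        rows = [ag.reshape(v, (1, v.shape[0])) for v in views]
        return ag.concat(rows, axis=0)
    if ndims != {2}:
        raise ShapeError("cannot mix batched and unbatched views")
    rows = [ag.reshape(v, (v.shape[0], 1, v.shape[1])) for v in views]
    return ag.concat(rows, axis=1)


class PermuteMLPBlock(Module):
    """Residual MLP along D, transpose, residual MLP along N, transpose back.

    With the residual-branch weights zeroed the block is the exact identity:
    LayerNorm of the zero vector is zero (beta initializes to zero), so only
    the residual path survives.
    """

    def __init__(self, n_views: int, dim: int, rng, dtype):
        self.lin1_d = Linear(dim, dim, rng, dtype)
        self.lin2_d = Linear(dim, dim, rng, dtype)
        self.ln_d = LayerNorm(dim, dtype)
        self.lin1_n = Linear(n_views, dim, rng, dtype)
        self.lin2_n = Linear(dim, n_views, rng, dtype)
        self.ln_n = LayerNorm(n_views, dtype)

    def zero_residual_branches(self) -> None:
        for lin in (self.lin1_d, self.lin2_d, self.lin1_n, self.lin2_n):
            lin.weight.data = np.zeros_like(lin.weight.data)
            lin.bias.data = np.zeros_like(lin.bias.data)

    def __call__(self, h: Tensor) -> Tensor:
        if h.shape[-2:] != (self.lin1_n.weight.shape[0], self.lin1_d.weight.shape[0]):
            raise ShapeError(f"expected trailing shape (N, D), got {h.shape}")
        u = h + self.ln_d(self.lin2_d(ag.silu(self.lin1_d(h))))
        t = ag.swap_last2(u)  # (.., D, N)
        v = t + self.ln_n(self.lin2_n(ag.silu(self.lin1_n(t))))
        return ag.swap_last2(v)


class FSN(Module):
    """One fingerprint-specific subnetwork: encoders, fusion, projection, head."""

    def __init__(self, kind: str, fp_len: int, cfg: ModelConfig, rng, dtype):
        self.kind = kind
        make = (
            (lambda L: ConvEncoder(L, cfg.conv, rng, dtype))
            if cfg.encoder == "conv"
            else (lambda L: FeedforwardEncoder(L, cfg.conv.out_dim, rng, dtype))
        )
        self.drug_encoder = make(fp_len)  # shared by both drugs of a pair
        self.expr_encoder = make(cfg.expr_len)
        self.mut_encoder = make(cfg.mut_len)
        fus = cfg.fusion
        self.blocks = (
            [PermuteMLPBlock(fus.n_views, fus.feature_dim, rng, dtype) for _ in range(fus.n_blocks)]
            if cfg.use_permute_mlp
            else []
        )
        self.proj1 = Linear(fus.n_views * fus.feature_dim, fus.hidden_dim, rng, dtype)
        self.proj2 = Linear(fus.hidden_dim, fus.out_dim, rng, dtype)
        self.head1 = Linear(fus.out_dim, cfg.head_hidden, rng, dtype)
        self.head2 = Linear(cfg.head_hidden, 1, rng, dtype)

    def fuse_and_project(self, h: Tensor) -> Tensor:
        """Flatten the fused N x D tensor, affine to D-hat, GELU, affine to D-tilde."""
        flat = ag.reshape(h, (h.shape[0], -1))
        return self.proj2(ag.gelu(self.proj1(flat)))

    def from_encoded(self, z_di, z_dj, z_e, z_m) -> tuple[Tensor, Tensor]:
        h = stack_features(z_di, z_dj, z_e, z_m)
        for block in self.blocks:
            h = block(h)
        m = self.fuse_and_project(h)
        y = self.head2(ag.gelu(self.head1(m)))
        return m, ag.reshape(y, (y.shape[0],))

    def __call__(self, fp_i: Tensor, fp_j: Tensor, expr: Tensor, mut: Tensor):
        """Forward one batch; returns (synergy feature, scalar scores)."""
        z_di = self.drug_encoder(fp_i)
        z_dj = self.drug_encoder(fp_j)
        z_e = self.expr_encoder(expr)
        z_m = self.mut_encoder(mut)
        return self.from_encoded(z_di, z_dj, z_e, z_m)


class PermuteDDS(Module):
    """The full multi-fingerprint synergy model."""

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.Generator(np.random.PCG64(config.seed))
        self.fsns = [
            FSN(kind, config.fp_lengths[kind], config, rng, dtype)
            for kind in config.kinds
        ]

    # -- forward paths -------------------------------------------------
    def forward(self, fps_i: dict, fps_j: dict, expr, mut):
        """Batched forward from raw feature arrays.

        ``fps_i[kind]`` / ``fps_j[kind]`` are (B, L_kind) arrays for drug i/j;
        ``expr`` and ``mut`` are (B, g) arrays. Returns the averaged
        prediction tensor (B,) and the per-kind score tensors.
        """
        expr_t = expr if isinstance(expr, Tensor) else Tensor(np.asarray(expr, dtype=self._dtype))
        mut_t = mut if isinstance(mut, Tensor) else Tensor(np.asarray(mut, dtype=self._dtype))
        per_kind: dict[str, Tensor] = {}
        for fsn in self.fsns:
            fi = self._as_tensor(fps_i[fsn.kind])
            fj = self._as_tensor(fps_j[fsn.kind])
            _, y = fsn(fi, fj, expr_t, mut_t)
            per_kind[fsn.kind] = y
        y_hat = per_kind[self.fsns[0].kind]
        for fsn in self.fsns[1:]:
            y_hat = y_hat + per_kind[fsn.kind]
        y_hat = y_hat * (1.0 / len(self.fsns))
        return y_hat, per_kind

    def forward_indexed(self, store, idx_a, idx_b, idx_cell):
        """Forward a batch referencing a feature store by integer index.

        Encodes each unique drug and cell line in the store once per step and
        gathers rows, which is far cheaper than re-encoding per record when
        the drug panel is small relative to the batch.
        """
        per_kind: dict[str, Tensor] = {}
        for fsn in self.fsns:
            z_all = fsn.drug_encoder(self._as_tensor(store.fp_matrix(fsn.kind)))
            z_e_all = fsn.expr_encoder(self._as_tensor(store.expr_matrix()))
            z_m_all = fsn.mut_encoder(self._as_tensor(store.mut_matrix()))
            z_di = ag.gather_rows(z_all, idx_a)
            z_dj = ag.gather_rows(z_all, idx_b)
            z_e = ag.gather_rows(z_e_all, idx_cell)
            z_m = ag.gather_rows(z_m_all, idx_cell)
            _, y = fsn.from_encoded(z_di, z_dj, z_e, z_m)
            per_kind[fsn.kind] = y
        y_hat = per_kind[self.fsns[0].kind]
        for fsn in self.fsns[1:]:
            y_hat = y_hat + per_kind[fsn.kind]
        y_hat = y_hat * (1.0 / len(self.fsns))
        return y_hat, per_kind

    def predict(self, fps_i: dict, fps_j: dict, expr, mut) -> list[PredictionTriple]:
        """Predict a batch and average the heads in float64."""
        _, per_kind = self.forward(fps_i, fps_j, expr, mut)
        scores = {k: np.asarray(v.data, dtype=np.float64) for k, v in per_kind.items()}
        n = len(next(iter(scores.values())))
        return [
            PredictionTriple.from_scores({k: float(s[i]) for k, s in scores.items()})
            for i in range(n)
        ]

    # -- plumbing ------------------------------------------------------
    @property
    def _dtype(self):
        return np.dtype(self.config.dtype).type

    def _as_tensor(self, x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        return Tensor(np.asarray(x, dtype=self._dtype))

    def clone_weights(self) -> dict:
        return self.state_dict()

    # -- checkpointing -------------------------------------------------
    def save(self, path: str) -> None:
        """Write weights to ``<path>.npz`` and the config to ``<path>.json``."""
        np.savez(f"{path}.npz", **self.state_dict())
        with open(f"{path}.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "PermuteDDS":
        with open(f"{path}.json") as fh:
            config = ModelConfig.from_dict(json.load(fh))
        model = cls(config)
        with np.load(f"{path}.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model


def mse_loss(y_true, y_pred):
    """Mean squared error; accepts arrays or autograd tensors.

    Returns an autograd ``Tensor`` when either input is one (for training),
    else a float.
    """
    symbolic = isinstance(y_pred, Tensor) or isinstance(y_true, Tensor)
    t = y_true.data if isinstance(y_true, Tensor) else np.asarray(y_true, dtype=float)
    p = y_pred.data if isinstance(y_pred, Tensor) else np.asarray(y_pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise ShapeError(f"mse_loss needs equal-length 1-D vectors, got {t.shape} and {p.shape}")
    if not symbolic:
        return float(np.mean((t - p) ** 2))
    diff = (y_pred if isinstance(y_pred, Tensor) else Tensor(p)) - (
        y_true if isinstance(y_true, Tensor) else Tensor(t)
    )
    return ag.mean(ag.mul(diff, diff))
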