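"""One-step repair networks.

The main model maps a degraded log-normalized expression profile directly to
its clean counterpart in a single forward pass (no iterative sampling): the
gene vector is split into fixed-size chunks, each chunk linearly embedded as
one token, a stack of pre-norm Transformer encoder blocks mixes information
across chunks through multi-head self-attention, and a linear head projects
every token back to its gene chunk. Training minimizes the mean squared error
between the prediction and the original profile.

MLP denoising/variational autoencoders are provided as baselines; they consume
the same (degraded, original) pairs.
"""

from __future__ import annotations

import json
import math
import zipfile
from dataclasses import asdict, dataclass
from io import BytesIO
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor, parameter
from .errors import ShapeError, ValidationError

TRAIN = "train"
EVAL = "eval"


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class RepairModelConfig:
    """Transformer repair-network hyperparameters.

    The reference configuration is embed_dim 256, 8 heads, 4 layers, FFN 1024,
    dropout 0.1; ``token_size`` genes form one attention token (100 tokens at
    5000 genes). ``noise_augment_sd`` > 0 adds Gaussian noise to the degraded
    input during training only.
    """

    n_genes: int
    embed_dim: int = 256
    num_heads: int = 8
    num_layers: int = 4
    ffn_dim: int = 1024
    dropout: float = 0.1
    token_size: int = 50
    noise_augment_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.token_size < 1:
            raise ValidationError("n_genes and token_size must be >= 1")
        if self.embed_dim % self.num_heads != 0:
            raise ValidationError("embed_dim must be divisible by num_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")

    @property
    def n_tokens(self) -> int:
        return math.ceil(self.n_genes / self.token_size)


@dataclass(frozen=True)
class BaselineConfig:
    """MLP autoencoder baseline hyperparameters (kind: 'dae' or 'vae')."""

    kind: str = "dae"
    hidden_dims: tuple[int, ...] = (256,)
    latent_dim: int = 32
    dropout: float = 0.1
    kl_weight: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("dae", "vae"):
            raise ValidationError("kind must be 'dae' or 'vae'")
        if not self.hidden_dims:
            raise ValidationError("hidden_dims must be nonempty")
        if self.latent_dim < 1:
            raise ValidationError("latent_dim must be >= 1")


# ---------------------------------------------------------------------------
# shared pieces


def mse_loss(prediction, target) -> Tensor:
    """Mean over all entries of the squared difference (the training loss)."""
    pred = prediction if isinstance(prediction, Tensor) else Tensor(prediction)
    targ = target if isinstance(target, Tensor) else Tensor(target)
    if pred.shape != targ.shape:
        raise ShapeError(f"shape mismatch {pred.shape} vs {targ.shape}")
    diff = pred - targ
    return (diff * diff).mean()


def kl_divergence(mu: Tensor, logvar: Tensor) -> Tensor:
    """KL(q || N(0, I)) summed over latent dims, averaged over the batch.

    Closed form per latent dim: 0.5 * (mu^2 + sigma^2 - 1 - ln sigma^2).
    """
    per_entry = (mu * mu + logvar.exp() - 1.0 - logvar) * 0.5
    return per_entry.sum(axis=-1).mean()


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gamma + beta


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: Optional[tuple[int, ...]] = None) -> np.ndarray:
    scale = math.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape or (fan_in, fan_out))


class RepairModel:
    """Common surface of all repair networks.

    Subclasses define ``_forward`` (Tensor graph) and register parameters in
    ``self.params`` (ordered name -> Tensor). ``repair`` is a single
    deterministic forward pass in eval mode.
    """

    kind: str = "base"

    def __init__(self) -> None:
        self.params: dict[str, Tensor] = {}
        self.mode = TRAIN
        self._rng = np.random.default_rng(0)
        self.forward_calls = 0  # incremented once per forward pass

    # subclasses override
    def _forward(self, x: np.ndarray, training: bool) -> Tensor:
        raise NotImplementedError

    def loss(self, x_deg: np.ndarray, x_orig: np.ndarray,
             training: bool = True) -> Tensor:
        pred = self._forward(x_deg, training=training)
        return mse_loss(pred, x_orig)

    def eval(self) -> "RepairModel":
        self.mode = EVAL
        return self

    def train(self) -> "RepairModel":
        self.mode = TRAIN
        return self

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def _add(self, name: str, data: np.ndarray) -> Tensor:
        t = parameter(data)
        self.params[name] = t
        return t

    def _dropout(self, x: Tensor, rate: float, training: bool) -> Tensor:
        if not training or rate <= 0.0:
            return x
        keep = (self._rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(keep)

    def repair(self, x_deg: np.ndarray) -> np.ndarray:
        """One-step repair: a single deterministic forward pass."""
        x_deg = np.atleast_2d(np.asarray(x_deg, dtype=np.float64))
        expected = self.n_genes
        if x_deg.shape[1] != expected:
            raise ShapeError(
                f"input has {x_deg.shape[1]} genes, model expects {expected}"
            )
        return self._forward(x_deg, training=False).data

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.asarray(arrays[k], dtype=np.float64).copy()


# ---------------------------------------------------------------------------
# Transformer repairer


class TransformerRepairer(RepairModel):
    """Chunk-tokenized Transformer encoder mapping degraded -> clean profiles."""

    kind = "transformer"

    def __init__(self, config: RepairModelConfig):
        super().__init__()
        self.config = config
        self._rng = np.random.default_rng(np.random.SeedSequence(
            config.seed).spawn(1)[0])
        rng = np.random.default_rng(config.seed)
        E, H, F, T, S = (config.embed_dim, config.num_heads, config.ffn_dim,
                         config.n_tokens, config.token_size)

        self._add("embed.W", _glorot(rng, S, E))
        self._add("embed.b", np.zeros(E))
        self._add("pos", rng.normal(0.0, 0.02, size=(T, E)))
        for i in range(config.num_layers):
            p = f"layer{i}."
            self._add(p + "ln1.g", np.ones(E))
            self._add(p + "ln1.b", np.zeros(E))
            for w in ("q", "k", "v"):
                self._add(p + f"attn.W{w}", _glorot(rng, E, E))
                self._add(p + f"attn.b{w}", np.zeros(E))
            # residual output projections start at zero so each block begins
            # as the identity on the residual stream (stable short budgets)
            self._add(p + "attn.Wo", np.zeros((E, E)))
            self._add(p + "attn.bo", np.zeros(E))
            self._add(p + "ln2.g", np.ones(E))
            self._add(p + "ln2.b", np.zeros(E))
            self._add(p + "ffn.W1", _glorot(rng, E, F))
            self._add(p + "ffn.b1", np.zeros(F))
            self._add(p + "ffn.W2", np.zeros((F, E)))
            self._add(p + "ffn.b2", np.zeros(E))
        self._add("ln_f.g", np.ones(E))
        self._add("ln_f.b", np.zeros(E))
        self._add("head.W", _glorot(rng, E, S))
        self._add("head.b", np.zeros(S))

    @property
    def n_genes(self) -> int:
        return self.config.n_genes

    def _tokenize(self, x: np.ndarray) -> Tensor:
        cfg = self.config
        pad = cfg.n_tokens * cfg.token_size - cfg.n_genes
        if pad:
            x = np.concatenate(
                [x, np.zeros((x.shape[0], pad))], axis=1
            )
        return Tensor(x.reshape(x.shape[0], cfg.n_tokens, cfg.token_size))

    def _attention(self, a: Tensor, prefix: str) -> Tensor:
        cfg = self.config
        B = a.shape[0]
        H, E = cfg.num_heads, cfg.embed_dim
        dh = E // H
        P = self.params

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, cfg.n_tokens, H, dh).swapaxes(1, 2)

        q = heads(a @ P[prefix + "attn.Wq"] + P[prefix + "attn.bq"])
        k = heads(a @ P[prefix + "attn.Wk"] + P[prefix + "attn.bk"])
        v = heads(a @ P[prefix + "attn.Wv"] + P[prefix + "attn.bv"])
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        mixed = scores.softmax(axis=-1) @ v          # (B, H, T, dh)
        merged = mixed.swapaxes(1, 2).reshape(B, cfg.n_tokens, E)
        return merged @ P[prefix + "attn.Wo"] + P[prefix + "attn.bo"]

    def _forward(self, x: np.ndarray, training: bool) -> Tensor:
        self.forward_calls += 1
        cfg = self.config
        P = self.params
        if training and cfg.noise_augment_sd > 0:
            x = x + self._rng.normal(0.0, cfg.noise_augment_sd, size=x.shape)

        h = self._tokenize(x) @ P["embed.W"] + P["embed.b"] + P["pos"]
        for i in range(cfg.num_layers):
            p = f"layer{i}."
            a = _layer_norm(h, P[p + "ln1.g"], P[p + "ln1.b"])
            h = h + self._dropout(self._attention(a, p), cfg.dropout, training)
            f = _layer_norm(h, P[p + "ln2.g"], P[p + "ln2.b"])
            f = (f @ P[p + "ffn.W1"] + P[p + "ffn.b1"]).gelu()
            f = f @ P[p + "ffn.W2"] + P[p + "ffn.b2"]
            h = h + self._dropout(f, cfg.dropout, training)
        h = _layer_norm(h, P["ln_f.g"], P["ln_f.b"])
        y = h @ P["head.W"] + P["head.b"]            # (B, T, token_size)
        flat = y.reshape(y.shape[0], cfg.n_tokens * cfg.token_size)
        return flat[:, : cfg.n_genes]


def build_model(config: RepairModelConfig) -> TransformerRepairer:
    """Construct the Transformer repairer with seeded initialization."""
    return TransformerRepairer(config)


# ---------------------------------------------------------------------------
# MLP baselines


class DenoisingAutoencoder(RepairModel):
    """MLP encoder -> latent -> MLP decoder, trained with the same MSE loss."""

    kind = "dae"

    def __init__(self, config: BaselineConfig, n_genes: int):
        super().__init__()
        self.config = config
        self.n_genes = n_genes
        self._rng = np.random.default_rng(np.random.SeedSequence(
            config.seed).spawn(1)[0])
        rng = np.random.default_rng(config.seed)
        dims = [n_genes, *config.hidden_dims, config.latent_dim,
                *reversed(config.hidden_dims), n_genes]
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            self._add(f"W{i}", _glorot(rng, a, b))
            self._add(f"b{i}", np.zeros(b))
        self.n_layers = len(dims) - 1

    def _forward(self, x: np.ndarray, training: bool) -> Tensor:
        self.forward_calls += 1
        h = Tensor(x)
        for i in range(self.n_layers):
            h = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < self.n_layers - 1:
                h = self._dropout(h.relu(), self.config.dropout, training)
        return h


class VariationalAutoencoder(RepairModel):
    """MLP VAE: Gaussian latent with reparameterization during training.

    Inference uses the posterior mean, so eval-mode repair is deterministic.
    Loss = MSE reconstruction + kl_weight * KL(q(z|x) || N(0, I)).
    """

    kind = "vae"

    def __init__(self, config: BaselineConfig, n_genes: int):
        super().__init__()
        self.config = config
        self.n_genes = n_genes
        self._rng = np.random.default_rng(np.random.SeedSequence(
            config.seed).spawn(1)[0])
        rng = np.random.default_rng(config.seed)
        enc = [n_genes, *config.hidden_dims]
        for i, (a, b) in enumerate(zip(enc[:-1], enc[1:])):
            self._add(f"enc.W{i}", _glorot(rng, a, b))
            self._add(f"enc.b{i}", np.zeros(b))
        last = enc[-1]
        self._add("mu.W", _glorot(rng, last, config.latent_dim))
        self._add("mu.b", np.zeros(config.latent_dim))
        self._add("logvar.W", _glorot(rng, last, config.latent_dim))
        self._add("logvar.b", np.zeros(config.latent_dim))
        dec = [config.latent_dim, *reversed(config.hidden_dims), n_genes]
        for i, (a, b) in enumerate(zip(dec[:-1], dec[1:])):
            self._add(f"dec.W{i}", _glorot(rng, a, b))
            self._add(f"dec.b{i}", np.zeros(b))
        self.n_enc = len(enc) - 1
        self.n_dec = len(dec) - 1

    def _encode(self, x: np.ndarray, training: bool) -> tuple[Tensor, Tensor]:
        h = Tensor(x)
        for i in range(self.n_enc):
            h = h @ self.params[f"enc.W{i}"] + self.params[f"enc.b{i}"]
            h = self._dropout(h.relu(), self.config.dropout, training)
        mu = h @ self.params["mu.W"] + self.params["mu.b"]
        logvar = h @ self.params["logvar.W"] + self.params["logvar.b"]
        return mu, logvar

    def _decode(self, z: Tensor) -> Tensor:
        h = z
        for i in range(self.n_dec):
            h = h @ self.params[f"dec.W{i}"] + self.params[f"dec.b{i}"]
            if i < self.n_dec - 1:
                h = h.relu()
        return h

    def _forward(self, x: np.ndarray, training: bool) -> Tensor:
        self.forward_calls += 1
        mu, logvar = self._encode(x, training)
        if training:
            eps = self._rng.normal(size=mu.shape)
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        else:
            z = mu
        self._last_mu, self._last_logvar = mu, logvar
        return self._decode(z)

    def loss(self, x_deg: np.ndarray, x_orig: np.ndarray,
             training: bool = True) -> Tensor:
        pred = self._forward(x_deg, training=training)
        recon = mse_loss(pred, x_orig)
        kl = kl_divergence(self._last_mu, self._last_logvar)
        return recon + kl * self.config.kl_weight


def build_baseline(config: BaselineConfig, n_genes: int) -> RepairModel:
    """Construct a DAE or VAE baseline for ``n_genes`` input features."""
    if config.kind == "dae":
        return DenoisingAutoencoder(config, n_genes)
    return VariationalAutoencoder(config, n_genes)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: RepairModel, path) -> None:
    """Write config (JSON) + parameter arrays (NPZ) into one zip archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    meta = {"kind": model.kind, "config": cfg}
    if model.kind != "transformer":
        meta["n_genes"] = model.n_genes
    buf = BytesIO()
    np.savez(buf, **model.state_arrays())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=2))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path) -> RepairModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = dict(np.load(BytesIO(zf.read("params.npz"))))
    cfg = meta["config"]
    if meta["kind"] == "transformer":
        model: RepairModel = TransformerRepairer(RepairModelConfig(**cfg))
    else:
        cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
        model = build_baseline(BaselineConfig(**cfg), meta["n_genes"])
    model.load_state_arrays(arrays)
    return model.eval()
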