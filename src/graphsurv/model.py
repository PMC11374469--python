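"""The graph attention-based fusion architecture.

Two configurations share one parameter container:

* **ISM** (imaging-only): per-node embedding -> L GraphMixer layers ->
  gated attention pooling over the N nodes -> affine head emitting one
  logit per survival bin.
* **FSM** (fusion): identical trunk, but after the mixers the M
  gene-signature embeddings query the node features through the Genomic
  Attention Module (QKV attention, N nodes -> M fused tokens) and the
  gated pool runs over the M tokens (N -> M -> 1).

A GraphMixer layer is a pre-norm residual pair: a node-mixing layer (graph
attention over the patch adjacency, layer-normalized, then a channel MLP)
and a channel-mixing layer (layer norm + channel MLP):

    H' = H + NML(LN(GA(H, A)))
    H  = H' + CML(LN(H'))

The graph attention scores an edge (j -> i) as
LeakyReLU(a^T [W h_i || W h_j]), softmax-normalizes over the neighbourhood
of i (self-loop included), and aggregates ELU(sum_j alpha_ij W h_j).

``forward`` retains the internals needed for interpretability: the last
mixer layer's node features (kept on the autodiff tape so a logit can be
differentiated with respect to them), the GAM attention matrix, and the
pooling weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor
from .errors import ConfigurationError
from .nn import MLP, Adam, LayerNorm, Linear, Module, glorot_uniform
from .graphs import ImagingGraph

__all__ = [
    "ModelConfig", "GATLayer", "NodeMixingLayer", "ChannelMixingLayer",
    "GraphMixerLayer", "GenomicAttentionModule", "GatedAttentionPool",
    "SurvivalModel", "save_checkpoint", "load_checkpoint",
]

_NEG_INF = -1e30  # additive mask for non-edges before softmax


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults: L=3, D=64, 4 bins)."""

    in_features: int = 32
    hidden_dim: int = 64
    n_mixer_layers: int = 3
    n_signatures: int = 0            # 0 selects the imaging-only model
    signature_lengths: tuple[int, ...] = ()
    attn_hidden_dim: int = 64
    n_bins: int = 4
    leaky_relu_slope: float = 0.2
    gam_scale: str = "sqrt_dim"      # "dim" divides scores by D instead
    mixer_expansion: int = 2
    dropout: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("in_features", "hidden_dim", "n_mixer_layers",
                     "attn_hidden_dim"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if self.n_signatures < 0:
            raise ConfigurationError("n_signatures must be >= 0")
        if self.n_signatures and len(self.signature_lengths) != self.n_signatures:
            raise ConfigurationError(
                f"signature_lengths has {len(self.signature_lengths)} entries "
                f"but n_signatures={self.n_signatures}")
        if self.gam_scale not in ("dim", "sqrt_dim"):
            raise ConfigurationError(
                f"gam_scale must be 'dim' or 'sqrt_dim', got {self.gam_scale!r}")

    @property
    def is_fusion(self) -> bool:
        return self.n_signatures > 0


def _neighbourhood_mask(adjacency) -> np.ndarray:
    """Dense float mask: 0 on edges and the diagonal, -inf elsewhere.

    The self-loop guarantees every neighbourhood is non-empty, so the
    per-row softmax is always well defined.
    """
    a = sp.csr_matrix(adjacency)
    dense = np.asarray(a.todense(), dtype=bool)
    np.fill_diagonal(dense, True)
    return np.where(dense, 0.0, _NEG_INF)


class GATLayer(Module):
    """Single-head graph attention (score, softmax, aggregate + ELU)."""

    def __init__(self, dim: int, rng: np.random.Generator, slope: float = 0.2):
        self.W = Tensor(glorot_uniform(rng, (dim, dim)), requires_grad=True)
        self.a = Tensor(glorot_uniform(rng, (2 * dim, 1)), requires_grad=True)
        self.slope = slope

    def forward(self, h: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        hw = h @ self.W                                   # (N, D)
        dim = hw.shape[1]
        # a^T [W h_i || W h_j] splits into a source and a target contribution
        src = hw @ self.a[:dim, :]                        # (N, 1) — node i term
        dst = hw @ self.a[dim:, :]                        # (N, 1) — node j term
        scores = (src + dst.T).leaky_relu(self.slope)     # (N, N), entry (i, j)
        scores = scores + Tensor(mask)
        alpha = scores.softmax(axis=1)
        out = (alpha @ hw).elu()
        return out, alpha


class NodeMixingLayer(Module):
    """LN of the graph-attention output followed by a channel MLP."""

    def __init__(self, dim: int, rng: np.random.Generator, slope: float,
                 expansion: int, dropout: float):
        self.gat = GATLayer(dim, rng, slope)
        self.norm = LayerNorm(dim)
        self.mlp = MLP(dim, rng, expansion, dropout)

    def forward(self, h: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        ga, alpha = self.gat(h, mask)
        return self.mlp(self.norm(ga)), alpha


class ChannelMixingLayer(Module):
    """Per-node MLP over channels (no token mixing, no transposition)."""

    def __init__(self, dim: int, rng: np.random.Generator, expansion: int,
                 dropout: float):
        self.norm = LayerNorm(dim)
        self.mlp = MLP(dim, rng, expansion, dropout)

    def forward(self, h: Tensor) -> Tensor:
        return self.mlp(self.norm(h))


class GraphMixerLayer(Module):
    """Double pre-norm residual: node mixing then channel mixing."""

    def __init__(self, dim: int, rng: np.random.Generator, slope: float = 0.2,
                 expansion: int = 2, dropout: float = 0.0):
        self.nml = NodeMixingLayer(dim, rng, slope, expansion, dropout)
        self.cml = ChannelMixingLayer(dim, rng, expansion, dropout)

    def forward(self, h: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        mixed, alpha = self.nml(h, mask)
        h1 = h + mixed
        h2 = h1 + self.cml(h1)
        return h2, alpha


class GenomicAttentionModule(Module):
    """QKV attention: signature embeddings query node features.

    attn = softmax_N((B Wq)(H Wk)^T / scale), F = attn (H Wv); one fused
    token per signature. ``scale`` is sqrt(D) by default, D optionally.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 scale: str = "sqrt_dim"):
        self.Wq = Tensor(glorot_uniform(rng, (dim, dim)), requires_grad=True)
        self.Wk = Tensor(glorot_uniform(rng, (dim, dim)), requires_grad=True)
        self.Wv = Tensor(glorot_uniform(rng, (dim, dim)), requires_grad=True)
        self.scale = float(np.sqrt(dim)) if scale == "sqrt_dim" else float(dim)

    def forward(self, b: Tensor, h: Tensor) -> tuple[Tensor, Tensor]:
        if b.shape[0] == 0:
            raise ConfigurationError("GAM requires at least one signature")
        q = b @ self.Wq                       # (M, D)
        k = h @ self.Wk                       # (N, D)
        v = h @ self.Wv                       # (N, D)
        attn = ((q @ k.T) * (1.0 / self.scale)).softmax(axis=1)   # (M, N)
        return attn @ v, attn


class GatedAttentionPool(Module):
    """Gated attention pooling: softmax-weighted average of K tokens.

    a_k = softmax_k( w^T (tanh(V x_k) * sigmoid(U x_k)) ); weights sum to 1,
    making the pooled vector invariant to the number of tokens.
    """

    def __init__(self, dim: int, rng: np.random.Generator, width: int = 64):
        self.V = Tensor(glorot_uniform(rng, (dim, width)), requires_grad=True)
        self.U = Tensor(glorot_uniform(rng, (dim, width)), requires_grad=True)
        self.w = Tensor(glorot_uniform(rng, (width, 1)), requires_grad=True)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        gate = (x @ self.V).tanh() * (x @ self.U).sigmoid()   # (K, width)
        scores = gate @ self.w                                # (K, 1)
        a = scores.softmax(axis=0)                            # (K, 1)
        pooled = (a * x).sum(axis=0)                          # (D,)
        return pooled, a.reshape(-1)


class SurvivalModel(Module):
    """Full ISM/FSM model; ``config.n_signatures == 0`` selects ISM."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.hidden_dim
        self.embed = Linear(config.in_features, d, rng)
        self.mixers = [
            GraphMixerLayer(d, rng, config.leaky_relu_slope,
                            config.mixer_expansion, config.dropout)
            for _ in range(config.n_mixer_layers)
        ]
        if config.is_fusion:
            self.sig_encoders = [Linear(p, d, rng)
                                 for p in config.signature_lengths]
            self.gam = GenomicAttentionModule(d, rng, config.gam_scale)
        else:
            self.sig_encoders = []
            self.gam = None
        self.pool = GatedAttentionPool(d, rng, config.attn_hidden_dim)
        self.head = Linear(d, config.n_bins, rng)

    # -- forward --------------------------------------------------------------

    def encode_signatures(self, signature_values) -> Tensor:
        """Encode per-signature value vectors into the M x D matrix B."""
        from .autodiff import concat

        if len(signature_values) != len(self.sig_encoders):
            raise ConfigurationError(
                f"got {len(signature_values)} signature vectors, model has "
                f"{len(self.sig_encoders)} encoders")
        rows = []
        for i, (vec, enc) in enumerate(zip(signature_values, self.sig_encoders)):
            vec = vec if isinstance(vec, Tensor) else Tensor(np.asarray(vec, float))
            if vec.shape[0] != enc.weight.shape[0]:
                raise ConfigurationError(
                    f"signature {i}: length {vec.shape[0]} != encoder input "
                    f"{enc.weight.shape[0]}")
            rows.append(enc(vec.reshape(1, -1)))
        return concat(rows, axis=0)

    def forward(self, graph: ImagingGraph, signatures=None
                ) -> tuple[Tensor, dict]:
        """Run the model; returns (logits, internals).

        ``signatures``: list of per-signature value vectors (FSM), a
        pre-encoded M x D array/Tensor, or None (ISM).
        """
        cfg = self.config
        if cfg.is_fusion and signatures is None:
            raise ConfigurationError("fusion model requires signature values")
        if not cfg.is_fusion and signatures is not None:
            raise ConfigurationError("imaging-only model takes no signatures")
        mask = _neighbourhood_mask(graph.adjacency)
        h = self.embed(Tensor(np.asarray(graph.node_features, dtype=np.float64)))
        gat_alphas = []
        for mixer in self.mixers:
            h, alpha = mixer(h, mask)
            gat_alphas.append(alpha)
        internals: dict = {"last_mixer": h, "gat_alphas": gat_alphas,
                           "gam_attn": None, "B": None}
        if cfg.is_fusion:
            if isinstance(signatures, Tensor):
                b = signatures
            elif isinstance(signatures, np.ndarray) and signatures.ndim == 2 \
                    and signatures.shape == (cfg.n_signatures, cfg.hidden_dim):
                b = Tensor(signatures)
            else:
                b = self.encode_signatures(signatures)
            fused, attn = self.gam(b, h)
            internals["gam_attn"] = attn
            internals["B"] = b
            tokens = fused
        else:
            tokens = h
        pooled, weights = self.pool(tokens)
        internals["pool_weights"] = weights
        logits = self.head(pooled.reshape(1, -1)).reshape(-1)
        internals["logits"] = logits
        return logits, internals

    def predict_logits(self, graph: ImagingGraph, signatures=None) -> np.ndarray:
        """Inference-mode logits as a plain array (no tape)."""
        from .autodiff import no_grad

        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits, _ = self.forward(graph, signatures)
        finally:
            self.train(was_training)
        return logits.data.copy()


def make_optimizer(model: SurvivalModel, lr: float = 2e-4,
                   weight_decay: float = 1e-5) -> Adam:
    return Adam(model.parameters(), lr=lr, weight_decay=weight_decay)


def save_checkpoint(model: SurvivalModel, path) -> None:
    """Single-file checkpoint: config (JSON) + parameter arrays (npz)."""
    import json

    state = model.state_dict()
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(model.config).items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> SurvivalModel:
    import json

    with np.load(path) as data:
        cfg_raw = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    cfg_raw["signature_lengths"] = tuple(cfg_raw.get("signature_lengths", ()))
    model = SurvivalModel(ModelConfig(**cfg_raw))
    model.load_state_dict(state)
    return model
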