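"""The modified attention temporal graph convolutional classifier.

Pipeline per trial (padded to ``nf`` frames, ``M`` markers):

1. *Spatial*: a three-layer graph convolution applied framewise with the
   normalized adjacency ``O_hat``::

       f(X) = sigmoid( O_hat . ReLU( O_hat . (O_hat . X . Psi0) . Psi1 ) . Psi2 )

   mapping ``M x 3`` coordinates to ``M x Z`` embeddings in (0, 1).
2. *Temporal*: node embeddings are flattened into a frame vector and fed to
   a bidirectional gated recurrent encoder.  Each direction runs the gated
   cell

       ugc_t = sigmoid(Wu [x_t, h_{t-1}])        (update gate)
       rgc_t = sigmoid(Wr [x_t, h_{t-1}])        (reset gate)
       mc_t  = tanh(Wc [x_t, rgc_t * h_{t-1}])   (candidate memory)
       h_t   = ugc_t * h_{t-1} + (1 - ugc_t) * mc_t

   Note the last line keeps the published gate convention: the update gate
   multiplies the *previous* state and its complement the candidate, which
   is the mirror of the usual GRU wiring.  The two directions have
   independent weights; their states are concatenated into ``u_t``.
3. *Attention*: a two-layer affine map scores each time step,
   ``e_t = psi2 (psi1 u_t + b1) + b2``; a softmax over time turns the
   energies into weights ``alpha`` and the context vector is the convex
   combination ``Cv = sum_t alpha_t u_t``.
4. *Head*: a two-layer perceptron on ``Cv``: a configurable hidden layer
   (tanh by default; softmax and relu selectable) followed by a linear
   layer to 4 scores and a terminal softmax, so the output is a proper
   class distribution for the cross-entropy loss.  A ``faithful`` mode
   reproduces the published wiring with a single softmax-activated hidden
   unit — degenerate, since a softmax over one unit is constantly 1 — and
   exists for comparison only; see ``head_forward`` for why the softmax
   hidden activation is not the default.

Training minimizes the sparse categorical cross-entropy
``-log p[true class]`` averaged over the batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import SkeletonGraph

__all__ = [
    "ModelConfig",
    "ModelParams",
    "gcn_layer",
    "gcn_stack",
    "gated_cell",
    "birnn_encode",
    "attention_energies",
    "attention_weights",
    "context_vector",
    "head_forward",
    "model_forward",
    "sparse_cce_loss",
    "preprocess_coords",
]

_LOG_CLAMP = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (hidden sizes are not printed in the
    method description; these defaults are the package's own choice)."""

    gcn_hidden: int = 64          # F
    gcn_out: int = 16             # Z
    rnn_hidden: int = 64
    head_hidden: int = 16
    head_activation: str = "tanh"  # tanh | relu | softmax (see module docs)
    n_classes: int = 4
    faithful_head: bool = False   # printed wiring: 1-unit softmax first layer
    pool: str = "flatten"         # flatten | mean over nodes
    center: bool = True           # translate to first-frame mid-pelvis, mm->m

    def __post_init__(self):
        if self.pool not in ("flatten", "mean"):
            raise ValueError("pool must be 'flatten' or 'mean'")
        if self.head_activation not in ("tanh", "relu", "softmax"):
            raise ValueError("head_activation must be tanh, relu or softmax")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape or (fan_in, fan_out))


@dataclass
class ModelParams:
    """All trainable weights as named autodiff tensors."""

    weights: dict[str, Tensor]
    config: ModelConfig
    n_nodes: int

    @classmethod
    def init(cls, rng: np.random.Generator, n_nodes: int,
             config: ModelConfig | None = None) -> "ModelParams":
        cfg = config or ModelConfig()
        F, Z, H = cfg.gcn_hidden, cfg.gcn_out, cfg.rnn_hidden
        D = (n_nodes * Z) if cfg.pool == "flatten" else Z
        head_in = 2 * H
        head_h = 1 if cfg.faithful_head else cfg.head_hidden
        w: dict[str, Tensor] = {}

        def param(name, arr):
            w[name] = Tensor(arr, requires_grad=True, name=name)

        param("gcn.psi0", _glorot(rng, 3, F))
        param("gcn.psi1", _glorot(rng, F, F))
        param("gcn.psi2", _glorot(rng, F, Z))
        for d in ("fwd", "bwd"):
            for gate in ("Wu", "Wr", "Wc"):
                param(f"rnn.{d}.{gate}", _glorot(rng, D + H, H))
        param("att.psi1", _glorot(rng, 2 * H, 2 * H))
        param("att.b1", np.zeros(2 * H))
        param("att.psi2", _glorot(rng, 2 * H, 1))
        param("att.b2", np.zeros(1))
        param("head.W1", _glorot(rng, head_in, head_h))
        param("head.b1", np.zeros(head_h))
        param("head.W2", _glorot(rng, head_h, cfg.n_classes))
        param("head.b2", np.zeros(cfg.n_classes))
        return cls(w, cfg, n_nodes)

    def __getitem__(self, k: str) -> Tensor:
        return self.weights[k]

    def as_list(self) -> list[Tensor]:
        return list(self.weights.values())

    def zero_grad(self) -> None:
        for t in self.weights.values():
            t.grad = None

    def copy_data(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.weights.items()}

    def load_data(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.weights[k].data[...] = v

    def save(self, path) -> None:
        """Single-file checkpoint of named weight arrays + architecture."""
        import json

        meta = dict(n_nodes=self.n_nodes, **vars(self.config))
        np.savez(path, __meta__=json.dumps(meta),
                 **{k: v.data for k, v in self.weights.items()})

    @classmethod
    def load(cls, path) -> "ModelParams":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            n_nodes = meta.pop("n_nodes")
            cfg = ModelConfig(**meta)
            rng = np.random.default_rng(0)
            params = cls.init(rng, n_nodes, cfg)
            for k in params.weights:
                params.weights[k].data[...] = z[k]
        return params


# ---------------------------------------------------------------------------
# layers


_ACTIVATIONS = {"relu": ad.relu, "sigmoid": ad.sigmoid, "none": lambda x: x}


def gcn_layer(X, O_hat, W, activation: str = "none") -> Tensor:
    """One graph convolution: ``activation(O_hat @ X @ W)``.

    ``X`` may carry leading batch/time axes; ``O_hat`` broadcasts over them.
    """
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    X = ad.as_tensor(X)
    O_hat = ad.as_tensor(O_hat)
    if X.shape[-2] != O_hat.shape[-1]:
        raise ValueError(f"node axes disagree: X {X.shape} vs O_hat {O_hat.shape}")
    return _ACTIVATIONS[activation](O_hat @ X @ W)


def gcn_stack(X, O_hat, params: ModelParams) -> Tensor:
    """Three-layer spatial encoder; output entries lie in (0, 1)."""
    h = gcn_layer(X, O_hat, params["gcn.psi0"], "none")
    h = gcn_layer(h, O_hat, params["gcn.psi1"], "relu")
    return gcn_layer(h, O_hat, params["gcn.psi2"], "sigmoid")


def gated_cell(x_t, h_prev, Wu, Wr, Wc) -> dict[str, Tensor]:
    """One step of the gated temporal cell (published gate convention)."""
    x_t, h_prev = ad.as_tensor(x_t), ad.as_tensor(h_prev)
    xh = ad.concat([x_t, h_prev], axis=-1)
    ugc = ad.sigmoid(xh @ Wu)
    rgc = ad.sigmoid(xh @ Wr)
    mc = ad.tanh(ad.concat([x_t, rgc * h_prev], axis=-1) @ Wc)
    h_t = ugc * h_prev + (1.0 - ugc) * mc
    return {"ugc": ugc, "rgc": rgc, "mc": mc, "h": h_t}


def birnn_encode(seq: list[Tensor] | Tensor, params: ModelParams) -> Tensor:
    """Bidirectional encoding: ``B x nf x 2H`` concatenated hidden states."""
    if isinstance(seq, Tensor):
        frames = [seq[:, t, :] for t in range(seq.shape[1])]
    else:
        frames = list(seq)
    if not frames:
        raise ValueError("empty sequence")
    B = frames[0].shape[0]
    H = params.config.rnn_hidden
    states = {}
    for d, ordered in (("fwd", frames), ("bwd", frames[::-1])):
        h = Tensor(np.zeros((B, H)))
        out = []
        for x_t in ordered:
            h = gated_cell(x_t, h, params[f"rnn.{d}.Wu"],
                           params[f"rnn.{d}.Wr"], params[f"rnn.{d}.Wc"])["h"]
            out.append(h)
        states[d] = out
    states["bwd"] = states["bwd"][::-1]
    per_t = [ad.concat([f, b], axis=-1).reshape(B, 1, 2 * H)
             for f, b in zip(states["fwd"], states["bwd"])]
    return ad.concat(per_t, axis=1)


def attention_energies(H: Tensor, params: ModelParams) -> Tensor:
    """Two-layer affine score per time step: ``B x nf``."""
    H = ad.as_tensor(H)
    hidden = H @ params["att.psi1"] + params["att.b1"]
    e = hidden @ params["att.psi2"] + params["att.b2"]
    return e.reshape(e.shape[0], e.shape[1])


def attention_weights(e: Tensor) -> Tensor:
    """Softmax over time; shift-invariant, rows sum to 1."""
    return ad.softmax(ad.as_tensor(e), axis=-1)


def context_vector(H: Tensor, alpha: Tensor) -> Tensor:
    """Attention-weighted sum of hidden states: ``B x 2H``."""
    H, alpha = ad.as_tensor(H), ad.as_tensor(alpha)
    if H.shape[1] != alpha.shape[-1]:
        raise ValueError("time axes of H and alpha disagree")
    return (H * alpha.reshape(alpha.shape[0], alpha.shape[1], 1)).sum(axis=1)


def head_forward(Cv: Tensor, params: ModelParams) -> Tensor:
    """Two-layer perceptron head returning class probabilities ``B x 4``.

    The hidden activation is configurable; ``"softmax"`` reproduces the
    published description (and is forced in ``faithful_head`` mode, where
    the hidden width is 1 and the activation is identically 1), but the
    default is tanh: in practice the softmax-activated hidden layer starves
    the upstream network of gradient and lets training collapse to a
    constant representation.
    """
    Cv = ad.as_tensor(Cv)
    pre = Cv @ params["head.W1"] + params["head.b1"]
    act = params.config.head_activation
    if params.config.faithful_head or act == "softmax":
        hidden = ad.softmax(pre, axis=-1)
    elif act == "relu":
        hidden = ad.relu(pre)
    else:
        hidden = ad.tanh(pre)
    scores = hidden @ params["head.W2"] + params["head.b2"]
    return ad.softmax(scores, axis=-1)


def preprocess_coords(coords: np.ndarray, marker_names,
                      config: ModelConfig) -> np.ndarray:
    """Centre on the first-frame mid-pelvis and rescale mm -> m.

    Operates on unpadded per-trial arrays (``T x M x 3``); padded zero
    frames are appended afterwards so they stay exactly zero.
    """
    out = np.asarray(coords, dtype=np.float64)
    if not config.center:
        return out / 1000.0
    pelvis = [marker_names.index(k) for k in ("LASI", "RASI", "LPSI", "RPSI")
              if k in marker_names]
    origin = out[0, pelvis].mean(axis=0) if pelvis else out[0].mean(axis=0)
    return (out - origin) / 1000.0


def model_forward(X, graph: SkeletonGraph, params: ModelParams) -> Tensor:
    """Full forward pass: ``B x nf x M x 3`` padded input to ``B x 4``
    class probabilities."""
    X = ad.as_tensor(X)
    if X.ndim == 3:
        X = X.reshape(1, *X.shape)
    B, nf, M, _ = X.shape
    if M != graph.n_nodes:
        raise ValueError(f"input has {M} markers but graph has {graph.n_nodes}")
    emb = gcn_stack(X, Tensor(graph.O_hat), params)        # B x nf x M x Z
    if params.config.pool == "flatten":
        frames = emb.reshape(B, nf, M * params.config.gcn_out)
    else:
        frames = emb.mean(axis=2)
    H = birnn_encode(frames, params)
    alpha = attention_weights(attention_energies(H, params))
    Cv = context_vector(H, alpha)
    return head_forward(Cv, params)


def sparse_cce_loss(pred: Tensor, labels) -> Tensor:
    """Mean ``-log p[true class]`` with the probability clamped at 1e-12."""
    pred = ad.as_tensor(pred)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim == 0:
        labels = labels[None]
    if (labels < 0).any() or (labels >= pred.shape[-1]).any():
        raise ValueError("label out of range")
    picked = pred[np.arange(len(labels)), labels]
    clamped = picked + _LOG_CLAMP
    return -(ad.log(clamped).mean())
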