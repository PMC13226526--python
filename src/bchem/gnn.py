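"""Chebyshev spectral graph convolution with multi-head attention.

The encoder works on the bipartite disease-drug resistance graph.  Features
propagate through the graph by Chebyshev polynomial filtering of the
normalized symmetric Laplacian,

    L = I - D^{-1/2} A D^{-1/2},     D_ii = sum_j A_ij,

    H^(l+1) = sum_{k=0..K} T_k(L~) H^(l) W_k,

with the polynomials built by the recurrence T_0 = I, T_1 = x,
T_k = 2 x T_{k-1} - T_{k-2}.  L~ is L rescaled to the Chebyshev-stable
interval [-1, 1] via 2L/lambda_max - I with lambda_max taken as its upper
bound 2 (the raw Laplacian is available for the literal, unscaled filter).

A dense multi-head scaled dot-product attention block then reweights node
pairs across the whole graph:

    Att_h = softmax(Q_h K_h^T / sqrt(d_k)) V_h,   d_k = C / H,

heads concatenated and mixed by an output map, with a residual connection
around the block.  Training is end-to-end supervised link prediction: a
bilinear scoring head on (disease, drug) embedding pairs under binary
cross-entropy, optimized with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .attributes import AttributeMatrix
from .data import AdjacencyMatrix
from .errors import SingleClassError

__all__ = [
    "LaplacianMatrix",
    "ChebLayerParams",
    "AttentionParams",
    "ChebAttnModel",
    "ModelConfig",
    "normalized_laplacian",
    "cheb_conv_forward",
    "multi_head_attention",
    "attention_weights",
    "model_forward",
    "train_model",
    "init_model",
    "save_model",
    "load_model",
]


@dataclass
class LaplacianMatrix:
    """Normalized symmetric graph Laplacian, optionally shifted to [-1, 1]."""

    values: np.ndarray
    scaled: bool


@dataclass
class ChebLayerParams:
    """One Chebyshev convolution layer: K+1 filter weight matrices W_k."""

    order_K: int
    weights: list[np.ndarray]  # K+1 matrices, each (in_dim, out_dim)
    layer_index: int = 0

    def __post_init__(self) -> None:
        if len(self.weights) != self.order_K + 1:
            raise ValueError(
                f"expected {self.order_K + 1} weight matrices, got {len(self.weights)}"
            )


@dataclass
class AttentionParams:
    """Per-head Q/K/V projections plus the head-mixing output map."""

    n_heads: int
    W_q: list[np.ndarray]  # per head, (C, d_k)
    W_k: list[np.ndarray]
    W_v: list[np.ndarray]
    W_out: np.ndarray  # (H * d_k, C)

    @property
    def head_dim(self) -> int:
        return int(self.W_q[0].shape[1])


@dataclass
class ModelConfig:
    """Hyperparameters of the graph encoder and its training loop."""

    cheb_order: int = 2
    n_layers: int = 2
    n_heads: int = 2
    embed_dim: int = 32
    epochs: int = 200
    lr: float = 1e-3
    scaled_laplacian: bool = True
    use_attention: bool = True

    def to_file(self, path) -> None:
        import json
        from dataclasses import asdict

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "ModelConfig":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ChebAttnModel:
    """All parameters of the encoder plus the training-time link head."""

    config: ModelConfig
    n_diseases: int
    input_maps: dict  # modality -> {"W": (attr_dim, C), "b": (C,)}
    layers: list[ChebLayerParams]
    attention: AttentionParams | None
    link_bilinear: np.ndarray = field(default=None)  # (C, C)
    link_bias: float = 0.0
    loss_history: list[float] = field(default_factory=list)

    @property
    def embed_dim(self) -> int:
        return self.config.embed_dim


def save_model(model: ChebAttnModel, path) -> None:
    """Checkpoint all parameter tensors plus the config (and its hash) to .npz."""
    import hashlib
    import json
    from dataclasses import asdict

    arrays: dict[str, np.ndarray] = {}
    for mod, m in model.input_maps.items():
        arrays[f"input.{mod}.W"] = m["W"]
        arrays[f"input.{mod}.b"] = m["b"]
    for layer in model.layers:
        for k, W in enumerate(layer.weights):
            arrays[f"layer{layer.layer_index}.W{k}"] = W
    if model.attention is not None:
        for h in range(model.attention.n_heads):
            arrays[f"attn.Wq{h}"] = model.attention.W_q[h]
            arrays[f"attn.Wk{h}"] = model.attention.W_k[h]
            arrays[f"attn.Wv{h}"] = model.attention.W_v[h]
        arrays["attn.Wout"] = model.attention.W_out
    arrays["link.B"] = model.link_bilinear
    arrays["link.b"] = np.array([model.link_bias])
    config = asdict(model.config)
    config["n_diseases"] = model.n_diseases
    blob = json.dumps(config, sort_keys=True)
    arrays["config_json"] = np.frombuffer(blob.encode(), dtype=np.uint8)
    arrays["config_hash"] = np.frombuffer(
        hashlib.sha256(blob.encode()).hexdigest().encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> ChebAttnModel:
    """Restore a checkpoint written by :func:`save_model`."""
    import json

    data = np.load(path)
    config = json.loads(bytes(data["config_json"]).decode())
    n_diseases = config.pop("n_diseases")
    cfg = ModelConfig(**config)
    input_maps = {
        mod: {"W": data[f"input.{mod}.W"], "b": data[f"input.{mod}.b"]}
        for mod in ("disease", "drug")
    }
    layers = [
        ChebLayerParams(
            order_K=cfg.cheb_order,
            weights=[data[f"layer{l}.W{k}"] for k in range(cfg.cheb_order + 1)],
            layer_index=l,
        )
        for l in range(cfg.n_layers)
    ]
    attention = None
    if cfg.use_attention:
        attention = AttentionParams(
            n_heads=cfg.n_heads,
            W_q=[data[f"attn.Wq{h}"] for h in range(cfg.n_heads)],
            W_k=[data[f"attn.Wk{h}"] for h in range(cfg.n_heads)],
            W_v=[data[f"attn.Wv{h}"] for h in range(cfg.n_heads)],
            W_out=data["attn.Wout"],
        )
    return ChebAttnModel(
        config=cfg,
        n_diseases=n_diseases,
        input_maps=input_maps,
        layers=layers,
        attention=attention,
        link_bilinear=data["link.B"],
        link_bias=float(data["link.b"][0]),
    )


def normalized_laplacian(A: AdjacencyMatrix, scale: bool = True) -> LaplacianMatrix:
    """L = I - D^{-1/2} A D^{-1/2}; optionally rescaled to 2L/lambda_max - I.

    Isolated nodes (zero degree) use d^{-1/2} := 0, so a fully empty graph
    yields L = I.  lambda_max is taken as its theoretical bound 2, the usual
    convention for Chebyshev filters.
    """
    M = A.dense()
    if not np.allclose(M, M.T):
        raise ValueError("adjacency matrix must be symmetric")
    deg = M.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    L = np.eye(M.shape[0]) - (d_inv_sqrt[:, None] * M) * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    if scale:
        L = L - np.eye(M.shape[0])  # 2L/2 - I
        return LaplacianMatrix(values=L, scaled=True)
    return LaplacianMatrix(values=L, scaled=False)


def _cheb_terms(L: np.ndarray, H: Tensor, K: int) -> list[Tensor]:
    """T_k(L) @ H for k = 0..K via the recurrence on matrix-feature products."""
    Lt = Tensor(L)
    terms = [H]
    if K >= 1:
        terms.append(Lt @ H)
    for _ in range(2, K + 1):
        terms.append(2.0 * (Lt @ terms[-1]) - terms[-2])
    return terms


def cheb_conv_forward(
    H_in: np.ndarray, L: LaplacianMatrix, params: ChebLayerParams
) -> np.ndarray:
    """One Chebyshev filter pass: sum_k T_k(L) H W_k.

    The recurrence acts on (T_k L @ H) products, never materializing matrix
    powers of L.
    """
    H = np.asarray(H_in, dtype=float)
    if L.values.shape[0] != H.shape[0]:
        raise ValueError(
            f"L is {L.values.shape[0]}x{L.values.shape[0]} but H has {H.shape[0]} rows"
        )
    if H.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"feature dim {H.shape[1]} does not match W_0 rows {params.weights[0].shape[0]}"
        )
    out = _cheb_layer(Tensor(H), L.values, [Tensor(W) for W in params.weights])
    return out.value


def _cheb_layer(H: Tensor, L: np.ndarray, weights: list[Tensor]) -> Tensor:
    terms = _cheb_terms(L, H, len(weights) - 1)
    out = terms[0] @ weights[0]
    for Tk, Wk in zip(terms[1:], weights[1:]):
        out = out + Tk @ Wk
    return out


def _attention_forward(
    X: Tensor, W_q: list[Tensor], W_k: list[Tensor], W_v: list[Tensor], W_out: Tensor
) -> Tensor:
    d_k = W_q[0].shape[1]
    heads = []
    for q, k, v in zip(W_q, W_k, W_v):
        Q, K_, V = X @ q, X @ k, X @ v
        A = ad.softmax((Q @ K_.T) / np.sqrt(d_k), axis=-1)
        heads.append(A @ V)
    return ad.concat(heads, axis=-1) @ W_out


def multi_head_attention(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Dense scaled dot-product attention over all node pairs.

    Per head h: softmax(Q_h K_h^T / sqrt(d_k)) V_h; head outputs are
    concatenated on the feature axis and mixed by W_out, preserving the
    feature dimension C.
    """
    X = np.asarray(X, dtype=float)
    C = X.shape[1]
    if C % params.n_heads != 0:
        raise ValueError(f"feature dim {C} not divisible by {params.n_heads} heads")
    out = _attention_forward(
        Tensor(X),
        [Tensor(w) for w in params.W_q],
        [Tensor(w) for w in params.W_k],
        [Tensor(w) for w in params.W_v],
        Tensor(params.W_out),
    )
    return out.value


def attention_weights(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Row-stochastic attention weight matrices, one (n, n) slab per head."""
    X = np.asarray(X, dtype=float)
    d_k = params.head_dim
    slabs = []
    for q, k in zip(params.W_q, params.W_k):
        S = (X @ q) @ (X @ k).T / np.sqrt(d_k)
        S = S - S.max(axis=1, keepdims=True)
        E = np.exp(S)
        slabs.append(E / E.sum(axis=1, keepdims=True))
    return np.stack(slabs)


# -- model construction / forward / training --------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_model(
    attr_dims: dict[str, int] | int,
    n_diseases: int,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> ChebAttnModel:
    """Seeded parameter initialization (Glorot-uniform weights, zero biases).

    ``attr_dims`` is either one shared attribute dimension or a
    ``{"disease": d1, "drug": d2}`` mapping when the modalities differ.
    """
    config = config or ModelConfig()
    if isinstance(attr_dims, int):
        attr_dims = {"disease": attr_dims, "drug": attr_dims}
    rng = np.random.default_rng(seed)
    C = config.embed_dim
    input_maps = {
        mod: {"W": _glorot(rng, (dim, C)), "b": np.zeros(C)}
        for mod, dim in attr_dims.items()
    }
    layers = [
        ChebLayerParams(
            order_K=config.cheb_order,
            weights=[_glorot(rng, (C, C)) for _ in range(config.cheb_order + 1)],
            layer_index=l,
        )
        for l in range(config.n_layers)
    ]
    attention = None
    if config.use_attention:
        H = config.n_heads
        if C % H != 0:
            raise ValueError(f"embed_dim {C} not divisible by n_heads {H}")
        d_k = C // H
        attention = AttentionParams(
            n_heads=H,
            W_q=[_glorot(rng, (C, d_k)) for _ in range(H)],
            W_k=[_glorot(rng, (C, d_k)) for _ in range(H)],
            W_v=[_glorot(rng, (C, d_k)) for _ in range(H)],
            W_out=_glorot(rng, (H * d_k, C)),
        )
    return ChebAttnModel(
        config=config,
        n_diseases=n_diseases,
        input_maps=input_maps,
        layers=layers,
        attention=attention,
        link_bilinear=_glorot(rng, (C, C)),
        link_bias=0.0,
    )


def _collect_tensors(model: ChebAttnModel) -> tuple[dict, list[Tensor]]:
    """Wrap every model parameter in a trainable Tensor; return the wiring."""
    params: list[Tensor] = []

    def wrap(arr):
        t = Tensor(np.array(arr, dtype=float), requires_grad=True)
        params.append(t)
        return t

    wiring = {
        "input_maps": {
            mod: {"W": wrap(m["W"]), "b": wrap(m["b"])}
            for mod, m in model.input_maps.items()
        },
        "layers": [[wrap(W) for W in layer.weights] for layer in model.layers],
        "attention": None,
        "link_B": wrap(model.link_bilinear),
        "link_b": wrap(np.array([model.link_bias])),
    }
    if model.attention is not None:
        att = model.attention
        wiring["attention"] = {
            "W_q": [wrap(w) for w in att.W_q],
            "W_k": [wrap(w) for w in att.W_k],
            "W_v": [wrap(w) for w in att.W_v],
            "W_out": wrap(att.W_out),
        }
    return wiring, params


def _forward(wiring: dict, model: ChebAttnModel, H0: np.ndarray, L: np.ndarray) -> Tensor:
    nd = model.n_diseases
    Xd = Tensor(H0[:nd])
    Xr = Tensor(H0[nd:])
    im_d, im_r = wiring["input_maps"]["disease"], wiring["input_maps"]["drug"]
    X = ad.concat([Xd @ im_d["W"] + im_d["b"], Xr @ im_r["W"] + im_r["b"]], axis=0)
    for layer_weights in wiring["layers"]:
        X = ad.relu(_cheb_layer(X, L, layer_weights))
    if wiring["attention"] is not None:
        att = wiring["attention"]
        X = X + _attention_forward(X, att["W_q"], att["W_k"], att["W_v"], att["W_out"])
    return X


def model_forward(
    model: ChebAttnModel, H0: AttributeMatrix | np.ndarray, L: LaplacianMatrix
) -> np.ndarray:
    """Deterministic forward pass: (n_nodes, C) node embeddings."""
    H = H0.values if isinstance(H0, AttributeMatrix) else np.asarray(H0, dtype=float)
    if H.shape[0] != L.values.shape[0]:
        raise ValueError(
            f"attribute rows ({H.shape[0]}) != Laplacian size ({L.values.shape[0]})"
        )
    wiring, _ = _collect_tensors(model)
    return _forward(wiring, model, H, L.values).value


def _link_logits(
    emb: Tensor, pairs: np.ndarray, n_diseases: int, B: Tensor, b: Tensor
) -> Tensor:
    """Bilinear pair score: e_d^T B e_r + b for each (disease, drug) pair."""
    Ed = emb[pairs[:, 0]]
    Er = emb[n_diseases + pairs[:, 1]]
    return ((Ed @ B) * Er).sum(axis=1) + b


def train_model(
    model: ChebAttnModel,
    H0: AttributeMatrix | np.ndarray,
    L: LaplacianMatrix,
    pairs: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
) -> ChebAttnModel:
    """Train the encoder end-to-end on link labels (in place; returns model).

    ``pairs`` holds (disease position, drug position) rows; ``labels`` are
    1 = resistance, 0 = sensitivity.  Full-graph, full-batch BCE on the
    bilinear link head, Adam, fixed epoch budget; deterministic given the
    initialization (already seeded) and inputs.  The Laplacian must be built
    from training-fold resistance edges only — held-out edges leaking into L
    would let test links score themselves.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("training pairs must contain both classes")
    H = H0.values if isinstance(H0, AttributeMatrix) else np.asarray(H0, dtype=float)
    pairs = np.asarray(pairs, dtype=int)
    wiring, params = _collect_tensors(model)
    opt = ad.Adam(params, lr=model.config.lr)
    model.loss_history = []
    for _ in range(model.config.epochs):
        opt.zero_grad()
        emb = _forward(wiring, model, H, L.values)
        logits = _link_logits(emb, pairs, model.n_diseases, wiring["link_B"], wiring["link_b"])
        loss = ad.binary_cross_entropy_with_logits(logits, labels)
        loss.backward()
        opt.step()
        model.loss_history.append(float(loss.value))
    _write_back(wiring, model)
    return model


def score_pairs(
    model: ChebAttnModel, emb: np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """Sigmoid link-head scores in [0, 1] for (disease, drug) position pairs."""
    pairs = np.asarray(pairs, dtype=int)
    Ed = emb[pairs[:, 0]]
    Er = emb[model.n_diseases + pairs[:, 1]]
    z = np.einsum("ij,jk,ik->i", Ed, model.link_bilinear, Er) + model.link_bias
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _write_back(wiring: dict, model: ChebAttnModel) -> None:
    for mod in model.input_maps:
        model.input_maps[mod]["W"] = wiring["input_maps"][mod]["W"].value
        model.input_maps[mod]["b"] = wiring["input_maps"][mod]["b"].value
    for layer, weights in zip(model.layers, wiring["layers"]):
        layer.weights = [w.value for w in weights]
    if model.attention is not None:
        att = wiring["attention"]
        model.attention.W_q = [w.value for w in att["W_q"]]
        model.attention.W_k = [w.value for w in att["W_k"]]
        model.attention.W_v = [w.value for w in att["W_v"]]
        model.attention.W_out = att["W_out"].value
    model.link_bilinear = wiring["link_B"].value
    model.link_bias = float(wiring["link_b"].value[0])
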