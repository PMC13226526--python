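"""Initial node attribute matrices.

Three interchangeable backends feed the graph encoder with per-node feature
vectors H0:

``encoder``
    Pooled embeddings from an external text/chemistry encoder (disease
    descriptions through a biomedical language model, drug SMILES through a
    chemical language model).  Encoders are reached through a thin adapter
    contract so the library itself stays offline; a deterministic hash-seeded
    mock adapter ships for testing, and precomputed embedding matrices can be
    loaded from delimited files.

``svd``
    Topology-only features: rows of U * diag(sigma) from the truncated SVD of
    the adjacency matrix.

``random``
    Seeded i.i.d. standard-normal vectors (the uninformative baseline).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .data import AdjacencyMatrix, DDRNetwork
from .errors import MissingAttributeError

BACKENDS = ("encoder", "svd", "random")


@dataclass
class EncoderOutput:
    """Per-token vectors plus the pooled sequence representation.

    The pooled vector is the output at the pooling position (first / [CLS]
    token by convention), so ``pooled == token_vectors[0]``.
    """

    token_vectors: np.ndarray  # (n_tokens, encoder_dim)
    pooled: np.ndarray  # (encoder_dim,)

    @property
    def encoder_dim(self) -> int:
        return int(self.token_vectors.shape[1])


@dataclass
class AttributeMatrix:
    """Per-node initial features, row order following the network node index."""

    values: np.ndarray  # (n_nodes, attr_dim)
    backend: str

    @property
    def attr_dim(self) -> int:
        return int(self.values.shape[1])

    @property
    def n_nodes(self) -> int:
        return int(self.values.shape[0])


class EncoderAdapter(Protocol):
    """Contract for external sequence encoders.

    Given a list of strings, return one :class:`EncoderOutput` per string.
    Tokenization, truncation and model specifics are the adapter's business.
    """

    def encode(self, texts: Sequence[str]) -> list[EncoderOutput]: ...


class HashEncoderAdapter:
    """Deterministic offline stand-in for a pre-trained sequence encoder.

    Synthetic adapter: each whitespace token maps to a Gaussian vector seeded
    by the token's hash, and a leading [CLS] position carries the mean of the
    content-token vectors, so pooling behaves like a real encoder's sequence
    summary while remaining fully reproducible with no model weights.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self.seed = seed

    def _token_vector(self, token: str) -> np.ndarray:
        h = hashlib.sha256(f"{self.seed}:{token}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(h[:4], "little"))
        return rng.standard_normal(self.dim)

    def encode(self, texts: Sequence[str]) -> list[EncoderOutput]:
        outputs = []
        for text in texts:
            tokens = text.split() or ["<empty>"]
            content = np.stack([self._token_vector(t) for t in tokens])
            cls = content.mean(axis=0)
            token_vectors = np.vstack([cls[None, :], content])
            outputs.append(EncoderOutput(token_vectors=token_vectors, pooled=cls))
        return outputs


def pool_cls_embedding(output: EncoderOutput, mode: str = "cls") -> np.ndarray:
    """Pool token vectors into one sequence vector.

    Default is first-position ([CLS]) extraction; ``mode='mean'`` averages
    all token vectors instead.
    """
    if output.token_vectors.shape[0] == 0:
        raise ValueError("cannot pool an empty token sequence")
    if mode == "cls":
        return np.asarray(output.token_vectors[0])
    if mode == "mean":
        return np.asarray(output.token_vectors.mean(axis=0))
    raise ValueError(f"unknown pooling mode: {mode!r}")


def svd_topology_features(A: AdjacencyMatrix, dim: int) -> AttributeMatrix:
    """Topology features from the truncated SVD of the adjacency matrix.

    Row i is the i-th row of U * diag(sigma) restricted to the top-``dim``
    singular triplets.  Columns past the matrix rank are zero.  The sign of
    each singular vector is fixed by forcing its largest-magnitude entry
    positive, making the features reproducible across LAPACK builds.
    """
    if dim <= 0:
        raise ValueError(f"dim must be >= 1, got {dim}")
    M = A.dense()
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    keep = min(dim, rank)
    feats = np.zeros((M.shape[0], dim))
    for j in range(keep):
        u = U[:, j]
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
        feats[:, j] = u * s[j]
    return AttributeMatrix(values=feats, backend="svd")


def random_features(n_nodes: int, dim: int, seed: int) -> AttributeMatrix:
    """Seeded i.i.d. standard-normal features (uninformative baseline)."""
    if n_nodes < 1 or dim < 1:
        raise ValueError(f"n_nodes and dim must be >= 1, got ({n_nodes}, {dim})")
    rng = np.random.default_rng(seed)
    return AttributeMatrix(
        values=rng.standard_normal((n_nodes, dim)), backend="random"
    )


def _seeded_projection(in_dim: int, out_dim: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((in_dim, out_dim)) / np.sqrt(in_dim)


def assemble_attributes(
    network: DDRNetwork,
    disease_vectors: Mapping[str, np.ndarray],
    drug_vectors: Mapping[str, np.ndarray],
    common_dim: int | None = None,
    seed: int = 0,
) -> AttributeMatrix:
    """Stack per-disease and per-drug vectors into the node-ordered H0.

    Rows follow the network node index (diseases first).  When the two
    modalities disagree in dimension, each passes through its own seeded
    Gaussian linear map to ``common_dim`` before stacking; downstream the
    graph model's per-modality input maps continue adapting these features
    during training.
    """
    for d in network.diseases:
        if d not in disease_vectors:
            raise MissingAttributeError(f"missing attribute for disease {d}")
    for r in network.drugs:
        if r not in drug_vectors:
            raise MissingAttributeError(f"missing attribute for drug {r}")
    Xd = np.stack([np.asarray(disease_vectors[d], dtype=float) for d in network.diseases])
    Xr = np.stack([np.asarray(drug_vectors[r], dtype=float) for r in network.drugs])
    if Xd.shape[1] != Xr.shape[1] or (
        common_dim is not None and Xd.shape[1] != common_dim
    ):
        if common_dim is None:
            raise ValueError(
                "disease/drug vector dims differ "
                f"({Xd.shape[1]} vs {Xr.shape[1]}); pass common_dim"
            )
        Xd = Xd @ _seeded_projection(Xd.shape[1], common_dim, seed)
        Xr = Xr @ _seeded_projection(Xr.shape[1], common_dim, seed + 1)
    return AttributeMatrix(values=np.vstack([Xd, Xr]), backend="encoder")


def encode_node_attributes(
    network: DDRNetwork,
    disease_texts: Mapping[str, str],
    drug_smiles: Mapping[str, str],
    adapter: EncoderAdapter,
    common_dim: int | None = None,
    pooling: str = "cls",
    seed: int = 0,
) -> AttributeMatrix:
    """Run both modalities through an encoder adapter and assemble H0."""
    d_out = adapter.encode([disease_texts[d] for d in network.diseases])
    r_out = adapter.encode([drug_smiles[r] for r in network.drugs])
    dvec = {
        d: pool_cls_embedding(o, mode=pooling)
        for d, o in zip(network.diseases, d_out)
    }
    rvec = {
        r: pool_cls_embedding(o, mode=pooling)
        for r, o in zip(network.drugs, r_out)
    }
    return assemble_attributes(network, dvec, rvec, common_dim=common_dim, seed=seed)


def load_descriptions(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Load two-column (node id, free text) delimited descriptions.

    A header line ``disease_id<sep>description`` is accepted and skipped.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            node_id, _, text = line.partition(sep)
            if i == 0 and node_id.lower() in ("disease_id", "node_id", "id"):
                continue
            out[node_id] = text
    return out


def load_embedding_file(path: str | Path, sep: str = "\t") -> dict[str, np.ndarray]:
    """Load a delimited per-node embedding matrix (node id in column 1)."""
    df = pd.read_csv(path, sep=sep, header=None, dtype={0: str})
    return {
        str(row[0]): np.asarray(row[1:], dtype=float) for row in df.itertuples(index=False)
    }


def save_embedding_file(
    vectors: Mapping[str, np.ndarray], path: str | Path, sep: str = "\t"
) -> None:
    with open(path, "w") as fh:
        for node_id, vec in vectors.items():
            fh.write(node_id + sep + sep.join(f"{v:.10g}" for v in vec) + "\n")
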