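"""Message-passing molecular encoders (GIN, GCN, GraphSAGE) on NumPy.

The default encoder is a five-layer, 300-dimensional GIN with edge
features: each layer computes ``h_v <- MLP(h_v + sum_{u in N(v)} (h_u +
e_uv))`` followed by batch normalisation and (except after the last
layer) a ReLU.  Graph embeddings are a permutation-invariant readout
(mean by default) over node embeddings, and a two-layer MLP projection
head maps graph embeddings to the space where contrastive losses are
computed.

Parameters live in a flat name->array registry (:class:`EncoderParams`)
so that they can be snapshotted, perturbed layer-by-layer, checkpointed
and optimised without any framework machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .autodiff import Tensor
from .molgraph import FeatureVocab, MolecularGraph

__all__ = [
    "EncoderConfig",
    "EncoderParams",
    "EmbeddingSet",
    "GraphBatch",
    "init_params",
    "encode",
    "forward_batch",
    "make_batch",
    "cosine_similarity",
    "is_perturbable",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class EncoderConfig:
    backbone: Literal["gin", "gcn", "graphsage"] = "gin"
    num_layers: int = 5
    hidden_dim: int = 300
    readout: Literal["mean", "sum", "max"] = "mean"
    dropout_rate: float = 0.0
    projection_hidden_dim: int = 300
    projection_out_dim: int = 300

    def __post_init__(self) -> None:
        if self.num_layers < 1 or self.hidden_dim < 1:
            raise ValueError("num_layers and hidden_dim must be >= 1")
        if self.backbone not in ("gin", "gcn", "graphsage"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.readout not in ("mean", "sum", "max"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


class EncoderParams:
    """Flat registry of named weight arrays plus batch-norm buffers.

    ``params`` hold everything the optimiser updates; ``buffers`` hold the
    batch-norm running statistics (not optimised, not perturbed).
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        buffers: dict[str, np.ndarray],
        config: EncoderConfig,
        vocab: FeatureVocab,
    ):
        self.params = params
        self.buffers = buffers
        self.config = config
        self.vocab = vocab

    def copy(self) -> "EncoderParams":
        """Deep copy sharing no storage with the original."""
        return EncoderParams(
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.buffers.items()},
            self.config,
            self.vocab,
        )

    def names(self) -> list[str]:
        return list(self.params)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.params.values()))


@dataclass
class GraphBatch:
    """A batch of molecular graphs packed into flat arrays."""

    node_features: np.ndarray  # N x 2
    edge_index: np.ndarray  # 2 x E (node indices offset per graph)
    edge_features: np.ndarray  # E x 2
    graph_membership: np.ndarray  # N, graph index of each node
    num_graphs: int


@dataclass
class EmbeddingSet:
    node_embeddings: np.ndarray
    graph_embeddings: np.ndarray
    projections: np.ndarray
    graph_membership: np.ndarray


def is_perturbable(name: str) -> bool:
    """Whether a registry entry is a GNN layer weight (the perturbed subset).

    Feature-embedding tables, the projection head and the reconstruction
    head are excluded: only the message/update weights of the encoder
    layers (including their batch-norm affine parameters) are perturbed.
    """
    return name.startswith("layer")


def make_batch(graphs: Sequence[MolecularGraph]) -> GraphBatch:
    if not graphs:
        raise ValueError("empty batch")
    node_feats, edge_idx, edge_feats, membership = [], [], [], []
    offset = 0
    for i, g in enumerate(graphs):
        node_feats.append(g.node_features)
        edge_idx.append(g.edge_index + offset)
        edge_feats.append(g.edge_features)
        membership.append(np.full(g.num_nodes, i, dtype=np.int64))
        offset += g.num_nodes
    return GraphBatch(
        node_features=np.concatenate(node_feats, axis=0),
        edge_index=np.concatenate(edge_idx, axis=1),
        edge_features=np.concatenate(edge_feats, axis=0).reshape(-1, 2),
        graph_membership=np.concatenate(membership),
        num_graphs=len(graphs),
    )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: EncoderConfig, vocab: FeatureVocab, seed: int) -> EncoderParams:
    """Deterministic Glorot-uniform initialisation of the full registry."""
    rng = np.random.default_rng(seed)
    d = config.hidden_dim
    p: dict[str, np.ndarray] = {}
    b: dict[str, np.ndarray] = {}

    p["embed.atom_type"] = _glorot(rng, vocab.atom_type_count, d)
    p["embed.chirality"] = _glorot(rng, vocab.chirality_count, d)
    for layer in range(config.num_layers):
        p[f"embed.bond_type.layer{layer}"] = _glorot(rng, vocab.bond_type_count, d)
        p[f"embed.bond_dir.layer{layer}"] = _glorot(rng, vocab.bond_dir_count, d)
        if config.backbone == "gin":
            p[f"layer{layer}.mlp.w1"] = _glorot(rng, d, 2 * d)
            p[f"layer{layer}.mlp.b1"] = np.zeros(2 * d)
            p[f"layer{layer}.mlp.w2"] = _glorot(rng, 2 * d, d)
            p[f"layer{layer}.mlp.b2"] = np.zeros(d)
        elif config.backbone == "gcn":
            p[f"layer{layer}.w"] = _glorot(rng, d, d)
            p[f"layer{layer}.b"] = np.zeros(d)
        else:  # graphsage
            p[f"layer{layer}.w_self"] = _glorot(rng, d, d)
            p[f"layer{layer}.w_neigh"] = _glorot(rng, d, d)
            p[f"layer{layer}.b"] = np.zeros(d)
        p[f"layer{layer}.bn.gamma"] = np.ones(d)
        p[f"layer{layer}.bn.beta"] = np.zeros(d)
        b[f"layer{layer}.bn.running_mean"] = np.zeros(d)
        b[f"layer{layer}.bn.running_var"] = np.ones(d)

    p["proj.w1"] = _glorot(rng, d, config.projection_hidden_dim)
    p["proj.b1"] = np.zeros(config.projection_hidden_dim)
    p["proj.w2"] = _glorot(rng, config.projection_hidden_dim, config.projection_out_dim)
    p["proj.b2"] = np.zeros(config.projection_out_dim)
    p["recon.w"] = _glorot(rng, d, vocab.num_real_atom_types)
    p["recon.b"] = np.zeros(vocab.num_real_atom_types)
    return EncoderParams(p, b, config, vocab)


def _batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    train: bool,
    update_stats: bool,
) -> Tensor:
    if train:
        if update_stats:
            mean = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            running_mean *= 1.0 - _BN_MOMENTUM
            running_mean += _BN_MOMENTUM * mean
            running_var *= 1.0 - _BN_MOMENTUM
            running_var += _BN_MOMENTUM * var
        return x.batchnorm(gamma, beta, eps=_BN_EPS)
    scale = 1.0 / np.sqrt(running_var + _BN_EPS)
    x_hat = (x - Tensor(running_mean)) * Tensor(scale)
    return x_hat * gamma + beta


def wrap_params(params: EncoderParams) -> dict[str, Tensor]:
    """Wrap every registry array in a gradient-tracking :class:`Tensor`."""
    return {k: Tensor(v, requires_grad=True) for k, v in params.params.items()}


def forward_batch(
    t: dict[str, Tensor],
    batch: GraphBatch,
    params: EncoderParams,
    *,
    train: bool = False,
    update_stats: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor, Tensor]:
    """Differentiable forward pass over a packed batch.

    ``t`` is a Tensor view of ``params.params`` (see :func:`wrap_params`);
    passing it explicitly lets callers reuse one wrapping across the
    several forward passes of a training step so gradients accumulate in
    a single place.  Returns ``(node_embeddings, graph_embeddings,
    projections)`` as Tensors.
    """
    config = params.config
    n_nodes = batch.node_features.shape[0]
    src, dst = batch.edge_index
    has_edges = src.size > 0

    h = t["embed.atom_type"].take_rows(batch.node_features[:, 0]) + t[
        "embed.chirality"
    ].take_rows(batch.node_features[:, 1])

    for layer in range(config.num_layers):
        if has_edges:
            e = t[f"embed.bond_type.layer{layer}"].take_rows(batch.edge_features[:, 0]) + t[
                f"embed.bond_dir.layer{layer}"
            ].take_rows(batch.edge_features[:, 1])
            msg = h.take_rows(src) + e

        if config.backbone == "gin":
            agg = msg.segment_sum(dst, n_nodes) if has_edges else Tensor(np.zeros(h.shape))
            pre = h + agg  # epsilon = 0
            hidden = (pre @ t[f"layer{layer}.mlp.w1"] + t[f"layer{layer}.mlp.b1"]).relu()
            out = hidden @ t[f"layer{layer}.mlp.w2"] + t[f"layer{layer}.mlp.b2"]
        elif config.backbone == "gcn":
            deg = np.bincount(dst, minlength=n_nodes).astype(np.float64) + 1.0
            if has_edges:
                norm = 1.0 / np.sqrt(deg[src] * deg[dst])
                agg = (msg * Tensor(norm[:, None])).segment_sum(dst, n_nodes)
            else:
                agg = Tensor(np.zeros(h.shape))
            agg = agg + h * Tensor((1.0 / deg)[:, None])
            out = agg @ t[f"layer{layer}.w"] + t[f"layer{layer}.b"]
        else:  # graphsage
            neigh = msg.segment_mean(dst, n_nodes) if has_edges else Tensor(np.zeros(h.shape))
            out = (
                h @ t[f"layer{layer}.w_self"]
                + neigh @ t[f"layer{layer}.w_neigh"]
                + t[f"layer{layer}.b"]
            )

        out = _batchnorm(
            out,
            t[f"layer{layer}.bn.gamma"],
            t[f"layer{layer}.bn.beta"],
            params.buffers[f"layer{layer}.bn.running_mean"],
            params.buffers[f"layer{layer}.bn.running_var"],
            train,
            update_stats,
        )
        if layer < config.num_layers - 1:
            out = out.relu()
        if train and config.dropout_rate > 0.0 and dropout_rng is not None:
            keep = (dropout_rng.random(out.shape) >= config.dropout_rate).astype(np.float64)
            out = out * Tensor(keep / (1.0 - config.dropout_rate))
        h = out

    seg = batch.graph_membership
    if config.readout == "mean":
        h_graph = h.segment_mean(seg, batch.num_graphs)
    elif config.readout == "sum":
        h_graph = h.segment_sum(seg, batch.num_graphs)
    else:
        h_graph = h.segment_max(seg, batch.num_graphs)

    z = (h_graph @ t["proj.w1"] + t["proj.b1"]).relu() @ t["proj.w2"] + t["proj.b2"]
    return h, h_graph, z


def encode(
    graphs: Sequence[MolecularGraph],
    params: EncoderParams,
    config: EncoderConfig | None = None,
) -> EmbeddingSet:
    """Inference-mode embedding of a batch of graphs.

    Batch normalisation uses the stored running statistics, so the result
    for each graph is independent of what else is in the batch.
    """
    if config is not None and config != params.config:
        params = EncoderParams(params.params, params.buffers, config, params.vocab)
    batch = make_batch(graphs)
    t = {k: Tensor(v) for k, v in params.params.items()}
    h, h_graph, z = forward_batch(t, batch, params, train=False)
    return EmbeddingSet(
        node_embeddings=h.data,
        graph_embeddings=h_graph.data,
        projections=z.data,
        graph_membership=batch.graph_membership,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two vectors; defined as 0 if either is zero."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))
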