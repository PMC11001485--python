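"""Attribute-masking contrastive learning (MaskGCL).

The module supplies the two halves of the hybrid objective: a node-level
attribute-reconstruction loss (predict the atom type of masked nodes from
their contextual embeddings through a single affine head) and a
graph-level NT-Xent contrastive loss between a molecule and its masked
view, combined as ``alpha * L_mask + (1 - alpha) * L_cl``.

The NT-Xent here uses, as negatives for anchor i, the partner views of
all other graphs in the batch; the denominator excludes the positive
term, so the loss can be negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .molgraph import FeatureVocab, MolecularGraph

logger = logging.getLogger(__name__)

__all__ = [
    "MaskConfig",
    "MaskedView",
    "mask_attributes",
    "cross_entropy_logits",
    "reconstruction_loss",
    "nt_xent",
    "maskgcl_loss",
]


@dataclass(frozen=True)
class MaskConfig:
    """How many node attributes to mask per graph.

    ``k = max(min_masked, floor(mask_rate * |V| + 0.5))`` nodes are chosen
    uniformly without replacement (k = 0 when mask_rate is 0; k clamps to
    |V|).  With ``mask_edges`` set, the same fraction of bonds also has
    its bond-type replaced by the edge mask token; edge attributes are
    never reconstructed.
    """

    mask_rate: float = 0.15
    min_masked: int = 1
    mask_edges: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must lie in [0, 1]")


@dataclass
class MaskedView:
    graph: MolecularGraph
    masked_node_indices: np.ndarray
    withheld_labels: np.ndarray  # original atom-type indices of the masked nodes


def _num_masked(mask_rate: float, min_masked: int, n: int) -> int:
    if mask_rate == 0.0:
        return 0
    k = max(min_masked, int(np.floor(mask_rate * n + 0.5)))
    return min(k, n)


def mask_attributes(
    graph: MolecularGraph,
    config: MaskConfig,
    rng: np.random.Generator,
    vocab: FeatureVocab | None = None,
) -> MaskedView:
    """Replace a random subset of node attributes with the mask indicator.

    Masked node rows become ``(mask_atom_index, 0)``; edges and unmasked
    rows are untouched.  Deterministic given the RNG state.
    """
    vocab = vocab or FeatureVocab()
    n = graph.num_nodes
    k = _num_masked(config.mask_rate, config.min_masked, n)
    masked = graph.copy()
    if k > 0:
        idx = np.sort(rng.choice(n, size=k, replace=False))
    else:
        idx = np.empty(0, dtype=np.int64)
    withheld = graph.node_features[idx, 0].copy()
    masked.node_features[idx, 0] = vocab.mask_atom_index
    masked.node_features[idx, 1] = 0
    if config.mask_edges and graph.num_directed_edges > 0:
        n_bonds = graph.num_directed_edges // 2
        kb = _num_masked(config.mask_rate, config.min_masked, n_bonds)
        if kb > 0:
            bonds = rng.choice(n_bonds, size=kb, replace=False)
            arcs = np.concatenate([2 * bonds, 2 * bonds + 1])  # both directions
            masked.edge_features[arcs, 0] = vocab.mask_bond_index
            masked.edge_features[arcs, 1] = 0
    return MaskedView(graph=masked, masked_node_indices=idx, withheld_labels=withheld)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy of integer ``labels`` under row ``logits``."""
    labels = np.asarray(labels, dtype=np.int64)
    log_probs = logits.log_softmax()
    one_hot = np.zeros(logits.shape)
    one_hot[np.arange(labels.size), labels] = 1.0
    return -(log_probs * Tensor(one_hot)).sum() * (1.0 / max(labels.size, 1))


def reconstruction_loss(
    masked_node_embeddings: Tensor,
    withheld_labels: np.ndarray,
    head_weight: Tensor,
    head_bias: Tensor,
) -> Tensor:
    """Mean cross-entropy of the affine head's atom-type predictions.

    The label space excludes the mask token (the head has
    ``atom_type_count - 1`` output classes).  With zero masked nodes the
    loss is defined as 0.
    """
    labels = np.asarray(withheld_labels, dtype=np.int64)
    if labels.size == 0:
        logger.warning("reconstruction_loss called with zero masked nodes; returning 0")
        return Tensor(0.0)
    logits = masked_node_embeddings @ head_weight + head_bias
    return cross_entropy_logits(logits, labels)


def nt_xent(anchors: Tensor | np.ndarray, partners: Tensor | np.ndarray, tau: float) -> Tensor:
    """Normalised temperature-scaled cross-entropy over a batch.

    For anchor i with positive partner i, the negatives are the partner
    views of all other graphs; the positive term is excluded from the
    denominator, so the value is unbounded below.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    a = anchors if isinstance(anchors, Tensor) else Tensor(anchors)
    p = partners if isinstance(partners, Tensor) else Tensor(partners)
    if a.shape != p.shape or a.ndim != 2:
        raise ValueError("anchors and partners must be matrices of identical shape")
    B = a.shape[0]
    if B < 2:
        raise ValueError("NT-Xent needs a batch of at least 2 (no negatives otherwise)")
    sims = (a.l2_normalize_rows() @ p.l2_normalize_rows().T) * (1.0 / tau)
    eye = np.eye(B)
    pos = (sims * Tensor(eye)).sum(axis=1)
    neg_logsum = ((sims.exp() * Tensor(1.0 - eye)).sum(axis=1)).log()
    return (neg_logsum - pos).mean()


def maskgcl_loss(l_mask, l_cl1, alpha: float):
    """Hybrid MaskGCL objective ``alpha * L_mask + (1 - alpha) * L_cl1``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return l_mask * alpha + l_cl1 * (1.0 - alpha)
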