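"""Scaffold splitting, fine-tuning and molecular retrieval.

The evaluation protocol: deterministic Bemis-Murcko scaffold split
(8:1:1), multi-task fine-tuning with sigmoid cross-entropy over
non-missing labels only, per-epoch validation, test ROC-AUC of the best
validation epoch, aggregated over random seeds.  Retrieval ranks a
corpus by cosine similarity of learned graph embeddings and annotates
hits with Morgan-fingerprint Tanimoto similarity.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem
from sklearn.metrics import roc_auc_score

from .autodiff import Tensor, backward
from .encoder import (
    EncoderConfig,
    EncoderParams,
    cosine_similarity,
    encode,
    forward_batch,
    init_params,
    make_batch,
)
from .molgraph import FeatureVocab, LabeledDataset, MolecularGraph, scaffold_of
from .optim import Adam
from .training import load_checkpoint

logger = logging.getLogger(__name__)

__all__ = [
    "SplitIndices",
    "FinetuneResult",
    "scaffold_split",
    "evaluate_auc",
    "finetune",
    "retrieve_similar",
    "tanimoto",
    "morgan_fingerprint",
]


@dataclass
class SplitIndices:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        parts = [set(map(int, p)) for p in (self.train, self.valid, self.test)]
        if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
            raise ValueError("split partitions must be disjoint")


def scaffold_split(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitIndices:
    """Deterministic scaffold split: no scaffold spans two partitions.

    Molecules are grouped by Bemis-Murcko scaffold; groups are placed
    whole, largest first (ties broken by scaffold string), filling train
    to its budget, then validation, then test.
    """
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n = len(dataset)
    groups: dict[str, list[int]] = defaultdict(list)
    for i, g in enumerate(dataset.graphs):
        groups[scaffold_of(g.smiles)].append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    t_train, t_valid = fractions[0] * n, (fractions[0] + fractions[1]) * n
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for scaffold, members in ordered:
        if len(train) < t_train:
            if len(members) > t_train - len(train):
                logger.warning(
                    "scaffold group %r (size %d) overflows the train budget", scaffold, len(members)
                )
            train.extend(members)
        elif len(train) + len(valid) < t_valid:
            valid.extend(members)
        else:
            test.extend(members)
    if not valid or not test:
        logger.warning("scaffold split produced an empty validation or test partition")
    return SplitIndices(
        train=np.asarray(sorted(train), dtype=np.int64),
        valid=np.asarray(sorted(valid), dtype=np.int64),
        test=np.asarray(sorted(test), dtype=np.int64),
    )


def evaluate_auc(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-task ROC-AUC over non-missing labels, plus the mean over valid tasks.

    Tasks whose non-missing labels are single-class are excluded from the
    mean and reported as NaN.  Tied scores count half, as usual.
    """
    labels = np.asarray(labels, dtype=np.float64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.ndim == 1:
        labels, scores = labels[:, None], scores[:, None]
    per_task = np.full(labels.shape[1], np.nan)
    for t in range(labels.shape[1]):
        mask = ~np.isnan(labels[:, t])
        y = labels[mask, t]
        if y.size == 0 or np.unique(y).size < 2:
            continue
        per_task[t] = roc_auc_score(y, scores[mask, t])
    valid = per_task[~np.isnan(per_task)]
    if valid.size == 0:
        raise ValueError("all tasks are degenerate; no AUC can be computed")
    return per_task, float(valid.mean())


@dataclass
class FinetuneResult:
    per_seed_test_auc: list[float]
    best_epochs: list[int]
    per_task_aucs: list[np.ndarray]
    per_seed_train_auc: list[float] = field(default_factory=list)  # best train AUC, if tracked
    mean_auc: float = field(init=False)
    std_auc: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_seed_test_auc, dtype=np.float64)
        self.mean_auc = float(arr.mean())
        self.std_auc = float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def _masked_bce(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean sigmoid cross-entropy over the non-missing entries of ``labels``."""
    observed = ~np.isnan(labels)
    y = Tensor(np.where(observed, labels, 0.0))
    w = Tensor(observed.astype(np.float64))
    # numerically stable: max(z,0) - z*y + log(1 + exp(-|z|))
    absz = logits.relu() + (-logits).relu()
    elem = logits.relu() - logits * y + ((-absz).exp() + 1.0).log()
    return (elem * w).sum() * (1.0 / max(int(observed.sum()), 1))


def _score_graphs(
    graphs: Sequence[MolecularGraph],
    params: EncoderParams,
    head_w: np.ndarray,
    head_b: np.ndarray,
) -> np.ndarray:
    emb = encode(graphs, params)
    return emb.graph_embeddings @ head_w + head_b


def finetune(
    checkpoint: EncoderParams | str | Path | None,
    dataset: LabeledDataset,
    split: SplitIndices,
    seeds: Sequence[int] = range(10),
    epochs: int = 100,
    batch_size: int = 32,
    learning_rate: float = 0.001,
    encoder_config: EncoderConfig | None = None,
    head_only: bool = False,
    eval_train: bool = False,
) -> FinetuneResult:
    """Fine-tune the encoder plus a fresh linear head on a labeled dataset.

    For each seed: attach a head (hidden_dim -> T logits), train with
    masked sigmoid cross-entropy on the train partition, evaluate the
    validation mean-AUC after every epoch, and report the test mean-AUC
    of the best-validation epoch.  ``checkpoint=None`` trains from random
    initialisation (seeded per run).  ``head_only`` freezes the encoder.
    """
    if split.valid.size == 0 or split.test.size == 0:
        raise ValueError("empty validation or test partition; see the scaffold-split warning")
    if isinstance(checkpoint, (str, Path)):
        base_params, pre_cfg, _, _, _ = load_checkpoint(checkpoint)
        encoder_config = pre_cfg.encoder
    else:
        base_params = checkpoint
        if base_params is not None:
            encoder_config = base_params.config
    encoder_config = encoder_config or EncoderConfig()
    n_tasks = dataset.labels.shape[1]
    train_graphs = [dataset.graphs[i] for i in split.train]
    valid_graphs = [dataset.graphs[i] for i in split.valid]
    test_graphs = [dataset.graphs[i] for i in split.test]
    y_train = dataset.labels[split.train]
    y_valid = dataset.labels[split.valid]
    y_test = dataset.labels[split.test]

    per_seed, best_epochs, per_task_list, train_aucs = [], [], [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        if base_params is None:
            params = init_params(encoder_config, FeatureVocab(), seed)
        else:
            params = base_params.copy()
        d = encoder_config.hidden_dim
        limit = np.sqrt(6.0 / (d + n_tasks))
        head = {
            "head.w": rng.uniform(-limit, limit, size=(d, n_tasks)),
            "head.b": np.zeros(n_tasks),
        }
        optimizer = Adam(lr=learning_rate)
        best_val, best_epoch, best_test_auc, best_task_aucs = -np.inf, -1, np.nan, None
        best_train = np.nan

        for epoch in range(epochs):
            order = rng.permutation(len(train_graphs))
            for start in range(0, len(order), batch_size):
                idx = order[start : start + batch_size]
                if idx.size < 2:
                    continue  # batch-norm needs at least two graphs
                t = {k: Tensor(v, requires_grad=not head_only) for k, v in params.params.items()}
                th = {k: Tensor(v, requires_grad=True) for k, v in head.items()}
                batch = make_batch([train_graphs[i] for i in idx])
                _, h_graph, _ = forward_batch(t, batch, params, train=True, update_stats=True)
                logits = h_graph @ th["head.w"] + th["head.b"]
                loss = _masked_bce(logits, y_train[idx])
                backward(loss)
                trainable = {**({} if head_only else {k: x for k, x in t.items()}), **th}
                grads = {k: x.grad for k, x in trainable.items() if x.grad is not None}
                targets = {**({} if head_only else params.params), **head}
                optimizer.step(targets, grads)
            if eval_train:
                train_scores = _score_graphs(train_graphs, params, head["head.w"], head["head.b"])
                _, train_auc = evaluate_auc(y_train, train_scores)
                best_train = train_auc if np.isnan(best_train) else max(best_train, train_auc)
            val_scores = _score_graphs(valid_graphs, params, head["head.w"], head["head.b"])
            try:
                _, val_auc = evaluate_auc(y_valid, val_scores)
            except ValueError:
                continue
            if val_auc > best_val:
                best_val, best_epoch = val_auc, epoch
                test_scores = _score_graphs(test_graphs, params, head["head.w"], head["head.b"])
                task_aucs, best_test_auc = evaluate_auc(y_test, test_scores)
                best_task_aucs = task_aucs
        per_seed.append(best_test_auc)
        best_epochs.append(best_epoch)
        per_task_list.append(best_task_aucs if best_task_aucs is not None else np.full(n_tasks, np.nan))
        train_aucs.append(best_train)
    return FinetuneResult(per_seed, best_epochs, per_task_list, train_aucs)


# ------------------------------------------------------------------ retrieval

def morgan_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048):
    """2048-bit circular (Morgan) fingerprint, the Tanimoto reference scheme."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| of two bit sets.

    Accepts sets of on-bit indices or equal-length 0/1 bit arrays.  Two
    empty fingerprints are defined as identical (similarity 1).
    """
    if isinstance(fp_a, (set, frozenset)) and isinstance(fp_b, (set, frozenset)):
        a, b = set(fp_a), set(fp_b)
    else:
        va = np.asarray(fp_a).astype(bool).ravel()
        vb = np.asarray(fp_b).astype(bool).ravel()
        if va.size != vb.size:
            raise ValueError("fingerprint length mismatch")
        a = set(np.flatnonzero(va))
        b = set(np.flatnonzero(vb))
    union = a | b
    if not union:
        logger.info("tanimoto of two empty fingerprints; returning 1.0 by convention")
        return 1.0
    return len(a & b) / len(union)


def retrieve_similar(
    query: MolecularGraph,
    corpus: Sequence[MolecularGraph],
    params: EncoderParams | str | Path,
    k: int,
) -> list[tuple[int, float, float]]:
    """Top-k corpus molecules by cosine similarity of graph embeddings.

    Returns ``(corpus_index, cosine, tanimoto)`` triples sorted by cosine
    descending, ties broken by corpus index.  Tanimoto is computed on
    Morgan fingerprints against the query.
    """
    if k > len(corpus):
        raise ValueError("k exceeds corpus size")
    if isinstance(params, (str, Path)):
        params, _, _, _, _ = load_checkpoint(params)
    emb = encode([query] + list(corpus), params)
    q = emb.graph_embeddings[0]
    sims = [cosine_similarity(q, emb.graph_embeddings[i + 1]) for i in range(len(corpus))]
    ranked = sorted(range(len(corpus)), key=lambda i: (-sims[i], i))[:k]
    fp_q = morgan_fingerprint(query.smiles)
    out = []
    for i in ranked:
        fp_i = morgan_fingerprint(corpus[i].smiles)
        out.append((i, sims[i], float(DataStructs.TanimotoSimilarity(fp_q, fp_i))))
    return out
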