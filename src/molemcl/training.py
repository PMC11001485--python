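"""Joint pre-training loop: reconstruction + two contrastive losses.

One training step, in order: (1) mask each graph's node attributes;
(2) encode the original and masked views and project; (3) form the
reconstruction loss, the masked-view contrastive loss and their hybrid;
(4) snapshot the contrastive-loss gradient, perturb the encoder layer
weights with it, run the perturbed forward on the unchanged graphs and
form the perturbation contrastive loss; (5) one Adam update on
``L = L_MaskGCL + L_PPGCL``.  Ablation arms drop terms or swap the
perturbation for Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .autodiff import Tensor, backward
from .encoder import EncoderConfig, EncoderParams, forward_batch, init_params, make_batch, wrap_params
from .maskgcl import MaskConfig, mask_attributes, maskgcl_loss, nt_xent, reconstruction_loss
from .molgraph import FeatureVocab, MolecularGraph, read_smiles_file, smiles_to_graph
from .optim import Adam
from .ppgcl import PerturbationConfig, grads_from_tensors, perturb_parameters, ppgcl_loss

logger = logging.getLogger(__name__)

__all__ = [
    "PretrainConfig",
    "LossBreakdown",
    "pretrain_step",
    "run_pretraining",
    "save_checkpoint",
    "load_checkpoint",
]

Ablation = Literal["molemcl", "maskgcl_only", "ppgcl_only", "maskgcl_plus_gaussian"]


@dataclass(frozen=True)
class PretrainConfig:
    """Hyper-parameters of the joint pre-training objective.

    Defaults follow the evaluation protocol: five-layer GIN of width 300
    with mean pooling, 100 epochs, batch size 256, learning rate 1e-3;
    the trade-off weight ``alpha`` is searched over {0.3, 0.5, 0.7} and
    the perturbation magnitude ``eta`` over {2, 4, 6, 8, 10}.
    """

    alpha: float = 0.5
    eta: float = 2.0
    tau: float = 0.1
    mask_rate: float = 0.15
    epochs: int = 100
    batch_size: int = 256
    learning_rate: float = 0.001
    seed: int = 0
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    ablation: Ablation = "molemcl"
    gaussian_scale: float = 0.1  # only the maskgcl_plus_gaussian arm uses it

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.eta < 0 or self.tau <= 0:
            raise ValueError("eta must be >= 0 and tau > 0")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must lie in [0, 1]")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.ablation not in ("molemcl", "maskgcl_only", "ppgcl_only", "maskgcl_plus_gaussian"):
            raise ValueError(f"unknown ablation arm {self.ablation!r}")

    def perturbation(self) -> PerturbationConfig:
        if self.ablation == "maskgcl_only":
            return PerturbationConfig(eta=self.eta, mode="none")
        if self.ablation == "maskgcl_plus_gaussian":
            return PerturbationConfig(eta=self.eta, mode="gaussian", gaussian_scale=self.gaussian_scale)
        return PerturbationConfig(eta=self.eta, mode="gradient")


@dataclass
class LossBreakdown:
    """Per-step loss terms; disabled terms are reported as 0."""

    l_mask: float
    l_cl1: float
    l_maskgcl: float
    l_ppgcl: float
    total: float
    step: int
    recon_correct: int = 0
    recon_count: int = 0

    def check_identities(self, alpha: float, tol: float = 1e-6) -> None:
        if abs(self.l_maskgcl - (alpha * self.l_mask + (1 - alpha) * self.l_cl1)) > tol:
            raise AssertionError("MaskGCL hybrid identity violated")
        if abs(self.total - (self.l_maskgcl + self.l_ppgcl)) > tol:
            raise AssertionError("total-loss identity violated")


def _masked_global_indices(views, graphs) -> tuple[np.ndarray, np.ndarray]:
    idx, labels = [], []
    offset = 0
    for g, v in zip(graphs, views):
        idx.append(v.masked_node_indices + offset)
        labels.append(v.withheld_labels)
        offset += g.num_nodes
    return np.concatenate(idx), np.concatenate(labels)


def pretrain_step(
    params: EncoderParams,
    optimizer: Adam,
    graphs: Sequence[MolecularGraph],
    config: PretrainConfig,
    rng: np.random.Generator,
    step: int = 0,
) -> LossBreakdown:
    """Run one joint pre-training step; ``params`` is updated in place."""
    if len(graphs) < 2:
        raise ValueError("pretrain_step needs a batch of at least 2 graphs")
    vocab = params.vocab
    mask_cfg = MaskConfig(mask_rate=config.mask_rate)
    views = [mask_attributes(g, mask_cfg, rng, vocab) for g in graphs]

    t = wrap_params(params)
    orig_batch = make_batch(graphs)
    masked_batch = make_batch([v.graph for v in views])
    _, _, z_orig = forward_batch(t, orig_batch, params, train=True, update_stats=True)
    h_masked, _, z_masked = forward_batch(t, masked_batch, params, train=True, update_stats=True)

    masked_idx, withheld = _masked_global_indices(views, graphs)
    masked_emb = h_masked.take_rows(masked_idx)
    l_mask_t = reconstruction_loss(masked_emb, withheld, t["recon.w"], t["recon.b"])
    l_cl1_t = nt_xent(z_orig, z_masked, config.tau)

    # masked-atom reconstruction accuracy (diagnostic, no gradient)
    logits = masked_emb.data @ params.params["recon.w"] + params.params["recon.b"]
    recon_correct = int((logits.argmax(axis=1) == withheld).sum())

    alpha = config.alpha
    arm = config.ablation
    use_mask_term = arm in ("molemcl", "maskgcl_only", "maskgcl_plus_gaussian")
    use_ppgcl_term = arm in ("molemcl", "ppgcl_only", "maskgcl_plus_gaussian")

    l_ppgcl_t = Tensor(0.0)
    if use_ppgcl_term:
        # snapshot the CL1 gradient from this very graph, before any update
        backward(l_cl1_t)
        snapshot = grads_from_tensors(t, step=step)
        for x in t.values():
            x.zero_grad()
        perturbed = perturb_parameters(params, snapshot, config.perturbation(), rng)
        tp = {k: Tensor(v) for k, v in perturbed.params.items()}  # constant branch
        _, _, z_pert = forward_batch(tp, orig_batch, perturbed, train=True, update_stats=False)
        l_ppgcl_t = ppgcl_loss(z_orig, z_pert.data, config.tau)

    if use_mask_term:
        l_maskgcl_t = maskgcl_loss(l_mask_t, l_cl1_t, alpha)
        total_t = l_maskgcl_t + l_ppgcl_t if use_ppgcl_term else l_maskgcl_t
        breakdown = LossBreakdown(
            l_mask=l_mask_t.item(),
            l_cl1=l_cl1_t.item(),
            l_maskgcl=l_maskgcl_t.item(),
            l_ppgcl=l_ppgcl_t.item() if use_ppgcl_term else 0.0,
            total=total_t.item(),
            step=step,
            recon_correct=recon_correct,
            recon_count=int(withheld.size),
        )
    else:  # ppgcl_only: the MaskGCL terms exist only to supply the gradient
        total_t = l_ppgcl_t
        breakdown = LossBreakdown(
            l_mask=0.0, l_cl1=0.0, l_maskgcl=0.0,
            l_ppgcl=l_ppgcl_t.item(), total=total_t.item(), step=step,
            recon_correct=recon_correct, recon_count=int(withheld.size),
        )

    if not np.isfinite(breakdown.total):
        offender = next(
            (k for k, v in dataclasses.asdict(breakdown).items()
             if isinstance(v, float) and not np.isfinite(v)),
            "total",
        )
        raise RuntimeError(f"non-finite loss at step {step}: {offender}")
    breakdown.check_identities(alpha if use_mask_term else 0.0)

    backward(total_t)
    grads = {name: x.grad for name, x in t.items() if x.grad is not None}
    optimizer.step(params.params, grads)
    for x in t.values():
        x.zero_grad()
    return breakdown


# ------------------------------------------------------------- checkpointing

def _config_to_dict(config: PretrainConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _config_from_dict(d: dict) -> PretrainConfig:
    d = dict(d)
    d["encoder"] = EncoderConfig(**d["encoder"])
    return PretrainConfig(**d)


def save_checkpoint(
    path: str | Path,
    params: EncoderParams,
    config: PretrainConfig,
    optimizer: Adam | None = None,
    rng: np.random.Generator | None = None,
    epoch: int = 0,
) -> None:
    """Write a single-archive checkpoint (named tensors + JSON metadata)."""
    arrays: dict[str, np.ndarray] = {}
    for k, v in params.params.items():
        arrays[f"param/{k}"] = v
    for k, v in params.buffers.items():
        arrays[f"buffer/{k}"] = v
    meta: dict = {
        "config": _config_to_dict(config),
        "vocab": dataclasses.asdict(params.vocab),
        "epoch": epoch,
    }
    if optimizer is not None:
        state = optimizer.state_dict()
        for k, v in state["m"].items():
            arrays[f"adam_m/{k}"] = v
        for k, v in state["v"].items():
            arrays[f"adam_v/{k}"] = v
        meta["adam"] = {"t": state["t"], "hyper": state["hyper"]}
    if rng is not None:
        meta["rng_state"] = rng.bit_generator.state
    arrays["meta_json"] = np.frombuffer(json.dumps(meta, default=int).encode(), dtype=np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str | Path):
    """Load a checkpoint -> (params, config, optimizer|None, rng|None, epoch)."""
    archive = np.load(path)
    meta = json.loads(bytes(archive["meta_json"]).decode())
    config = _config_from_dict(meta["config"])
    vocab = FeatureVocab(**meta["vocab"])
    p = {k[len("param/"):]: archive[k].copy() for k in archive.files if k.startswith("param/")}
    b = {k[len("buffer/"):]: archive[k].copy() for k in archive.files if k.startswith("buffer/")}
    params = EncoderParams(p, b, config.encoder, vocab)
    optimizer = None
    if "adam" in meta:
        optimizer = Adam(**meta["adam"]["hyper"])
        optimizer.load_state_dict(
            {
                "t": meta["adam"]["t"],
                "m": {k[len("adam_m/"):]: archive[k].copy() for k in archive.files if k.startswith("adam_m/")},
                "v": {k[len("adam_v/"):]: archive[k].copy() for k in archive.files if k.startswith("adam_v/")},
                "hyper": meta["adam"]["hyper"],
            }
        )
    rng = None
    if "rng_state" in meta:
        rng = np.random.default_rng(0)
        state = meta["rng_state"]
        state["state"] = {k: int(v) for k, v in state["state"].items()}
        rng.bit_generator.state = state
    return params, config, optimizer, rng, int(meta["epoch"])


# ------------------------------------------------------------ epoch driver

def _make_batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    if n < batch_size:
        return [order]
    num = n // batch_size  # drop-last keeps every batch >= 2
    return [order[i * batch_size : (i + 1) * batch_size] for i in range(num)]


def run_pretraining(
    corpus: str | Path | Sequence[str],
    config: PretrainConfig,
    out_dir: str | Path,
    resume_from: str | Path | None = None,
) -> Path:
    """Pre-train on a SMILES corpus; returns the final checkpoint path.

    Writes per-epoch mean loss breakdowns to ``metrics.csv`` and a
    resumable checkpoint (parameters, optimiser state, RNG state) after
    every epoch.  Resuming reproduces the uninterrupted loss trace
    bit-exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    smiles = list(corpus) if not isinstance(corpus, (str, Path)) else read_smiles_file(corpus)
    vocab = FeatureVocab()
    graphs, dropped = [], 0
    for s in smiles:
        try:
            graphs.append(smiles_to_graph(s, vocab))
        except ValueError:
            dropped += 1
    if dropped:
        logger.warning("dropped %d unparseable corpus molecule(s)", dropped)
    if len(graphs) < 2:
        raise ValueError("corpus must contain at least 2 parseable molecules")

    if resume_from is not None:
        params, saved_config, optimizer, rng, start_epoch = load_checkpoint(resume_from)
        saved_d, want_d = _config_to_dict(saved_config), _config_to_dict(config)
        saved_d.pop("epochs"), want_d.pop("epochs")  # extending the run is the point of resuming
        if saved_d != want_d:
            raise ValueError("refusing to resume: checkpoint config differs from requested config")
        metrics_path = out_dir / "metrics.csv"
        rows = metrics_path.read_text().splitlines() if metrics_path.exists() else []
        header_written = bool(rows)
    else:
        params = init_params(config.encoder, vocab, config.seed)
        optimizer = Adam(lr=config.learning_rate)
        rng = np.random.default_rng(config.seed)
        start_epoch = 0
        header_written = False

    metrics_path = out_dir / "metrics.csv"
    ckpt_path = out_dir / "checkpoint.npz"
    mode = "a" if (resume_from is not None and header_written) else "w"
    with open(metrics_path, mode) as fh:
        if mode == "w":
            fh.write("epoch,l_mask,l_cl1,l_maskgcl,l_ppgcl,total,recon_accuracy\n")
        step = start_epoch * max(len(graphs) // config.batch_size, 1)
        for epoch in range(start_epoch, config.epochs):
            sums = np.zeros(5)
            correct = count = 0
            batches = _make_batches(len(graphs), config.batch_size, rng)
            for batch_idx in batches:
                bd = pretrain_step(params, optimizer, [graphs[i] for i in batch_idx], config, rng, step)
                sums += (bd.l_mask, bd.l_cl1, bd.l_maskgcl, bd.l_ppgcl, bd.total)
                correct += bd.recon_correct
                count += bd.recon_count
                step += 1
            means = sums / len(batches)
            acc = correct / count if count else float("nan")
            fh.write(f"{epoch},{means[0]:.8f},{means[1]:.8f},{means[2]:.8f},{means[3]:.8f},{means[4]:.8f},{acc:.6f}\n")
            fh.flush()
            logger.info(
                "epoch %d: total %.4f (mask %.4f, cl1 %.4f, ppgcl %.4f), recon acc %.3f",
                epoch, means[4], means[0], means[1], means[3], acc,
            )
            save_checkpoint(ckpt_path, params, config, optimizer, rng, epoch=epoch + 1)
    return ckpt_path
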