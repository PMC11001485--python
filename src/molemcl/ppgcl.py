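"""Parameter-perturbation contrastive learning (PPGCL).

Instead of augmenting the input graph, a second view of every molecule is
produced by perturbing the encoder's layer weights along the gradient of
the MaskGCL contrastive loss::

    theta'_l = theta_l + eta * grad_{theta_l} L_CL1

(gradient mode).  A Gaussian-noise mode reproduces the random-perturbation
ablation baseline.  The perturbed encoder re-embeds the *unchanged*
molecular graphs and the (original, perturbed) projection pairs feed the
same NT-Xent loss; the perturbed branch is treated as a constant during
optimisation (no second-order terms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .autodiff import Tensor, backward
from .encoder import EncoderParams, forward_batch, is_perturbable, make_batch, wrap_params
from .maskgcl import MaskedView, nt_xent
from .molgraph import MolecularGraph

__all__ = [
    "PerturbationConfig",
    "GradientSnapshot",
    "snapshot_cl1_gradient",
    "perturb_parameters",
    "ppgcl_loss",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Magnitude and kind of the encoder-parameter perturbation.

    ``eta`` scales the contrastive-loss gradient in ``gradient`` mode;
    ``gaussian`` adds elementwise N(0, gaussian_scale^2) noise instead
    (the random-perturbation ablation); ``none`` disables PPGCL entirely.
    """

    eta: float = 2.0
    mode: Literal["gradient", "gaussian", "none"] = "gradient"
    gaussian_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.mode not in ("gradient", "gaussian", "none"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.gaussian_scale < 0:
            raise ValueError("gaussian_scale must be >= 0")


@dataclass
class GradientSnapshot:
    """Gradients of L_CL1 aligned one-to-one with the parameter registry."""

    grads: dict[str, np.ndarray]
    taken_at_step: int = 0

    def validate_against(self, params: EncoderParams) -> None:
        for name, value in params.params.items():
            g = self.grads.get(name)
            if g is None or g.shape != value.shape:
                raise ValueError(f"gradient snapshot misaligned for tensor {name!r}")


def snapshot_cl1_gradient(
    params: EncoderParams,
    graphs: Sequence[MolecularGraph],
    mask_views: Sequence[MaskedView],
    tau: float,
    step: int = 0,
) -> GradientSnapshot:
    """Gradient of the MaskGCL contrastive loss w.r.t. every registry tensor.

    Recomputes L_CL1 on the given batch with exactly the supplied masked
    views (the same ones the MaskGCL term of the step uses).  ``params``
    is read only: batch-norm runs on batch statistics without touching
    the stored running statistics.  Entries with no gradient flow are
    zero tensors.
    """
    t = wrap_params(params)
    orig_batch = make_batch(graphs)
    masked_batch = make_batch([v.graph for v in mask_views])
    _, _, z_orig = forward_batch(t, orig_batch, params, train=True, update_stats=False)
    _, _, z_masked = forward_batch(t, masked_batch, params, train=True, update_stats=False)
    loss = nt_xent(z_orig, z_masked, tau)
    backward(loss)
    grads = {
        name: (tensor.grad.copy() if tensor.grad is not None else np.zeros_like(tensor.data))
        for name, tensor in t.items()
    }
    return GradientSnapshot(grads=grads, taken_at_step=step)


def grads_from_tensors(t: dict[str, Tensor], step: int = 0) -> GradientSnapshot:
    """Collect accumulated ``.grad`` fields into a snapshot (zeros where absent)."""
    return GradientSnapshot(
        grads={
            name: (x.grad.copy() if x.grad is not None else np.zeros_like(x.data))
            for name, x in t.items()
        },
        taken_at_step=step,
    )


def perturb_parameters(
    params: EncoderParams,
    grad: GradientSnapshot | None,
    config: PerturbationConfig,
    rng: np.random.Generator | None = None,
) -> EncoderParams:
    """Return a perturbed deep copy of the registry; the input is untouched.

    Only the GNN layer weights are perturbed — feature-embedding tables,
    the projection head and the reconstruction head carry over unchanged,
    as do the batch-norm running statistics.
    """
    out = params.copy()
    if config.mode == "none":
        return out
    if config.mode == "gradient":
        if grad is None:
            raise ValueError("gradient mode requires a GradientSnapshot")
        grad.validate_against(params)
        for name in out.params:
            if is_perturbable(name):
                out.params[name] = out.params[name] + config.eta * grad.grads[name]
    else:  # gaussian
        if rng is None:
            raise ValueError("gaussian mode requires an rng")
        for name in out.params:
            if is_perturbable(name):
                noise = rng.normal(0.0, config.gaussian_scale, size=out.params[name].shape)
                out.params[name] = out.params[name] + noise
    return out


def ppgcl_loss(
    z_original: Tensor | np.ndarray,
    z_perturbed: np.ndarray,
    tau: float,
) -> Tensor:
    """NT-Xent between original and perturbed-encoder projections.

    The perturbed projections enter as constants: gradient flows only
    through the original branch.
    """
    z_perturbed = z_perturbed.data if isinstance(z_perturbed, Tensor) else np.asarray(z_perturbed)
    return nt_xent(z_original, Tensor(z_perturbed), tau)
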