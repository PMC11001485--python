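"""Gradient snapshots, parameter perturbation, and the second contrastive loss."""

import numpy as np
import pytest

from molemcl import (
    FeatureVocab,
    GradientSnapshot,
    MaskConfig,
    PerturbationConfig,
    mask_attributes,
    nt_xent,
    perturb_parameters,
    ppgcl_loss,
    snapshot_cl1_gradient,
)
from molemcl.autodiff import Tensor
from molemcl.encoder import cosine_similarity, forward_batch, is_perturbable, make_batch
from conftest import brute_force_nt_xent


@pytest.fixture(scope="module")
def masked_views(fixture_graphs, vocab):
    rng = np.random.default_rng(0)
    return [mask_attributes(g, MaskConfig(), rng, vocab) for g in fixture_graphs[:6]]


@pytest.fixture(scope="module")
def snapshot(tiny_params, fixture_graphs, masked_views):
    return snapshot_cl1_gradient(tiny_params, fixture_graphs[:6], masked_views, tau=0.1)


class TestGradientSnapshot:
    def test_deterministic_given_frozen_inputs(self, tiny_params, fixture_graphs, masked_views, snapshot):
        again = snapshot_cl1_gradient(tiny_params, fixture_graphs[:6], masked_views, tau=0.1)
        for name in snapshot.grads:
            np.testing.assert_array_equal(snapshot.grads[name], again.grads[name])

    def test_every_registry_tensor_has_aligned_gradient(self, tiny_params, snapshot):
        assert set(snapshot.grads) == set(tiny_params.names())
        for name in tiny_params.names():
            assert snapshot.grads[name].shape == tiny_params[name].shape

    def test_params_left_unchanged(self, tiny_params, fixture_graphs, masked_views):
        before = tiny_params.checksum()
        snapshot_cl1_gradient(tiny_params, fixture_graphs[:6], masked_views, tau=0.1)
        assert tiny_params.checksum() == before

    def test_directional_derivative_matches_finite_differences(
        self, tiny_params, fixture_graphs, masked_views, snapshot
    ):
        """Central differences along random directions agree with the snapshot."""

        def cl1(params):
            t = {k: Tensor(v) for k, v in params.params.items()}
            _, _, zo = forward_batch(t, make_batch(fixture_graphs[:6]), params, train=True)
            _, _, zm = forward_batch(
                t, make_batch([v.graph for v in masked_views]), params, train=True
            )
            return nt_xent(zo, zm, 0.1).item()

        rng = np.random.default_rng(17)
        h = 1e-4
        for _ in range(20):
            direction = {k: rng.normal(size=v.shape) for k, v in tiny_params.params.items()}
            norm = np.sqrt(sum((d**2).sum() for d in direction.values()))
            direction = {k: d / norm for k, d in direction.items()}
            plus, minus = tiny_params.copy(), tiny_params.copy()
            for k in direction:
                plus.params[k] = plus.params[k] + h * direction[k]
                minus.params[k] = minus.params[k] - h * direction[k]
            fd = (cl1(plus) - cl1(minus)) / (2 * h)
            inner = sum((snapshot.grads[k] * direction[k]).sum() for k in direction)
            assert abs(fd - inner) <= 1e-3 * max(abs(fd), 1e-8)


class TestPerturbParameters:
    def test_eta_zero_is_bitwise_identity(self, tiny_params, snapshot):
        out = perturb_parameters(tiny_params, snapshot, PerturbationConfig(eta=0.0, mode="gradient"))
        for name in tiny_params.names():
            np.testing.assert_array_equal(out[name], tiny_params[name])

    def test_hand_arithmetic(self, tiny_params, snapshot):
        grads = {k: np.zeros_like(v) for k, v in tiny_params.params.items()}
        layer_name = next(n for n in tiny_params.names() if is_perturbable(n) and tiny_params[n].size >= 2)
        g = np.zeros_like(tiny_params[layer_name])
        g.flat[0], g.flat[1] = 0.5, -0.5
        grads[layer_name] = g
        base = tiny_params.copy()
        base.params[layer_name].flat[0] = 1.0
        base.params[layer_name].flat[1] = 1.0
        out = perturb_parameters(base, GradientSnapshot(grads), PerturbationConfig(eta=2.0, mode="gradient"))
        assert out[layer_name].flat[0] == pytest.approx(2.0)
        assert out[layer_name].flat[1] == pytest.approx(0.0)

    @pytest.mark.parametrize("eta", [0.5, 2.0, 10.0])
    def test_per_layer_norm_identity(self, tiny_params, snapshot, eta):
        out = perturb_parameters(tiny_params, snapshot, PerturbationConfig(eta=eta, mode="gradient"))
        for name in tiny_params.names():
            delta = np.linalg.norm(out[name] - tiny_params[name])
            if is_perturbable(name):
                assert delta == pytest.approx(eta * np.linalg.norm(snapshot.grads[name]), abs=1e-6)
            else:
                assert delta == 0.0

    def test_purity_input_never_mutated(self, tiny_params, snapshot):
        before = tiny_params.checksum()
        out = perturb_parameters(tiny_params, snapshot, PerturbationConfig(eta=5.0, mode="gradient"))
        out.params["layer0.bn.gamma"][:] = 99.0
        assert tiny_params.checksum() == before

    def test_gaussian_mode_reproducible_and_rng_required(self, tiny_params):
        cfg = PerturbationConfig(mode="gaussian", gaussian_scale=0.1)
        a = perturb_parameters(tiny_params, None, cfg, np.random.default_rng(5))
        b = perturb_parameters(tiny_params, None, cfg, np.random.default_rng(5))
        for name in tiny_params.names():
            np.testing.assert_array_equal(a[name], b[name])
        with pytest.raises(ValueError):
            perturb_parameters(tiny_params, None, cfg, None)

    def test_misaligned_snapshot_names_offending_tensor(self, tiny_params, snapshot):
        bad = GradientSnapshot({k: v.copy() for k, v in snapshot.grads.items()})
        bad.grads["layer0.bn.gamma"] = np.zeros(3)
        with pytest.raises(ValueError, match="layer0.bn.gamma"):
            perturb_parameters(tiny_params, bad, PerturbationConfig(eta=1.0, mode="gradient"))

    def test_mode_none_is_plain_copy(self, tiny_params):
        out = perturb_parameters(tiny_params, None, PerturbationConfig(mode="none"))
        for name in tiny_params.names():
            np.testing.assert_array_equal(out[name], tiny_params[name])


class TestPPGCLLoss:
    def test_identity_perturbation_gives_unit_positive_similarity(
        self, tiny_params, fixture_graphs, snapshot
    ):
        """With eta = 0 the perturbed view is the original: loss = ln(B-1)."""
        perturbed = perturb_parameters(tiny_params, snapshot, PerturbationConfig(eta=0.0, mode="gradient"))
        t = {k: Tensor(v) for k, v in tiny_params.params.items()}
        tp = {k: Tensor(v) for k, v in perturbed.params.items()}
        batch = make_batch(fixture_graphs[:5])
        _, _, z = forward_batch(t, batch, tiny_params, train=True)
        _, _, zp = forward_batch(tp, batch, perturbed, train=True)
        np.testing.assert_array_equal(z.data, zp.data)
        for i in range(5):
            assert cosine_similarity(z.data[i], zp.data[i]) == pytest.approx(1.0, abs=1e-12)

    def test_all_identical_projections_closed_form(self):
        z = np.tile([0.6, -0.8], (6, 1))
        assert ppgcl_loss(Tensor(z), z, tau=0.2).item() == pytest.approx(np.log(5), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        z = rng.normal(size=(4, 8))
        zp = rng.normal(size=(4, 8))
        assert ppgcl_loss(Tensor(z), zp, tau=0.7).item() == pytest.approx(
            brute_force_nt_xent(z, zp, 0.7), abs=1e-6
        )

    def test_no_gradient_flows_into_perturbed_branch(self):
        from molemcl.autodiff import backward

        z = Tensor(np.random.default_rng(0).normal(size=(3, 4)), requires_grad=True)
        zp = Tensor(np.random.default_rng(1).normal(size=(3, 4)), requires_grad=True)
        loss = ppgcl_loss(z, zp, tau=0.5)
        backward(loss)
        assert z.grad is not None
        assert zp.grad is None
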