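"""Network specs and builder: padding alignment, parameter counting,
initialization, and structural invariants of the shipped family."""

import numpy as np
import pytest

from eegauth import _nn, model
from eegauth.model import (BranchSpec, KernelSpec, ModuleSpec, NetworkSpec,
                           build_network, compute_padding, count_parameters)


class TestComputePadding:
    def test_three_five_seven(self):
        pads = compute_padding([KernelSpec(3, 3), KernelSpec(5, 3),
                                KernelSpec(7, 3)])
        assert [p[0] for p in pads] == [0, 1, 2]
        assert [p[1] for p in pads] == [0, 0, 0]

    def test_single_branch_zero(self):
        assert compute_padding([KernelSpec(9, 7)]) == [(0, 0)]

    def test_three_nine_alignment(self):
        """{3, 9} -> {0, 3}; equal output length verified on a length-20
        axis (shape-arithmetic oracle)."""
        pads = compute_padding([KernelSpec(3), KernelSpec(9)])
        assert pads == [(0,), (3,)]
        lengths = {20 + 2 * p[0] - k + 1
                   for p, k in zip(pads, (3, 9))}
        assert lengths == {18}

    def test_parity_mismatch_raises(self):
        with pytest.raises(ValueError, match="parity"):
            compute_padding([KernelSpec(3), KernelSpec(4)])


def tiny_spec(n_branches=1, pool=(2, 2), width=4, form="2d"):
    kernels = [KernelSpec(3 + 2 * i, 3) for i in range(n_branches)]
    mod = ModuleSpec(branches=tuple(BranchSpec(k, width) for k in kernels),
                     pool=pool)
    return NetworkSpec(form, (mod,), input_shape=(1, 20, 12))


class TestBuildNetwork:
    def test_softmax_normalization(self, rng):
        net = build_network(tiny_spec()).initialize(0)
        p = net.predict_proba(rng.normal(size=(5, 1, 20, 12)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-5)
        assert np.all(p >= 0)

    def test_branch_alignment_asserted(self, rng):
        net = build_network(tiny_spec(n_branches=3)).initialize(1)
        out = net.forward(rng.normal(size=(2, 1, 20, 12)))
        assert out.shape == (2, 2)

    def test_pool_exhaustion_names_module(self):
        mod = ModuleSpec(branches=(BranchSpec(KernelSpec(3, 3), 4),),
                         pool=(2, 32))
        spec = NetworkSpec("2d", (mod,), input_shape=(1, 20, 12))
        with pytest.raises(ValueError, match="module 0"):
            build_network(spec)

    def test_kernel_exhaustion_names_module(self):
        mods = (ModuleSpec(branches=(BranchSpec(KernelSpec(3, 3), 4),),
                           pool=(2, 4)),
                ModuleSpec(branches=(BranchSpec(KernelSpec(3, 9), 4),),
                           pool=(1, 1)))
        spec = NetworkSpec("2d", mods, input_shape=(1, 20, 12))
        with pytest.raises(ValueError, match="module 1"):
            build_network(spec)

    def test_parameter_count_toy_by_hand(self):
        """1-branch, 1-module count equals kernel x channel arithmetic."""
        spec = tiny_spec(width=4)
        # conv 1->4 (3x3): 4*9+4; BN: 8; flatten 4*9*5=180 -> 32 -> 2
        expected = (4 * 9 + 4) + 8 + (32 * 180 + 32) + (2 * 32 + 2)
        assert count_parameters(spec) == expected
        assert build_network(spec).n_parameters() == expected

    def test_count_matches_build_for_family(self):
        for name, spec in model.reference_architectures().items():
            assert count_parameters(spec) == \
                build_network(spec).n_parameters(), name

    def test_branch_monotone_parameters(self):
        counts = [count_parameters(tiny_spec(n)) for n in (1, 2, 3)]
        assert counts[0] < counts[1] < counts[2]


class TestInit:
    def test_deterministic(self):
        a = build_network(tiny_spec()).initialize(42)
        b = build_network(tiny_spec()).initialize(42)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_kaiming_bound(self):
        net = build_network(model.load_architecture("2d-simple"))
        net.initialize(0)
        for layer in net._walk():
            if isinstance(layer, _nn.ConvNd):
                bound = np.sqrt(6.0 / layer.fan_in)
                assert np.abs(layer.weight.value).max() <= bound

    def test_empirical_variance(self, rng):
        """Weight variance approximates the uniform bound's 2/fan_in at
        large fan-in (sampling check)."""
        lin = _nn.Linear(1500, 64)
        _nn.kaiming_uniform_(lin.weight, lin.fan_in, rng)
        var = lin.weight.value.var()
        assert abs(var - 2.0 / 1500) < 0.1 * (2.0 / 1500)


class TestReferenceFamily:
    def test_all_ten_specs_load(self):
        archs = model.reference_architectures()
        assert set(archs) == set(model.ARCHITECTURE_NAMES)
        for name, spec in archs.items():
            assert spec.name == name
            assert 3 <= len(spec.modules) <= 5

    def test_multi_scale_length_3d_contract(self):
        """The temporally elongated 3D multi-scale column: branch kernels
        7/5/3 in time, 3 in frequency, spatial depth 6, widths 24/72/72."""
        spec = model.load_architecture("3d-multi-scale-length")
        a = spec.modules[0]
        assert [b.kernel.sizes for b in a.branches] == \
            [(6, 7, 3), (6, 5, 3), (6, 3, 3)]
        assert [m.branches[0].out_channels for m in spec.modules] == \
            [24, 72, 72]
        assert [m.pool for m in spec.modules] == \
            [(1, 2, 2), (1, 2, 2), (1, 5, 5)]
        assert a.resolved_paddings() == [(0, 2, 0), (0, 1, 0), (0, 0, 0)]

    def test_equivariance_time_translation(self, rng):
        """Without pooling/padding, translating the input in time
        translates the pre-head feature map equally."""
        conv = _nn.ConvNd(1, 3, (3, 3))
        _nn.kaiming_uniform_(conv.weight, conv.fan_in, rng)
        x = rng.normal(size=(1, 1, 30, 10)).astype(np.float32)
        shifted = np.roll(x, 4, axis=2)
        a = conv.forward(x)[:, :, :-4]
        b = conv.forward(shifted)[:, :, 4:]
        # compare interior (roll wrap affects edges only)
        np.testing.assert_allclose(a[:, :, 4:], b[:, :, 4:], atol=1e-5)


class TestTraining3DFamily:
    def test_forward_backward_3d_simple(self, rng):
        """A full-size 3D architecture accepts a 16x94x60 tensor and
        backpropagates without shape errors."""
        spec = model.load_architecture("3d-simple")
        net = build_network(spec).initialize(3)
        x = rng.normal(size=(1, 1, 16, 94, 60)).astype(np.float32)
        logits = net.forward(x, train=True)
        loss, d = _nn.cross_entropy(logits, np.array([1]))
        net.zero_grad()
        net.backward(d)
        g = np.concatenate([p.grad.ravel() for p in net.parameters()])
        assert np.isfinite(loss) and np.any(g != 0)
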