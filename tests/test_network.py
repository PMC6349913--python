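"""Architecture contracts: shapes, determinism, locally-connected semantics."""

import numpy as np
import pytest

from panbind.data import BindingSample, Dataset
from panbind.encoding import encode_hla, encode_peptide
from panbind.errors import ConstructionError, NetworkShapeError, UnknownAlleleError
from panbind.network import (
    ConvBlockSpec,
    LCBlockSpec,
    NetworkConfig,
    build_network,
    load_checkpoint,
    locally_connected_apply,
    predict,
    save_checkpoint,
)


@pytest.fixture(scope="module")
def small_net():
    return build_network(NetworkConfig.reduced(seed=0))


def _random_inputs(rng, n):
    """Random valid one-hot peptide/HLA tensor batches."""
    p = np.zeros((n, 9, 20), dtype=np.float32)
    p[np.arange(n)[:, None], np.arange(9), rng.integers(0, 20, (n, 9))] = 1
    h = np.zeros((n, 372, 21), dtype=np.float32)
    h[np.arange(n)[:, None], np.arange(372), rng.integers(0, 21, (n, 372))] = 1
    return p, h


class TestShapeContract:
    def test_forward_chain_shapes(self, small_net):
        """1x9x20 + 1x372x21 -> two 1x9x10 encodings -> 1x9x20 -> 2560 -> 2 scalars."""
        p = encode_peptide("HLNPNKTKR")
        h = encode_hla("A" * 300)
        fp = small_net.peptide_encoder.forward(p.astype(np.float32))
        fh = small_net.hla_encoder.forward(h.astype(np.float32))
        assert fp.shape == (1, 9, 10)
        assert fh.shape == (1, 9, 10)
        pair, context = small_net.forward(p, h)
        assert context.shape == (2560,)
        assert 0.0 <= pair.binding_prob <= 1.0
        assert np.isfinite(pair.log_ic50_pred)

    def test_default_config_builds_2560_context(self):
        net = build_network(NetworkConfig.default(seed=1))
        rng = np.random.default_rng(0)
        p, h = _random_inputs(rng, 2)
        out = net.forward_batch(p, h)
        assert out["context"].shape == (2, 2560)

    def test_probability_bounded_on_random_inputs(self, small_net):
        rng = np.random.default_rng(42)
        p, h = _random_inputs(rng, 1000)
        out = small_net.forward_batch(p, h)
        assert np.all(out["prob"] >= 0.0) and np.all(out["prob"] <= 1.0)

    def test_invalid_shapes_rejected(self, small_net):
        with pytest.raises(NetworkShapeError):
            small_net.forward_batch(np.zeros((1, 8, 20)), np.zeros((1, 372, 21)))
        with pytest.raises(NetworkShapeError):
            small_net.forward_batch(np.zeros((1, 9, 20)), np.zeros((1, 371, 21)))

    def test_bad_extractor_flatten_rejected(self):
        cfg = NetworkConfig(
            peptide_encoder=(ConvBlockSpec(16), ConvBlockSpec(10)),
            hla_encoder=(ConvBlockSpec(16, pool=4), ConvBlockSpec(32, pool=2)),
            extractor=(LCBlockSpec(64), LCBlockSpec(256)),  # 5*256 = 1280 != 2560
        )
        with pytest.raises(ConstructionError):
            build_network(cfg)

    def test_bad_encoder_shape_rejected(self):
        cfg = NetworkConfig(
            peptide_encoder=(ConvBlockSpec(16), ConvBlockSpec(12)),  # 12 != 10 channels
            hla_encoder=(ConvBlockSpec(16, pool=4),),
            extractor=(LCBlockSpec(64), LCBlockSpec(512)),
        )
        with pytest.raises(ConstructionError):
            build_network(cfg)


class TestDeterminism:
    def test_same_seed_same_parameters(self):
        a = build_network(NetworkConfig.reduced(seed=5))
        b = build_network(NetworkConfig.reduced(seed=5))
        sa, sb = a.state_dict(), b.state_dict()
        assert sa.keys() == sb.keys()
        for k in sa:
            assert np.array_equal(sa[k], sb[k]), k

    def test_different_seed_different_parameters(self):
        a = build_network(NetworkConfig.reduced(seed=5))
        b = build_network(NetworkConfig.reduced(seed=6))
        assert any(not np.array_equal(a.state_dict()[k], b.state_dict()[k])
                   for k in a.state_dict())

    def test_forward_bit_identical(self, small_net):
        p = encode_peptide("HLNPNKTKR")
        h = encode_hla("A" * 372)
        pair1, ctx1 = small_net.forward(p, h)
        pair2, ctx2 = small_net.forward(p, h)
        assert pair1 == pair2
        assert np.array_equal(ctx1, ctx2)

    def test_context_differs_between_peptides(self, small_net):
        h = encode_hla("ACDEFGHIKL" * 37)
        _, c1 = small_net.forward(encode_peptide("HLNPNKTKR"), h)
        _, c2 = small_net.forward(encode_peptide("WYVQFMRAC"), h)
        assert not np.allclose(c1, c2)


class TestLocallyConnected:
    def test_tied_weights_equal_convolution(self):
        """With all position blocks equal, the LC layer is a plain valid conv."""
        rng = np.random.default_rng(0)
        w, c_in, c_out, k = 9, 6, 4, 3
        kernel = rng.normal(size=(k * c_in, c_out)).astype(np.float32)
        weights = np.repeat(kernel[None], w - k + 1, axis=0)
        x = rng.normal(size=(1, w, c_in)).astype(np.float32)
        out = locally_connected_apply(weights, x)
        # oracle: direct sliding-window correlation
        expected = np.zeros((1, w - k + 1, c_out))
        for i in range(w - k + 1):
            patch = x[0, i:i + k, :].reshape(-1)
            expected[0, i] = patch @ kernel
        np.testing.assert_allclose(out, expected, rtol=1e-5)

    def test_full_width_kernel_single_output(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 5, 3)).astype(np.float32)
        weights = rng.normal(size=(1, 15, 2)).astype(np.float32)
        assert locally_connected_apply(weights, x).shape == (1, 1, 2)

    def test_position_distinct_weights_break_translation(self):
        """The same patch at positions 0 and 4 gets different responses."""
        rng = np.random.default_rng(2)
        w, c, k = 9, 4, 3
        weights = rng.normal(size=(w - k + 1, k * c, 1)).astype(np.float32)
        patch = rng.normal(size=(k, c)).astype(np.float32)
        x0 = np.zeros((1, w, c), dtype=np.float32)
        x4 = np.zeros((1, w, c), dtype=np.float32)
        x0[0, 0:k] = patch
        x4[0, 4:4 + k] = patch
        r0 = locally_connected_apply(weights, x0)[0, 0, 0]
        r4 = locally_connected_apply(weights, x4)[0, 4, 0]
        assert not np.isclose(r0, r4)

    def test_output_locality(self):
        """Output position i depends only on x[i:i+k]."""
        rng = np.random.default_rng(3)
        w, c, k = 9, 4, 3
        weights = rng.normal(size=(w - k + 1, k * c, 2)).astype(np.float32)
        x = rng.normal(size=(1, w, c)).astype(np.float32)
        base = locally_connected_apply(weights, x)
        x2 = x.copy()
        x2[0, 8] += 10.0  # outside the window of output position 0
        bumped = locally_connected_apply(weights, x2)
        np.testing.assert_array_equal(base[0, 0], bumped[0, 0])
        assert not np.allclose(base[0, 6], bumped[0, 6])

    def test_kernel_wider_than_input_rejected(self):
        weights = np.zeros((1, 30, 2), dtype=np.float32)  # k = 10 for c = 3
        with pytest.raises(NetworkShapeError):
            locally_connected_apply(weights, np.zeros((1, 5, 3)))


def _toy_dataset(n=6):
    alleles = {"HLA-A*90:01": "A" * 372, "HLA-B*90:01": "C" * 300}
    peps = ["HLNPNKTKR", "AAAAAAAAA", "WYVQFMRAC", "KLMNPQRST", "CCCCCCCCC", "DEDEDEDED"]
    samples = [BindingSample.from_measurement(list(alleles)[i % 2], peps[i], "ic50", 100.0 + i)
               for i in range(n)]
    return Dataset(samples, alleles)


class TestPredict:
    def test_cardinality_and_order(self, small_net):
        ds = _toy_dataset()
        rows = predict(small_net, ds)
        assert len(rows) == len(ds)
        assert [r.sample.peptide for r in rows] == [s.peptide for s in ds.samples]

    def test_inverse_transform_applied(self, small_net):
        for r in predict(small_net, _toy_dataset()):
            assert 0.0 <= r.ic50_pred <= 80000.0
            assert r.ic50_pred == pytest.approx(
                min(np.exp(r.log_ic50_pred), 80000.0), rel=1e-6)

    def test_deterministic(self, small_net):
        ds = _toy_dataset()
        a = [(r.ic50_pred, r.binding_prob) for r in predict(small_net, ds)]
        b = [(r.ic50_pred, r.binding_prob) for r in predict(small_net, ds)]
        assert a == b

    def test_empty_dataset(self, small_net):
        assert predict(small_net, Dataset([], {})) == []

    def test_unknown_allele(self, small_net):
        ds = _toy_dataset()
        ds.allele_index.pop("HLA-B*90:01")
        with pytest.raises(UnknownAlleleError):
            predict(small_net, ds)


def test_checkpoint_round_trip(tmp_path, small_net):
    path = tmp_path / "model.npz"
    save_checkpoint(small_net, path)
    loaded = load_checkpoint(path)
    ds = _toy_dataset()
    a = [(r.ic50_pred, r.binding_prob) for r in predict(small_net, ds)]
    b = [(r.ic50_pred, r.binding_prob) for r in predict(loaded, ds)]
    assert a == b
    assert loaded.config == small_net.config
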