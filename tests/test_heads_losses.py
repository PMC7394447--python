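"""Loss terms against closed forms and brute-force oracles."""

import numpy as np
import pytest

from uncrowd.autograd import Tensor
from uncrowd.capsule_core import CapsuleNetwork, CapsuleState, NetworkConfig
from uncrowd.heads_losses import (DecoderHeads, LossWeights, MarginParams,
                                  location_loss, margin_loss,
                                  reconstruction_loss, shape_repetition_loss,
                                  total_loss, vernier_offset_loss)

LN3 = np.log(3.0)


# --------------------------------------------------------------- margin loss
def test_margin_params_validated():
    with pytest.raises(ValueError):
        MarginParams(m_plus=0.1, m_minus=0.9)
    with pytest.raises(ValueError):
        MarginParams(lambda_down=0.0)
    p = MarginParams()
    assert (p.m_plus, p.m_minus, p.lambda_down) == (0.9, 0.1, 0.5)


def test_margin_loss_zero_when_hinges_inactive():
    norms = Tensor(np.array([[0.95, 0.05, 0.02]]))
    targets = np.array([[1, 0, 0]])
    assert margin_loss(norms, targets).item() == 0.0


def test_margin_loss_present_class_at_zero_norm():
    norms = Tensor(np.array([[0.0]]))
    targets = np.array([[1]])
    np.testing.assert_allclose(margin_loss(norms, targets).item(), 0.81,
                               atol=1e-12)


def test_margin_loss_absent_class_value():
    norms = Tensor(np.array([[0.95]]))
    targets = np.array([[0]])
    np.testing.assert_allclose(margin_loss(norms, targets).item(),
                               0.5 * 0.85 ** 2, atol=1e-12)


def test_margin_loss_multiple_present_classes(rng):
    """Brute-force oracle over random norms/targets."""
    norms = rng.uniform(0, 0.999, size=(4, 7))
    targets = (rng.random(size=(4, 7)) < 0.3).astype(float)
    got = margin_loss(Tensor(norms), targets).item()
    m_plus, m_minus, lam = 0.9, 0.1, 0.5
    expected = 0.0
    for b in range(4):
        for k in range(7):
            if targets[b, k]:
                expected += max(0.0, m_plus - norms[b, k]) ** 2
            else:
                expected += lam * max(0.0, norms[b, k] - m_minus) ** 2
    np.testing.assert_allclose(got, expected / 4, atol=1e-8)


def test_margin_loss_rejects_norms_at_or_above_one():
    with pytest.raises(ValueError, match="norms"):
        margin_loss(Tensor(np.array([[1.0]])), np.array([[1]]))


# ------------------------------------------------------------ cross entropies
def test_vernier_loss_perfect_prediction_is_zero():
    scores = Tensor(np.array([[100.0, 0.0, 0.0]]))
    assert vernier_offset_loss(scores, ["left"]).item() < 1e-12


def test_vernier_loss_uniform_is_ln3():
    scores = Tensor(np.zeros((5, 3)))
    got = vernier_offset_loss(scores, ["left", "right", "none", "left",
                                       "right"]).item()
    np.testing.assert_allclose(got, LN3, atol=1e-12)


def test_vernier_loss_shift_invariance(rng):
    scores = rng.normal(size=(4, 3))
    a = vernier_offset_loss(Tensor(scores), ["left"] * 4).item()
    b = vernier_offset_loss(Tensor(scores + 7.3), ["left"] * 4).item()
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_repetition_loss_uniform_and_labels():
    scores = Tensor(np.zeros((3, 3)))
    got = shape_repetition_loss(scores, [1, 3, 5]).item()
    np.testing.assert_allclose(got, LN3, atol=1e-12)
    with pytest.raises(ValueError, match="unmapped"):
        shape_repetition_loss(scores, [1, 2, 5])


def test_repetition_loss_perfect():
    scores = np.full((1, 3), -50.0)
    scores[0, 2] = 50.0
    assert shape_repetition_loss(Tensor(scores), [5]).item() < 1e-12


def test_cross_entropy_matches_logsumexp_oracle(rng):
    from scipy.special import logsumexp
    scores = rng.normal(size=(10, 3))
    labels = rng.integers(0, 3, size=10)
    names = [("left", "right", "none")[i] for i in labels]
    got = vernier_offset_loss(Tensor(scores), names).item()
    expected = np.mean(logsumexp(scores, axis=1)
                       - scores[np.arange(10), labels])
    np.testing.assert_allclose(got, expected, atol=1e-10)


# -------------------------------------------------------------- reconstruction
def test_reconstruction_loss_identical_images(rng):
    img = rng.random(size=(2, 6, 7))
    assert reconstruction_loss(img, Tensor(img)).item() == 0.0


def test_reconstruction_loss_ones_vs_zeros():
    h, w = 9, 13
    got = reconstruction_loss(np.ones((1, h, w)), Tensor(np.zeros((1, h, w))))
    np.testing.assert_allclose(got.item(), h * w, atol=1e-12)


def test_reconstruction_loss_dimension_mismatch(rng):
    with pytest.raises(ValueError):
        reconstruction_loss(np.zeros((1, 4, 4)), Tensor(np.zeros((1, 4, 5))))


def test_reconstruction_loss_brute_force(rng):
    a = rng.random(size=(3, 5, 4))
    b = rng.random(size=(3, 5, 4))
    got = reconstruction_loss(a, Tensor(b)).item()
    np.testing.assert_allclose(got, ((a - b) ** 2).sum() / 3, atol=1e-10)


# ------------------------------------------------------------------ location
def test_location_loss_perfect():
    x = np.full((1, 10), -50.0)
    x[0, 3] = 50.0
    y = np.full((1, 8), -50.0)
    y[0, 2] = 50.0
    got = location_loss((Tensor(x), Tensor(y)), [(3, 2)], (8, 10))
    assert got.item() < 1e-10


def test_location_loss_uniform_is_2_ln_bins():
    w, h = 12, 9
    got = location_loss((Tensor(np.zeros((2, w))), Tensor(np.zeros((2, h)))),
                        [(3, 4), (5, 6)], (h, w))
    np.testing.assert_allclose(got.item(), np.log(w) + np.log(h), atol=1e-12)


def test_location_loss_coordinate_outside_canvas():
    with pytest.raises(ValueError, match="outside"):
        location_loss((Tensor(np.zeros((1, 10))), Tensor(np.zeros((1, 8)))),
                      [(10, 2)], (8, 10))


def test_location_loss_two_additive_terms(rng):
    sx = rng.normal(size=(3, 10))
    sy = rng.normal(size=(3, 8))
    xy = [(1, 2), (3, 4), (5, 6)]
    both = location_loss((Tensor(sx), Tensor(sy)), xy, (8, 10)).item()
    from uncrowd.heads_losses import cross_entropy_loss
    x_only = cross_entropy_loss(Tensor(sx), np.array([1, 3, 5]), 10).item()
    y_only = cross_entropy_loss(Tensor(sy), np.array([2, 4, 6]), 8).item()
    np.testing.assert_allclose(both, x_only + y_only, atol=1e-10)


# ---------------------------------------------------------------- total loss
def test_total_loss_zero_components():
    comps = {k: Tensor(np.array(0.0)) for k in
             ("shape_type", "vernier_offset", "shape_repetitions",
              "reconstruction", "location")}
    assert total_loss(comps, experiment=1).item() == 0.0


def test_total_loss_unit_components_printed_alphas():
    comps = {k: Tensor(np.array(1.0)) for k in
             ("shape_type", "vernier_offset", "shape_repetitions",
              "reconstruction", "location")}
    np.testing.assert_allclose(total_loss(comps, experiment=1).item(),
                               2.0005, atol=1e-12)


def test_total_loss_experiment2_drops_terms():
    comps = {"shape_type": Tensor(np.array(1.0)),
             "vernier_offset": Tensor(np.array(1.0)),
             "reconstruction": Tensor(np.array(1.0)),
             "shape_repetitions": Tensor(np.array(100.0)),
             "location": Tensor(np.array(100.0))}
    np.testing.assert_allclose(total_loss(comps, experiment=2).item(),
                               0.5 + 1.0 + 0.0005, atol=1e-12)


def test_total_loss_linear_in_components(rng):
    for name, alpha in (("shape_type", 0.5), ("vernier_offset", 1.0),
                        ("shape_repetitions", 0.4),
                        ("reconstruction", 0.0005), ("location", 0.1)):
        comps = {k: Tensor(np.array(0.0)) for k in
                 ("shape_type", "vernier_offset", "shape_repetitions",
                  "reconstruction", "location")}
        comps[name] = Tensor(np.array(2.0))
        np.testing.assert_allclose(total_loss(comps, experiment=1).item(),
                                   2.0 * alpha, atol=1e-12)


def test_total_loss_rejects_negative_components():
    comps = {"shape_type": Tensor(np.array(-0.1)),
             "vernier_offset": Tensor(np.array(0.0)),
             "reconstruction": Tensor(np.array(0.0))}
    with pytest.raises(ValueError, match="negative"):
        total_loss(comps, experiment=2)


def test_loss_weights_defaults():
    w = LossWeights()
    assert (w.alpha_shape_type, w.alpha_vernier_offset,
            w.alpha_shape_repetitions, w.alpha_reconstruction,
            w.alpha_location) == (0.5, 1.0, 0.4, 0.0005, 0.1)


# ------------------------------------------------------------------ decoders
@pytest.fixture
def heads(tiny_net_cfg, rng):
    return DecoderHeads(tiny_net_cfg, rng, n_classes=7)


@pytest.fixture
def secondary(tiny_net_cfg, rng):
    m, d = tiny_net_cfg.n_capsule_types, tiny_net_cfg.secondary_dim
    return CapsuleState(Tensor(rng.normal(size=(2, m, d)) * 0.1), n_types=m)


def test_vernier_decoder_output_dimension(heads, secondary):
    assert heads.decode_vernier(secondary).shape == (2, 3)


def test_vernier_decoder_reads_only_vernier_capsule(heads, secondary,
                                                    tiny_net_cfg):
    v = secondary.vectors.data.copy()
    v2 = v.copy()
    v2[:, 1:, :] = 0.0   # zero all non-vernier capsules
    a = heads.decode_vernier(CapsuleState(Tensor(v), 7), vernier_index=0)
    b = heads.decode_vernier(CapsuleState(Tensor(v2), 7), vernier_index=0)
    np.testing.assert_array_equal(a.data, b.data)


def test_vernier_decoder_zero_input_gives_biases(heads, tiny_net_cfg):
    m, d = 7, tiny_net_cfg.secondary_dim
    zero = CapsuleState(Tensor(np.zeros((1, m, d))), m)
    out = heads.decode_vernier(zero).data
    # hidden ReLU(0 + b1) then W2 + b2
    b1 = heads.params["vern1_b"].data
    expected = np.maximum(b1, 0) @ heads.params["vern2_w"].data \
        + heads.params["vern2_b"].data
    np.testing.assert_allclose(out[0], expected, atol=1e-6)


def test_reconstruction_decoder_hidden_sizes_default():
    assert NetworkConfig().recon_hidden == (512, 1024)


def test_reconstruction_shape_and_masking(heads, secondary, tiny_net_cfg):
    h, w = tiny_net_cfg.image_shape
    out = heads.reconstruct(secondary)
    assert out.shape == (2, h, w)
    mask = np.zeros((2, 7))
    mask[:, 3] = 1
    out_masked = heads.reconstruct(secondary, mask=mask)
    assert out_masked.shape == (2, h, w)
    with pytest.raises(ValueError, match="mask"):
        heads.reconstruct(secondary, mask=np.zeros((2, 7)))


def test_reconstruction_all_capsules_zeroed_is_constant(heads, tiny_net_cfg):
    m, d = 7, tiny_net_cfg.secondary_dim
    zero = CapsuleState(Tensor(np.zeros((3, m, d))), m)
    out = heads.reconstruct(zero).data
    assert np.allclose(out, out[0])  # same image for every batch element
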