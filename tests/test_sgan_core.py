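"""The adversarial networks and the four loss quantities.

The real/fake probability D(x) = Z/(Z+1) is checked against its algebraic
equivalent — the fake-class probability of a 3-way softmax with the third
logit pinned at zero — and each loss against a naive direct-formula oracle.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import softmax

from sganvi import sgan_core
from sganvi.sgan_core import (Generator, Discriminator, GeneratorSpec,
                              DiscriminatorSpec, DiscriminatorOutput,
                              class_probabilities, supervised_loss,
                              real_fake_probability, unsupervised_loss,
                              discriminator_loss, feature_matching_loss)

finite_logits = st.floats(min_value=-50, max_value=50, allow_nan=False)


# ---------------------------------------------------------------------- #
# class probabilities and supervised loss
# ---------------------------------------------------------------------- #

def test_class_probabilities_examples():
    np.testing.assert_allclose(class_probabilities([[0.0, 0.0]]),
                               [[0.5, 0.5]])
    np.testing.assert_allclose(class_probabilities([[0.0, np.log(3)]]),
                               [[0.25, 0.75]], atol=1e-12)
    # extreme logits survive without overflow
    p = class_probabilities([[1000.0, 0.0]])
    assert np.isfinite(p).all() and p[0, 0] > 0.999999


@settings(deadline=None, derandomize=True)
@given(st.lists(st.tuples(finite_logits, finite_logits), min_size=1, max_size=30))
def test_class_probabilities_sum_to_one(logit_pairs):
    p = class_probabilities(np.array(logit_pairs))
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


def test_supervised_loss_uniform_prediction_is_ln2():
    logits = np.zeros((8, 2))
    labels = np.array([0, 1] * 4)
    assert supervised_loss(logits, labels) == pytest.approx(np.log(2), abs=1e-12)


def test_supervised_loss_confident_correct_approaches_zero():
    logits = np.array([[30.0, -30.0], [-30.0, 30.0]])
    assert supervised_loss(logits, np.array([0, 1])) < 1e-10


def test_supervised_loss_matches_direct_cross_entropy():
    rng = np.random.default_rng(8)
    logits = rng.normal(0, 3, (64, 2))
    labels = rng.integers(0, 2, 64)
    p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    expected = -np.mean(np.log(p[np.arange(64), labels]))
    assert supervised_loss(logits, labels) == pytest.approx(expected, abs=1e-9)


def test_supervised_loss_rejects_unlabeled_and_empty():
    with pytest.raises(ValueError):
        supervised_loss(np.zeros((2, 2)), np.array([0, -1]))
    with pytest.raises(ValueError):
        supervised_loss(np.zeros((0, 2)), np.array([], dtype=int))


# ---------------------------------------------------------------------- #
# real/fake probability and unsupervised loss
# ---------------------------------------------------------------------- #

def test_real_fake_probability_forced_arithmetic():
    # Z = e^0 + e^0 = 2 -> D = 2/3
    assert real_fake_probability([[0.0, 0.0]])[0] == pytest.approx(2 / 3, abs=1e-12)
    # very negative logits: the sample looks synthetic
    assert real_fake_probability([[-200.0, -200.0]])[0] < 1e-80
    # very positive logits: clearly real, no overflow
    assert real_fake_probability([[500.0, 400.0]])[0] == pytest.approx(1.0)


def test_real_fake_probability_equals_k_plus_one_softmax():
    rng = np.random.default_rng(9)
    logits = rng.normal(0, 10, (1000, 2))
    padded = np.concatenate([logits, np.zeros((1000, 1))], axis=1)
    fake_class_prob = softmax(padded, axis=1)[:, 2]
    np.testing.assert_allclose(real_fake_probability(logits),
                               1.0 - fake_class_prob, atol=1e-12)


moderate_logits = st.floats(min_value=-20, max_value=3, allow_nan=False)


@settings(deadline=None, derandomize=True)
@given(moderate_logits, moderate_logits, st.floats(min_value=1e-3, max_value=5))
def test_real_fake_probability_open_interval_and_monotone(l1, l2, eps):
    # restricted to logits where D is not saturated to within one ulp of 1,
    # so strict inequalities are meaningful in double precision
    d = real_fake_probability([[l1, l2]])[0]
    assert 0.0 < d < 1.0
    assert real_fake_probability([[l1 + eps, l2]])[0] > d
    assert real_fake_probability([[l1, l2 + eps]])[0] > d


def test_unsupervised_loss_forced_arithmetic():
    # D(real) = 2/3, 1 - D(fake) = 1/3
    value = unsupervised_loss(np.zeros((1, 2)), np.zeros((1, 2)))
    assert value == pytest.approx(-(np.log(2 / 3) + np.log(1 / 3)), abs=1e-12)


def test_unsupervised_loss_vanishes_for_optimal_discriminator():
    real = np.full((4, 2), 40.0)    # D -> 1
    fake = np.full((4, 2), -40.0)   # D -> 0
    assert unsupervised_loss(real, fake) < 1e-12


def test_unsupervised_loss_matches_naive_formula():
    rng = np.random.default_rng(10)
    real = rng.normal(0, 2, (50, 2))
    fake = rng.normal(0, 2, (60, 2))
    z_r = np.exp(real).sum(axis=1)
    z_f = np.exp(fake).sum(axis=1)
    naive = -(np.mean(np.log(z_r / (z_r + 1)))
              + np.mean(np.log(1 / (z_f + 1))))
    assert unsupervised_loss(real, fake) == pytest.approx(naive, abs=1e-9)


def test_discriminator_loss_is_plain_sum():
    assert discriminator_loss(0.5, 1.0) == 1.5
    assert discriminator_loss(0.0, 0.0) == 0.0


# ---------------------------------------------------------------------- #
# feature matching
# ---------------------------------------------------------------------- #

def _out(features, logits=None):
    features = np.asarray(features, dtype=np.float64)
    if logits is None:
        logits = np.zeros((features.shape[0], 2))
    return DiscriminatorOutput(logits=logits, features=features)


def test_feature_matching_loss_identity_and_example():
    f = np.random.default_rng(0).normal(size=(5, 7))
    assert feature_matching_loss(_out(f), _out(f.copy())) == 0.0
    real = np.zeros((4, 6))
    fake = np.zeros((4, 6))
    real[:, 0], real[:, 1] = 0.3, -0.4  # mean difference (0.3, -0.4, 0...)
    assert feature_matching_loss(_out(real), _out(fake)) == pytest.approx(0.25)


def test_feature_matching_loss_matches_mean_then_norm_oracle():
    rng = np.random.default_rng(11)
    fr, ff = rng.normal(size=(30, 16)), rng.normal(size=(20, 16))
    expected = float(np.sum((fr.mean(axis=0) - ff.mean(axis=0)) ** 2))
    assert feature_matching_loss(_out(fr), _out(ff)) == pytest.approx(expected, abs=1e-9)


def test_feature_matching_loss_rejects_dimension_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        feature_matching_loss(_out(np.zeros((3, 4))), _out(np.zeros((3, 5))))


# ---------------------------------------------------------------------- #
# networks
# ---------------------------------------------------------------------- #

SMALL_GEN = GeneratorSpec(noise_dim=16, hidden_sizes=(8, 12, 16), output_dim=24)
SMALL_DISC = DiscriminatorSpec(input_dim=24, channels=(4, 8, 8))


def test_generator_output_in_unit_interval_even_untrained():
    rng = np.random.default_rng(12)
    gen = Generator(SMALL_GEN, rng)
    out = gen.sample(500, rng)
    assert out.shape == (500, 24)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_generator_rejects_wrong_noise_dimension():
    gen = Generator(SMALL_GEN, np.random.default_rng(0))
    with pytest.raises(ValueError, match="noise"):
        gen.forward(np.zeros((3, 7)))


def test_generator_eval_mode_is_deterministic():
    gen = Generator(SMALL_GEN, np.random.default_rng(1))
    z = np.random.default_rng(2).standard_normal((10, 16))
    np.testing.assert_array_equal(gen.forward(z, train=False),
                                  gen.forward(z, train=False))


def test_discriminator_exposes_two_logits_and_features():
    disc = Discriminator(SMALL_DISC, np.random.default_rng(3))
    out = disc.forward(np.random.default_rng(4).random((7, 24)))
    assert out.logits.shape == (7, 2)
    assert out.features.shape == (7, disc.n_features)
    assert np.isfinite(out.logits).all() and np.isfinite(out.features).all()


def test_discriminator_feature_source_switch():
    spec = DiscriminatorSpec(input_dim=24, channels=(4, 8, 8),
                             feature_source="logits")
    disc = Discriminator(spec, np.random.default_rng(5))
    out = disc.forward(np.random.default_rng(6).random((5, 24)))
    np.testing.assert_array_equal(out.features, out.logits)


def test_discriminator_rejects_wrong_width():
    disc = Discriminator(SMALL_DISC, np.random.default_rng(7))
    with pytest.raises(ValueError, match="input"):
        disc.forward(np.zeros((2, 25)))


def test_whole_network_gradients_match_finite_differences():
    """End-to-end gradcheck: supervised loss through the discriminator."""
    from test_nn import numeric_grad

    disc = Discriminator(DiscriminatorSpec(input_dim=12, channels=(3, 4)),
                         np.random.default_rng(8))
    x = np.random.default_rng(9).random((6, 12))
    labels = np.array([0, 1, 0, 1, 0, 1])

    def run():
        out = disc.forward(x, train=True)
        return sgan_core.supervised_loss(out.logits, labels)

    out = disc.forward(x, train=True)
    _, grad = sgan_core.supervised_loss_grad(out.logits, labels)
    disc.zero_grad()
    grad_x = disc.backward(grad_logits=grad)
    np.testing.assert_allclose(grad_x, numeric_grad(run, x), atol=1e-7)
    for j, p in enumerate(disc.parameters()):
        np.testing.assert_allclose(p.grad, numeric_grad(run, p.value),
                                   atol=1e-7, err_msg=f"param {j}")


def test_single_discriminator_step_reduces_loss_on_separable_data():
    from sganvi import nn
    rng = np.random.default_rng(13)
    disc = Discriminator(SMALL_DISC, np.random.default_rng(14))
    x = np.vstack([rng.normal(0.2, 0.02, (40, 24)),
                   rng.normal(0.8, 0.02, (40, 24))])
    labels = np.array([0] * 40 + [1] * 40)
    opt = nn.Adam(disc.parameters(), lr=0.01)

    def loss():
        return sgan_core.supervised_loss(disc.forward(x, train=True).logits,
                                         labels)

    before = loss()
    disc.zero_grad()
    out = disc.forward(x, train=True)
    _, grad = sgan_core.supervised_loss_grad(out.logits, labels)
    disc.backward(grad_logits=grad)
    opt.step()
    assert loss() < before
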