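"""Objective-function identities checked against hand arithmetic and
independent pixel-loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ct2adc.features import build_extractor
from ct2adc.losses import (
    LossBundle,
    LossWeights,
    adversarial_loss,
    cycle_loss,
    fidelity_loss,
    identity_loss,
    l1_cycle_identity_losses,
    make_bundle,
    total_loss,
)


@pytest.fixture(scope="module")
def identity_fx():
    return build_extractor("fixed_random", layer_tag="input", seed=0)


def pixel_loop_mean_sq(a, b):
    """Brute-force elementwise mean-square oracle."""
    total, count = 0.0, 0
    for x, y in zip(np.ravel(a), np.ravel(b)):
        total += (x - y) ** 2
        count += 1
    return total / count


# ---------------------------------------------------------------------------
# adversarial
# ---------------------------------------------------------------------------

def test_generator_loss_zero_when_fooling_perfectly():
    fake = np.ones((2, 1, 4, 4))
    assert adversarial_loss(None, fake, role="generator") == 0.0


def test_discriminator_loss_zero_when_perfectly_separating():
    real = np.ones((2, 1, 4, 4))
    fake = np.zeros((2, 1, 4, 4))
    assert adversarial_loss(real, fake, role="discriminator") == 0.0


def test_half_scores_give_quarter_for_both_roles():
    s = np.full((3, 1, 5, 5), 0.5)
    assert adversarial_loss(s, s, role="generator") == pytest.approx(0.25)
    assert adversarial_loss(s, s, role="discriminator") == pytest.approx(0.25)


def test_mismatched_score_shapes_rejected():
    with pytest.raises(ValueError):
        adversarial_loss(np.ones((1, 1, 4, 4)), np.ones((1, 1, 3, 3)),
                         role="discriminator")


def test_unknown_role_and_objective_rejected():
    s = np.ones((1, 1, 2, 2))
    with pytest.raises(ValueError):
        adversarial_loss(s, s, role="critic")
    with pytest.raises(ValueError):
        adversarial_loss(s, s, role="generator", objective="wasserstein")


def test_cross_entropy_objective_is_minimised_by_confident_scores():
    good = adversarial_loss(None, np.full((1, 1, 4, 4), 10.0), "generator",
                            objective="cross_entropy")
    bad = adversarial_loss(None, np.full((1, 1, 4, 4), -10.0), "generator",
                           objective="cross_entropy")
    assert good < 1e-3 < bad


# ---------------------------------------------------------------------------
# fidelity
# ---------------------------------------------------------------------------

def test_fidelity_zero_at_equality(identity_fx, rng):
    a = rng.normal(size=(1, 8, 8))
    assert fidelity_loss(a, a.copy(), identity_fx) == 0.0


def test_fidelity_hand_arithmetic(identity_fx):
    a = np.array([[1.0, 2.0]])
    b = np.array([[1.0, 4.0]])
    assert fidelity_loss(a, b, identity_fx) == pytest.approx(2.0)


def test_fidelity_shape_mismatch(identity_fx):
    with pytest.raises(ValueError):
        fidelity_loss(np.ones((4, 4)), np.ones((5, 5)), identity_fx)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_fidelity_symmetric_and_nonnegative(seed):
    fx = build_extractor("fixed_random", seed=11)
    r = np.random.default_rng(seed)
    a = r.normal(size=(1, 16, 16)).astype(np.float32)
    b = r.normal(size=(1, 16, 16)).astype(np.float32)
    ab = fidelity_loss(a, b, fx)
    assert ab >= 0.0
    assert ab == pytest.approx(fidelity_loss(b, a, fx), rel=1e-5)


def test_fidelity_equals_pixel_oracle_with_identity_extractor(identity_fx, rng):
    a = rng.normal(size=(16, 16))
    b = rng.normal(size=(16, 16))
    assert fidelity_loss(a, b, identity_fx) == pytest.approx(
        pixel_loop_mean_sq(a, b), rel=1e-6)


# ---------------------------------------------------------------------------
# cycle / identity
# ---------------------------------------------------------------------------

class _Pair:
    def __init__(self, ct, adc):
        self.ct, self.adc = ct, adc


def test_cycle_loss_vanishes_for_oracle_generators(identity_fx, rng):
    pairs = [_Pair(rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8)))
             for _ in range(3)]
    targets_adc = np.stack([2 * p.adc - 1 for p in pairs])[:, None]
    targets_ct = np.stack([2 * p.ct - 1 for p in pairs])[:, None]
    g_mri = lambda x: targets_adc  # outputs exactly the paired targets
    g_ct = lambda x: targets_ct
    assert cycle_loss(pairs, g_mri, g_ct, identity_fx) == 0.0


def test_cycle_loss_identity_generators_match_pixel_oracle(identity_fx, rng):
    pairs = [_Pair(rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8)))]
    ident = lambda x: x
    got = cycle_loss(pairs, ident, ident, identity_fx)
    ct = 2 * pairs[0].ct - 1
    adc = 2 * pairs[0].adc - 1
    expected = pixel_loop_mean_sq(ct, adc) + pixel_loop_mean_sq(adc, ct)
    assert got == pytest.approx(expected, rel=1e-6)


def test_cycle_loss_value_is_independent_of_loss_weights(identity_fx, rng):
    pairs = [_Pair(rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8)))]
    ident = lambda x: x
    v = cycle_loss(pairs, ident, ident, identity_fx)
    # weights enter only in total_loss; cycle_loss has no weight argument
    assert total_loss(0.0, v, 0.0, LossWeights(2.0, 9.0)) == pytest.approx(2 * v)


def test_two_step_cycle_mode_vanishes_for_inverse_generators(identity_fx, rng):
    pairs = [_Pair(rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8)))]
    flip = lambda x: -x  # an involution: two steps recover the source
    assert cycle_loss(pairs, flip, flip, identity_fx,
                      mode="two_step") == pytest.approx(0.0)


def test_identity_loss_vanishes_for_identity_generators(identity_fx, rng):
    pairs = [_Pair(rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8)))]
    ident = lambda x: x
    assert identity_loss(pairs, ident, ident, identity_fx) == 0.0


def test_identity_loss_constant_zero_generator_hand_value(identity_fx):
    ct01 = np.full((4, 4), 0.75)   # model scale 0.5
    pairs = [_Pair(ct01, ct01.copy())]
    zero = lambda x: np.zeros_like(x)
    # each direction contributes mean-square(0.5) = 0.25
    assert identity_loss(pairs, zero, zero, identity_fx) == pytest.approx(0.5)


def test_unpaired_batch_rejected(identity_fx):
    with pytest.raises(ValueError):
        cycle_loss([object()], lambda x: x, lambda x: x, identity_fx)


# ---------------------------------------------------------------------------
# L1 ablation variants
# ---------------------------------------------------------------------------

def test_l1_losses_zero_for_perfect_generators(rng):
    pairs = [_Pair(rng.uniform(size=(6, 6)), rng.uniform(size=(6, 6)))]
    t_adc = (2 * pairs[0].adc - 1)[None, None]
    t_ct = (2 * pairs[0].ct - 1)[None, None]
    cyc, idt = l1_cycle_identity_losses(
        pairs, lambda x: t_adc if x is not t_adc else x, lambda x: t_ct)
    assert cyc == pytest.approx(0.0)


def test_l1_constant_offset_gives_offset_per_direction(rng):
    pairs = [_Pair(rng.uniform(size=(6, 6)), rng.uniform(size=(6, 6)))]
    d = 0.125
    t_adc = (2 * pairs[0].adc - 1)[None, None]
    t_ct = (2 * pairs[0].ct - 1)[None, None]
    cyc, idt = l1_cycle_identity_losses(
        pairs, lambda x: t_adc + d, lambda x: t_ct + d)
    assert cyc == pytest.approx(2 * d, rel=1e-6)


def test_l1_matches_pixel_loop_oracle(rng):
    pairs = [_Pair(rng.uniform(size=(5, 5)), rng.uniform(size=(5, 5)))]
    ident = lambda x: x
    cyc, idt = l1_cycle_identity_losses(pairs, ident, ident)
    ct = 2 * pairs[0].ct - 1
    adc = 2 * pairs[0].adc - 1
    loop = sum(abs(x - y) for x, y in zip(ct.ravel(), adc.ravel())) / ct.size
    assert cyc == pytest.approx(2 * loop, rel=1e-6)
    assert idt == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# total
# ---------------------------------------------------------------------------

def test_total_loss_weighted_arithmetic():
    assert total_loss(1.0, 2.0, 3.0, LossWeights(10.0, 5.0)) == 36.0
    assert total_loss(7.0, 2.0, 3.0, LossWeights(0.0, 0.0)) == 7.0


def test_total_loss_monotone_in_components(rng):
    w = LossWeights(3.0, 2.0)
    base = total_loss(1.0, 1.0, 1.0, w)
    assert total_loss(1.5, 1.0, 1.0, w) > base
    assert total_loss(1.0, 1.5, 1.0, w) > base
    assert total_loss(1.0, 1.0, 1.5, w) > base


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        LossWeights(-1.0, 0.0)


def test_bundle_total_is_exact_composition(rng):
    w = LossWeights(10.0, 5.0)
    adv, cyc, idt = rng.uniform(size=3)
    b = make_bundle(adv, cyc, idt, w)
    assert isinstance(b, LossBundle)
    assert b.total == pytest.approx(adv + 10 * cyc + 5 * idt, rel=1e-12)
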