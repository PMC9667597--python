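"""The three loss levels: reconstruction MSE, supervised contrastive loss,
and the scheduled cross-entropy / focal classification loss."""

import math

import numpy as np
import pytest

from ddiscl.losses import (
    ClassificationLossConfig,
    ContrastiveConfig,
    TrainingDivergenceError,
    focal_loss,
    mse_loss,
    select_classification_loss,
    smoothed_cross_entropy,
    supervised_contrastive_loss,
    total_loss,
)

RNG = np.random.default_rng(7)


def scl_oracle(cfvs, labels, tau):
    """Naive triple-loop evaluation of the supervised contrastive loss."""
    n = len(labels)

    def sim(u, v):
        return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))

    total = 0.0
    for i in range(n):
        positives = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not positives:
            continue
        li = 0.0
        for j in positives:
            den = sum(math.exp(sim(cfvs[i], cfvs[k]) / tau) for k in range(n) if k != i)
            li += math.log(math.exp(sim(cfvs[i], cfvs[j]) / tau) / den)
        total += -li / len(positives)
    return total / n


# ------------------------------------------------------------------- MSE
def test_mse_identity_is_zero():
    x = RNG.normal(size=8)
    assert float(mse_loss(x, x)) == 0.0


def test_mse_hand_value():
    assert float(mse_loss(np.array([1.0, 0.0]), np.array([0.0, 0.0]))) == 0.5


def test_mse_quadratic_homogeneity():
    x = RNG.normal(size=6)
    y = RNG.normal(size=6)
    base = float(mse_loss(x, y))
    assert float(mse_loss(3.0 * x, 3.0 * y)) == pytest.approx(9.0 * base)


def test_mse_shape_mismatch():
    with pytest.raises(ValueError):
        mse_loss(np.zeros(3), np.zeros(4))


# ------------------------------------------------- supervised contrastive
def test_scl_two_sample_same_class_is_zero():
    cfvs = RNG.normal(size=(2, 5))
    assert float(supervised_contrastive_loss(cfvs, [3, 3])) == pytest.approx(0.0)


def test_scl_all_singleton_classes_is_zero():
    cfvs = RNG.normal(size=(5, 4))
    assert float(supervised_contrastive_loss(cfvs, [0, 1, 2, 3, 4])) == 0.0


def test_scl_matches_triple_loop_oracle():
    cfg = ContrastiveConfig(temperature=0.05)
    worst = 0.0
    for _ in range(200):
        n = int(RNG.integers(2, 17))
        d = int(RNG.integers(2, 33))
        c = int(RNG.integers(1, 6))
        cfvs = RNG.normal(size=(n, d))
        labels = RNG.integers(0, c, size=n)
        ours = float(supervised_contrastive_loss(cfvs, labels, cfg))
        ref = scl_oracle(cfvs, labels, cfg.temperature)
        worst = max(worst, abs(ours - ref))
    assert worst < 1e-6


def test_scl_nonnegative_and_invariances():
    cfg = ContrastiveConfig(temperature=0.05)
    cfvs = RNG.normal(size=(10, 6))
    labels = RNG.integers(0, 3, size=10)
    base = float(supervised_contrastive_loss(cfvs, labels, cfg))
    assert base >= 0.0
    # batch permutation
    perm = RNG.permutation(10)
    assert float(
        supervised_contrastive_loss(cfvs[perm], labels[perm], cfg)
    ) == pytest.approx(base, abs=1e-5)
    # common orthogonal rotation
    q, _ = np.linalg.qr(RNG.normal(size=(6, 6)))
    assert float(
        supervised_contrastive_loss(cfvs @ q, labels, cfg)
    ) == pytest.approx(base, abs=1e-5)
    # positive rescaling of a single embedding (cosine similarity)
    scaled = cfvs.copy()
    scaled[3] *= 17.0
    assert float(
        supervised_contrastive_loss(scaled, labels, cfg)
    ) == pytest.approx(base, abs=1e-5)


def test_scl_input_validation():
    with pytest.raises(ValueError):
        supervised_contrastive_loss(RNG.normal(size=(1, 4)), [0])
    bad = RNG.normal(size=(3, 4))
    bad[1] = 0.0
    with pytest.raises(ValueError):
        supervised_contrastive_loss(bad, [0, 0, 1])
    with pytest.raises(ValueError):
        ContrastiveConfig(temperature=0.0)


# ------------------------------------------------------- classification
def test_smoothed_ce_epsilon_zero_is_plain_ce():
    logits = RNG.normal(size=(5, 4))
    y = RNG.integers(0, 4, size=5)
    lp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
    expected = -lp[np.arange(5), y].mean()
    assert float(smoothed_cross_entropy(logits, y, 0.0)) == pytest.approx(expected)


def test_smoothed_ce_target_convention():
    # eps=0.3, 3 classes, label 0 -> target (0.8, 0.1, 0.1)
    logits = np.array([0.3, -0.7, 1.1])
    lp = logits - np.log(np.exp(logits).sum())
    expected = -(0.8 * lp[0] + 0.1 * lp[1] + 0.1 * lp[2])
    assert float(smoothed_cross_entropy(logits, 0, 0.3)) == pytest.approx(expected)


def test_smoothed_ce_label_out_of_range():
    with pytest.raises(ValueError):
        smoothed_cross_entropy(np.zeros(3), 3, 0.1)


def test_focal_perfectly_classified_is_zero():
    logits = np.array([100.0, 0.0, 0.0])
    assert float(focal_loss(logits, 0, gamma=2.0)) == pytest.approx(0.0, abs=1e-12)


def test_focal_gamma_zero_equals_unsmoothed_ce():
    worst = 0.0
    for _ in range(1000):
        c = int(RNG.integers(2, 8))
        logits = RNG.normal(size=c) * 3
        y = int(RNG.integers(0, c))
        worst = max(
            worst,
            abs(float(focal_loss(logits, y, 0.0))
                - float(smoothed_cross_entropy(logits, y, 0.0))),
        )
    assert worst < 1e-7


def test_focal_hand_value_half_probability():
    # p_t = 0.5, gamma = 2 -> 0.25 * ln 2
    logits = np.array([0.0, 0.0])
    assert float(focal_loss(logits, 0, gamma=2.0)) == pytest.approx(0.25 * math.log(2))


def test_focal_below_ce_pointwise():
    for _ in range(200):
        c = int(RNG.integers(2, 6))
        logits = RNG.normal(size=c) * 2
        y = int(RNG.integers(0, c))
        assert float(focal_loss(logits, y, 2.0)) <= float(
            smoothed_cross_entropy(logits, y, 0.0)
        ) + 1e-12


# ---------------------------------------------------------- scheduling
@pytest.mark.parametrize(
    "epoch,switch,expected",
    [(10, 40, "cross_entropy"), (39, 40, "cross_entropy"), (40, 40, "focal"),
     (119, 40, "focal"), (0, 0, "focal")],
)
def test_loss_schedule(epoch, switch, expected):
    cfg = ClassificationLossConfig(switch_epoch=switch, total_epochs=120)
    assert select_classification_loss(epoch, cfg) == expected


def test_loss_schedule_epoch_out_of_range():
    cfg = ClassificationLossConfig()
    with pytest.raises(ValueError):
        select_classification_loss(120, cfg)


# ------------------------------------------------------------- totals
def test_total_loss_additive_and_commutative():
    b = total_loss(0.1, 0.2, 0.3)
    assert b.total == pytest.approx(0.6)
    assert total_loss(0.3, 0.1, 0.2).total == pytest.approx(b.total)
    assert total_loss(0.0, 0.0, 0.0).total == 0.0


def test_total_loss_flags_nonfinite_component():
    with pytest.raises(TrainingDivergenceError, match="l_con"):
        total_loss(0.1, float("nan"), 0.3)
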