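"""Fine-tuning losses (closed forms + properties), up-sampling policy,
pseudo-labeling, and the early-stopping training loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entner import (
    DistributionPair,
    EncoderConfig,
    FinetuneConfig,
    LabelScheme,
    NERModel,
    TaggedSentence,
    Token,
    Vocab,
    finetune_loss,
    pseudo_label,
    rdrop_loss,
    token_ce_loss,
    two_pass_forward,
    upsample,
)
from entner.errors import ConfigurationError, ContractError
from entner.finetuning import train


# ---------------------------------------------------------------------------
# Cross-entropy with label smoothing
# ---------------------------------------------------------------------------

def test_ce_perfect_onehot_no_smoothing_is_zero():
    p = np.array([[1.0 - 2e-13, 1e-13, 1e-13]])
    assert token_ce_loss(p, [0], epsilon=0.0) < 1e-10


def test_ce_uniform_19_labels_is_ln19():
    C = 19
    p = np.full((4, C), 1.0 / C)
    assert abs(token_ce_loss(p, [3, 0, 7, 18], epsilon=0.0) - math.log(C)) < 1e-9


def test_ce_smoothed_hand_case():
    """2-label toy: yhat=(0.8, 0.2), gold=0, eps=0.1; smoothed targets are
    (1-eps)*onehot + eps/C = (0.95, 0.05)."""
    p = np.array([[0.8, 0.2]])
    expected = -(0.95 * math.log(0.8) + 0.05 * math.log(0.2))
    assert abs(token_ce_loss(p, [0], epsilon=0.1) - expected) < 1e-9


def test_ce_smoothing_floor_matches_closed_form():
    """As the true-label probability -> 1, the loss approaches the
    eps-dependent floor -sum_j (eps/C) log(yhat_j)."""
    eps = 0.1
    p = np.array([[1.0 - 1e-9, 0.5e-9, 0.5e-9]])
    C = 3
    floor = -(1 - eps) * math.log(p[0, 0]) - (eps / C) * np.log(p[0]).sum()
    assert abs(token_ce_loss(p, [0], epsilon=eps) - floor) < 1e-9


def test_ce_rejects_unnormalized_rows():
    with pytest.raises(ContractError, match="normalized"):
        token_ce_loss(np.array([[0.5, 0.2]]), [0])


# ---------------------------------------------------------------------------
# R-drop
# ---------------------------------------------------------------------------

def test_rdrop_identical_distributions_zero():
    p = np.array([[0.3, 0.7], [0.5, 0.5]])
    assert rdrop_loss(DistributionPair(p, p.copy())) == 0.0


def test_rdrop_hand_case_half_quarter():
    """Single token, P1=(0.5,0.5), P2=(0.25,0.75): direct evaluation of both
    KL terms and their half-sum gives ~0.1373 nats."""
    p1 = np.array([[0.5, 0.5]])
    p2 = np.array([[0.25, 0.75]])
    kl12 = 0.5 * math.log(0.5 / 0.25) + 0.5 * math.log(0.5 / 0.75)
    kl21 = 0.25 * math.log(0.25 / 0.5) + 0.75 * math.log(0.75 / 0.5)
    expected = 0.5 * (kl12 + kl21)
    val = rdrop_loss(DistributionPair(p1, p2))
    assert abs(val - expected) < 1e-9
    assert abs(val - 0.1373) < 5e-4


def test_rdrop_symmetry():
    rng = np.random.default_rng(0)
    p1 = rng.dirichlet(np.ones(5), size=7)
    p2 = rng.dirichlet(np.ones(5), size=7)
    assert abs(rdrop_loss(DistributionPair(p1, p2)) - rdrop_loss(DistributionPair(p2, p1))) < 1e-12


@settings(max_examples=100, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_rdrop_nonnegative_property(seed):
    rng = np.random.default_rng(seed)
    n, C = int(rng.integers(1, 6)), int(rng.integers(2, 8))
    p1 = rng.dirichlet(np.ones(C), size=n)
    p2 = rng.dirichlet(np.ones(C), size=n)
    assert rdrop_loss(DistributionPair(p1, p2)) >= 0.0


def test_rdrop_shape_mismatch_rejected():
    with pytest.raises(ContractError):
        DistributionPair(np.ones((1, 2)) / 2, np.ones((2, 2)) / 2)


# ---------------------------------------------------------------------------
# Combined objective
# ---------------------------------------------------------------------------

def test_finetune_loss_arithmetic():
    assert finetune_loss(1.0, 0.2, 1.0) == pytest.approx(1.2)
    assert finetune_loss(1.0, 0.2, 0.0) == pytest.approx(1.0)


def test_finetune_loss_monotone_in_alpha():
    vals = [finetune_loss(0.5, 0.3, a) for a in (0.0, 0.5, 1.0, 2.0)]
    assert vals == sorted(vals)
    # exact linearity
    assert finetune_loss(0.5, 0.3, 2.0) - finetune_loss(0.5, 0.3, 1.0) == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# Two-pass forward
# ---------------------------------------------------------------------------

def make_model(vocab, scheme, dropout):
    cfg = EncoderConfig(vocab_size=len(vocab), hidden_dim=16, n_heads=2,
                        n_layers=1, max_len=48, dropout_rate=dropout, seed=2)
    return NERModel(cfg, vocab, scheme)


def test_two_pass_no_dropout_identical(vocab, scheme, sentences):
    model = make_model(vocab, scheme, dropout=0.0)
    pair = two_pass_forward(model, sentences[:4], np.random.default_rng(0))
    assert np.array_equal(pair.p1, pair.p2)
    assert rdrop_loss(pair) == 0.0


def test_two_pass_with_dropout_differs(vocab, scheme, sentences):
    model = make_model(vocab, scheme, dropout=0.1)
    pair = two_pass_forward(model, sentences[:4], np.random.default_rng(0))
    assert not np.array_equal(pair.p1, pair.p2)


def test_two_pass_eval_mode_rejected(vocab, scheme, sentences):
    model = make_model(vocab, scheme, dropout=0.1)
    with pytest.raises(ContractError):
        two_pass_forward(model, sentences[:2], np.random.default_rng(0), training=False)


def test_two_pass_seed_reproducible(vocab, scheme, sentences):
    model = make_model(vocab, scheme, dropout=0.1)
    a = two_pass_forward(model, sentences[:4], np.random.default_rng(7))
    b = two_pass_forward(model, sentences[:4], np.random.default_rng(7))
    assert np.array_equal(a.p1, b.p1) and np.array_equal(a.p2, b.p2)


# ---------------------------------------------------------------------------
# Up-sampling
# ---------------------------------------------------------------------------

def sent_with(etype, scheme):
    return TaggedSentence([Token("x", 0, 1)], [f"B-{etype}"])


def test_upsample_balanced_unchanged(scheme):
    data = [sent_with("diagnosis", scheme) for _ in range(10)] + [
        sent_with("length", scheme) for _ in range(10)
    ]
    assert len(upsample(data, scheme, ratio=2.0)) == len(data)


def test_upsample_rare_class_duplicated(scheme):
    data = [sent_with("diagnosis", scheme) for _ in range(90)] + [
        sent_with("peri_anal_disease", scheme) for _ in range(10)
    ]
    out = upsample(data, scheme, ratio=2.0)
    n_peri = sum(1 for s in out if s.tags[0].endswith("peri_anal_disease"))
    assert n_peri >= 45
    # multiset superset: originals all retained
    assert len(out) >= len(data)
    n_diag = sum(1 for s in out if s.tags[0].endswith("diagnosis"))
    assert n_diag == 90


def test_upsample_empty_rejected(scheme):
    with pytest.raises(ConfigurationError):
        upsample([], scheme)


# ---------------------------------------------------------------------------
# Pseudo-labeling
# ---------------------------------------------------------------------------

def test_pseudo_label_threshold_above_one_keeps_nothing(vocab, scheme, small_corpus):
    model = make_model(vocab, scheme, dropout=0.1)
    notes = [gn.note for gn in small_corpus if not gn.is_labeled]
    out = pseudo_label(model, notes, threshold=1.01)
    assert out.sentences == [] and out.is_silver


def test_pseudo_label_keeps_all_without_threshold(vocab, scheme, small_corpus):
    model = make_model(vocab, scheme, dropout=0.1)
    notes = [gn.note for gn in small_corpus if not gn.is_labeled]
    out = pseudo_label(model, notes, threshold=None, provenance="ckpt-x")
    n_sents = sum(len(s.tokens) > 0 for s in out.sentences)
    assert n_sents == len(out.sentences) > 0
    assert out.provenance == "ckpt-x"
    assert len(out.scores) == len(out.sentences)


def test_pseudo_label_outputs_are_valid(vocab, scheme, small_corpus):
    """Silver spans audit: BIO-valid tags from the scheme, aligned lengths."""
    from entner.formats import repair_bio

    model = make_model(vocab, scheme, dropout=0.1)
    notes = [gn.note for gn in small_corpus if not gn.is_labeled]
    out = pseudo_label(model, notes)
    for s in out.sentences:
        assert len(s.tags) == len(s.tokens)
        assert all(t in scheme.bio_labels for t in s.tags)
        assert repair_bio(s.tags, scheme)[1] == 0  # already valid after repair


def test_pseudo_label_empty_pool(vocab, scheme):
    model = make_model(vocab, scheme, dropout=0.1)
    out = pseudo_label(model, [])
    assert out.sentences == []


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def test_train_stops_after_patience_with_constant_metric(
    vocab, scheme, sentences, monkeypatch
):
    import entner.finetuning as ft

    monkeypatch.setattr(ft, "dev_strict_f1", lambda model, dev: 0.5)
    model = make_model(vocab, scheme, dropout=0.1)
    cfg = FinetuneConfig(epochs=10, patience=1, seed=0)
    _, log = train(model, sentences[:20], sentences[20:24], cfg)
    assert len(log) == 2  # epoch 0 improves over -inf, epoch 1 triggers the stop


def test_train_logs_one_record_per_epoch(vocab, scheme, sentences):
    model = make_model(vocab, scheme, dropout=0.1)
    cfg = FinetuneConfig(epochs=3, patience=10, seed=0)
    _, log = train(model, sentences[:30], sentences[30:36], cfg)
    assert [rec["epoch"] for rec in log] == [0, 1, 2]
    assert all("dev_strict_f1" in rec and "l_finetune" in rec for rec in log)


def test_train_empty_sets_rejected(vocab, scheme, sentences):
    model = make_model(vocab, scheme, dropout=0.1)
    with pytest.raises(ConfigurationError):
        train(model, [], sentences[:2], FinetuneConfig(epochs=1))
    with pytest.raises(ConfigurationError):
        train(model, sentences[:2], [], FinetuneConfig(epochs=1))
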