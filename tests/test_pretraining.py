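"""Pre-training objectives: closed-form values, the frozen-teacher contract,
loss additivity, and checkpoint round trips."""

import hashlib
import math

import numpy as np
import pytest

from entner import (
    ConfigurationError,
    ContrastiveConfig,
    EncoderConfig,
    MaskingConfig,
    Vocab,
    contrastive_loss,
    emlm_loss,
    masked_entity_alignment,
    run_pretraining,
)
from entner.masking import MaskedBatch
from entner.nn import Adam, TransformerEncoder
from entner.pretraining import Checkpoint, PretrainModel, pretrain_step
from entner.masking import MaskingConfig as MC


def uniform_batch(n, masked_positions):
    ind = np.zeros(n, dtype=np.int64)
    ind[list(masked_positions)] = 1
    ids = np.arange(n, dtype=np.int64)
    return MaskedBatch(ids, ids, ind)


# ---------------------------------------------------------------------------
# EMLM loss closed forms
# ---------------------------------------------------------------------------

def test_emlm_loss_no_masked_positions_is_zero():
    assert emlm_loss(np.zeros((4, 11)), uniform_batch(4, [])) == 0.0


@pytest.mark.parametrize("k,V", [(1, 7), (3, 19), (5, 100)])
def test_emlm_loss_uniform_logits_equal_k_ln_v(k, V):
    batch = uniform_batch(6, range(k))
    val = emlm_loss(np.zeros((6, V)), batch)
    assert abs(val - k * math.log(V)) < 1e-9


def test_emlm_loss_hand_computed_probabilities():
    # two masked positions with target probabilities 0.5 and 0.25
    probs = np.array([[0.5, 0.5, 1e-12], [0.25, 0.5, 0.25], [1 / 3, 1 / 3, 1 / 3]])
    logits = np.log(probs)
    batch = MaskedBatch(np.zeros(3, np.int64), np.zeros(3, np.int64), np.array([1, 1, 0]))
    expected = -(math.log(0.5) + math.log(0.25))  # ≈ 2.0794
    assert abs(emlm_loss(logits, batch) - expected) < 1e-6


def test_emlm_loss_alignment_contract():
    from entner.errors import ContractError

    with pytest.raises(ContractError):
        emlm_loss(np.zeros((3, 5)), uniform_batch(4, [0]))


# ---------------------------------------------------------------------------
# Contrastive loss closed forms
# ---------------------------------------------------------------------------

def test_contrastive_single_position_is_zero():
    s = np.array([[1.0, 2.0]])
    t = np.array([[0.5, -1.0]])
    assert abs(contrastive_loss(s, t, np.array([1]), tau=0.7)) < 1e-12


def test_contrastive_identical_teacher_rows_is_k_ln_n():
    rng = np.random.default_rng(0)
    n, k = 6, 4
    teacher = np.tile(rng.normal(size=2), (n, 1))
    student = rng.normal(size=(n, 2))
    ind = np.zeros(n, dtype=int)
    ind[:k] = 1
    val = contrastive_loss(student, teacher, ind, tau=0.01)
    assert abs(val - k * math.log(n)) < 1e-9


def test_contrastive_matches_brute_force_oracle():
    """Hand-chosen 2-d vectors; the oracle evaluates cosine/softmax directly."""
    student = np.array([[1.0, 0.0], [0.3, 0.4], [0.5, 0.5]])
    teacher = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    tau = 1.0

    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    sims = np.array([cos(student[0], teacher[j]) for j in range(3)]) / tau
    oracle = -(sims[0] - math.log(np.exp(sims).sum()))
    val = contrastive_loss(student, teacher, np.array([1, 0, 0]), tau=tau)
    assert abs(val - oracle) < 1e-9


def test_contrastive_cosine_agrees_with_dot_norm_oracle():
    rng = np.random.default_rng(3)
    s = rng.normal(size=(5, 8))
    t = rng.normal(size=(5, 8))
    ind = np.array([1, 0, 1, 0, 1])
    tau = 0.37
    sims = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            sims[i, j] = s[i] @ t[j] / (np.linalg.norm(s[i]) * np.linalg.norm(t[j]))
    oracle = 0.0
    for i in np.nonzero(ind)[0]:
        z = sims[i] / tau
        oracle += -(z[i] - math.log(np.exp(z).sum()))
    assert abs(contrastive_loss(s, t, ind, tau) - oracle) < 1e-6


def test_contrastive_zero_norm_rejected():
    s = np.array([[0.0, 0.0], [1.0, 0.0]])
    t = np.array([[1.0, 0.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match="zero-norm"):
        contrastive_loss(s, t, np.array([1, 0]), tau=1.0)


def test_contrastive_zero_indicator_zero_loss():
    rng = np.random.default_rng(4)
    s, t = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
    assert contrastive_loss(s, t, np.zeros(4, int), tau=0.5) == 0.0


# ---------------------------------------------------------------------------
# Pre-training step and loop contracts
# ---------------------------------------------------------------------------

def _hash_params(module) -> str:
    h = hashlib.sha256()
    for k in sorted(module.parameters()):
        h.update(module.parameters()[k].data.tobytes())
    return h.hexdigest()


def test_teacher_frozen_across_steps(sentences, vocab):
    cfg = EncoderConfig(vocab_size=len(vocab), hidden_dim=16, n_heads=2,
                        n_layers=1, max_len=48, seed=0)
    student = PretrainModel(cfg)
    teacher = TransformerEncoder(cfg)
    teacher.load_state_dict(student.encoder.state_dict())
    before = _hash_params(teacher)
    student_before = _hash_params(student)
    opt = Adam(student.parameters(), lr=1e-3)
    rng = np.random.default_rng(0)
    from entner.masking import emlm_mask, insert_entity_labels

    tagged = [s for s in sentences if any(t != "O" for t in s.tags)][:8]
    for _ in range(10):
        items = [
            emlm_mask(insert_entity_labels(s), vocab, MC(eta=0.7, strategy="emlm"), rng)
            for s in tagged
        ]
        bundle = pretrain_step(student, teacher, items, vocab, tau=0.01,
                               optimizer=opt, rng=rng, use_cl=True)
        assert bundle.l_emlm >= 0 and bundle.l_cl >= 0
        assert abs(bundle.l_pretrain - (bundle.l_cl + bundle.l_emlm)) < 1e-12
    assert _hash_params(teacher) == before
    assert _hash_params(student) != student_before  # student did move


def test_mlm_variant_ignores_entity_annotations(sentences, vocab):
    """Same seed, annotations scrubbed vs present: identical checkpoints."""
    import copy

    cfg = EncoderConfig(vocab_size=len(vocab), hidden_dim=16, n_heads=2,
                        n_layers=1, max_len=48, seed=0)
    cc = ContrastiveConfig(steps=5, batch_size=8)
    subset = sentences[:40]
    scrubbed = []
    for s in subset:
        c = copy.deepcopy(s)
        c.tags = ["O"] * len(c.tags)
        scrubbed.append(c)
    ck1 = run_pretraining(subset, "mlm", encoder_config=cfg, contrastive=cc,
                          vocab=vocab, seed=3)
    ck2 = run_pretraining(scrubbed, "mlm", encoder_config=cfg, contrastive=cc,
                          vocab=vocab, seed=3)
    for k in ck1.weights:
        assert np.array_equal(ck1.weights[k], ck2.weights[k])


def test_emlm_variant_requires_entities(sentences, vocab):
    import copy

    scrubbed = []
    for s in sentences[:10]:
        c = copy.deepcopy(s)
        c.tags = ["O"] * len(c.tags)
        scrubbed.append(c)
    with pytest.raises(ConfigurationError, match="entity"):
        run_pretraining(scrubbed, "emlm", vocab=vocab)


def test_checkpoint_round_trip_reproduces_forward(sentences, vocab, tmp_path):
    cfg = EncoderConfig(vocab_size=len(vocab), hidden_dim=16, n_heads=2,
                        n_layers=1, max_len=48, seed=0)
    ck = run_pretraining(sentences[:30], "emlm", encoder_config=cfg,
                         contrastive=ContrastiveConfig(steps=3, batch_size=8),
                         vocab=vocab, seed=1)
    path = ck.save(tmp_path / "ck")
    back = Checkpoint.load(path)
    assert back.variant == "emlm"
    ids = vocab.encode(sentences[0].surfaces())[None, :]
    pad = np.ones_like(ids, dtype=bool)
    h1 = ck.build_encoder()(ids, pad).data
    h2 = back.build_encoder()(ids, pad).data
    assert np.array_equal(h1, h2)


def test_pretraining_loss_decreases(sentences, vocab):
    """Median over 3 seeds: per-masked-token loss at the end below the start
    (raw sums fluctuate with how many tokens a batch happens to mask)."""
    cfg = EncoderConfig(vocab_size=len(vocab), hidden_dim=32, n_heads=4,
                        n_layers=2, max_len=48, seed=0)
    deltas = []
    for seed in (0, 1, 2):
        ck = run_pretraining(
            sentences, "emlm_cl", encoder_config=cfg,
            contrastive=ContrastiveConfig(steps=120, batch_size=16),
            vocab=vocab, seed=seed,
        )
        deltas.append(ck.log[-1]["l_per_masked"] - ck.log[0]["l_per_masked"])
    assert np.median(deltas) < 0


def test_emlm_cl_improves_masked_entity_alignment(sentences, vocab):
    cfg = EncoderConfig(vocab_size=len(vocab), hidden_dim=32, n_heads=4,
                        n_layers=2, max_len=48, seed=0)
    tagged = [s for s in sentences if any(t != "O" for t in s.tags)][:60]
    teacher = TransformerEncoder(cfg)
    student0 = PretrainModel(cfg)
    from entner.pretraining import init_label_token_embeddings

    init_label_token_embeddings(student0.encoder, vocab)
    teacher.load_state_dict(student0.encoder.state_dict())
    mc = MaskingConfig(eta=0.7, strategy="emlm")
    before = masked_entity_alignment(student0.encoder, teacher, tagged, vocab, mc, seed=5)
    ck = run_pretraining(tagged, "emlm_cl", encoder_config=cfg,
                         contrastive=ContrastiveConfig(steps=60, batch_size=16),
                         vocab=vocab, seed=0)
    after = masked_entity_alignment(ck.build_encoder(), teacher, tagged, vocab, mc, seed=5)
    assert after > before
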