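"""NER model: Viterbi vs exhaustive search, section-fusion contracts,
transition constraints, and the multi-task head."""

import itertools

import numpy as np
import pytest

from entner import (
    EncoderConfig,
    LabelScheme,
    NERModel,
    TaggedSentence,
    Token,
    TransitionMatrix,
    Vocab,
    build_transitions,
    viterbi_decode,
)
from entner.errors import ConfigurationError, ContractError
from entner.nn import softmax, Tensor


def brute_force_best_path(emissions, transitions):
    T, C = emissions.shape
    tr = transitions.scores
    best, best_score = None, -np.inf
    for path in itertools.product(range(C), repeat=T):
        score = tr[transitions.start, path[0]] + emissions[0, path[0]]
        for t in range(1, T):
            score += tr[path[t - 1], path[t]] + emissions[t, path[t]]
        score += tr[path[-1], transitions.stop]
        if score > best_score + 1e-12:
            best, best_score = list(path), score
    return best, best_score


def random_transitions(rng, C):
    return TransitionMatrix(scores=rng.normal(size=(C + 2, C + 2)), n_labels=C)


def test_viterbi_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(200):
        T = int(rng.integers(1, 7))
        C = int(rng.integers(2, 6))
        emissions = rng.normal(size=(T, C))
        tr = random_transitions(rng, C)
        path = viterbi_decode(emissions, tr)
        _, oracle_score = brute_force_best_path(emissions, tr)
        # compare scores: ties may admit multiple optimal paths
        score = tr.scores[tr.start, path[0]] + emissions[0, path[0]]
        for t in range(1, T):
            score += tr.scores[path[t - 1], path[t]] + emissions[t, path[t]]
        score += tr.scores[path[-1], tr.stop]
        assert abs(score - oracle_score) < 1e-9


def test_viterbi_zero_transitions_is_argmax():
    rng = np.random.default_rng(1)
    emissions = rng.normal(size=(5, 4))
    tr = TransitionMatrix(scores=np.zeros((6, 6)), n_labels=4)
    assert viterbi_decode(emissions, tr) == list(emissions.argmax(axis=1))


def test_viterbi_respects_hard_constraints(scheme):
    """Structural transitions never decode I-x after anything but B-x/I-x."""
    rng = np.random.default_rng(2)
    tr = build_transitions(scheme)
    labels = scheme.bio_labels
    for _ in range(50):
        emissions = rng.normal(size=(6, len(labels))) * 5
        path = [labels[i] for i in viterbi_decode(emissions, tr)]
        prev = "O"
        for tag in path:
            if tag.startswith("I-"):
                assert prev in (f"B-{tag[2:]}", f"I-{tag[2:]}")
            prev = tag


def test_viterbi_tie_break_lowest_index():
    emissions = np.zeros((3, 3))
    tr = TransitionMatrix(scores=np.zeros((5, 5)), n_labels=3)
    assert viterbi_decode(emissions, tr) == [0, 0, 0]


# ---------------------------------------------------------------------------
# Section fusion
# ---------------------------------------------------------------------------

def make_model(vocab, scheme, fusion="none", **kw):
    cfg = EncoderConfig(vocab_size=len(vocab), hidden_dim=16, n_heads=2,
                        n_layers=1, max_len=32, seed=4)
    return NERModel(cfg, vocab, scheme, fusion_mode=fusion,
                    section_titles=["Anamnese", "Familiaal"], **kw)


def example_sentence():
    return TaggedSentence(
        [Token("ziekte", 0, 6), Token("van", 7, 10), Token("Crohn", 11, 16)],
        ["B-diagnosis", "I-diagnosis", "I-diagnosis"],
        section="Familiaal",
    )


def test_embed_fusion_is_identity_at_initialization(vocab, scheme):
    """Zero section embeddings + [I;0] projection: embed == none at init."""
    plain = make_model(vocab, scheme, "none")
    fused = make_model(vocab, scheme, "embed")
    fused.encoder.load_state_dict(plain.encoder.state_dict())
    batch = fused.assemble([example_sentence()])
    h_plain = plain.encode(batch["ids"], batch["pad_mask"], batch["sec_ids"])
    h_fused = fused.encode(batch["ids"], batch["pad_mask"], batch["sec_ids"])
    assert np.allclose(h_plain.data, h_fused.data, atol=1e-12)


def test_embed_fusion_sections_differ_after_perturbation(vocab, scheme, rng):
    model = make_model(vocab, scheme, "embed")
    # random weights: perturb both the attribute embeddings and the rows of the
    # projection that consume them (zeroed at init by design)
    model.sec_emb.data = rng.normal(size=model.sec_emb.data.shape)
    D = model.encoder.config.hidden_dim
    model.fuse_proj.data[D:] = rng.normal(size=model.fuse_proj.data[D:].shape)
    s = example_sentence()
    batch = model.assemble([s])
    h1 = model.encode(batch["ids"], batch["pad_mask"], np.array([0]))
    h2 = model.encode(batch["ids"], batch["pad_mask"], np.array([1]))
    assert not np.allclose(h1.data, h2.data)


def test_text_fusion_prepends_title_tokens(vocab, scheme):
    model = make_model(vocab, scheme, "text")
    batch = model.assemble([example_sentence()])
    ids = batch["ids"][0]
    assert ids[0] == vocab.cls_id
    assert ids[1] == vocab.encode(["Familiaal"])[0]
    assert ids[2] == vocab.sec_id
    # token positions skip the prefix
    assert batch["token_pos"][0][0] == 3


def test_bias_fusion_is_uniform_additive_shift(vocab, scheme, rng):
    model = make_model(vocab, scheme, "bias")
    model.sec_bias.data = rng.normal(size=model.sec_bias.data.shape)
    batch = model.assemble([example_sentence()])
    h = model.encode(batch["ids"], batch["pad_mask"], batch["sec_ids"])
    base = model.classifier(h).data
    biased = model.token_logits(h, batch["sec_ids"]).data
    diff = biased[0] - base[0]
    assert np.allclose(diff, diff[0])  # same offset vector at every position
    sec = int(batch["sec_ids"][0])
    assert np.allclose(diff[0], model.sec_bias.data[sec])


def test_bias_fusion_zero_bias_equals_none(vocab, scheme):
    model = make_model(vocab, scheme, "bias")
    batch = model.assemble([example_sentence()])
    h = model.encode(batch["ids"], batch["pad_mask"], batch["sec_ids"])
    assert np.allclose(model.token_logits(h, batch["sec_ids"]).data,
                       model.classifier(h).data)


def test_unknown_section_falls_back_to_unk(vocab, scheme):
    model = make_model(vocab, scheme, "embed")
    assert model.section_id("Radiologie") == len(model.section_titles)
    assert model.section_id(None) == len(model.section_titles)


def test_probability_rows_normalize(vocab, scheme):
    model = make_model(vocab, scheme, "none")
    batch = model.assemble([example_sentence()])
    _, logits = model.forward(batch)
    rows = softmax(logits, axis=-1).data.sum(axis=-1)
    assert np.allclose(rows, 1.0, atol=1e-6)


def test_unknown_fusion_mode_rejected(vocab, scheme):
    with pytest.raises(ConfigurationError):
        make_model(vocab, scheme, "concat")


# ---------------------------------------------------------------------------
# Multi-task head
# ---------------------------------------------------------------------------

def test_multitask_output_contracts(vocab, scheme):
    model = make_model(vocab, scheme, "none", multitask=True)
    out = model.multitask_forward(example_sentence())
    assert 0.0 <= out.sentence_prob <= 1.0
    assert out.token_dists.shape == (3, len(scheme.bio_labels))
    assert np.allclose(out.token_dists.sum(axis=-1), 1.0, atol=1e-6)


def test_multitask_disabled_raises(vocab, scheme):
    model = make_model(vocab, scheme, "none", multitask=False)
    with pytest.raises(ContractError):
        model.multitask_forward(example_sentence())


def test_sentence_head_does_not_leak_into_token_dists(vocab, scheme, rng):
    """Token distributions are identical whether the sentence head is attached
    or not: at inference the head reads h1 but never feeds back."""
    with_head = make_model(vocab, scheme, "none", multitask=True)
    without = make_model(vocab, scheme, "none", multitask=False)
    without.encoder.load_state_dict(with_head.encoder.state_dict())
    without.classifier.w.data = with_head.classifier.w.data.copy()
    without.classifier.b.data = with_head.classifier.b.data.copy()
    s = example_sentence()
    out = with_head.multitask_forward(s)
    batch = without.assemble([s])
    _, logits = without.forward(batch)
    dists = softmax(Tensor(logits.data[0][batch["token_pos"][0]]), axis=-1).data
    assert np.allclose(out.token_dists, dists, atol=1e-12)


def test_sentence_flag_targets(sentences):
    for s in sentences:
        has_peri = any(t.endswith("peri_anal_disease") for t in s.tags)
        assert s.sentence_flag == int(has_peri)


# ---------------------------------------------------------------------------
# CRF sequence NLL
# ---------------------------------------------------------------------------

def test_crf_nll_matches_enumeration(vocab, scheme):
    """Sequence NLL equals -log of the gold path's share of the partition
    function computed by exhaustive enumeration over all label paths."""
    model = make_model(vocab, scheme, "none", crf_nll=True)
    rng = np.random.default_rng(8)
    C = len(scheme.bio_labels)
    model.trans.data = rng.normal(size=model.trans.data.shape)
    T = 3
    emissions = rng.normal(size=(T, C))
    tags = [1, 2, 0]
    nll = model.crf_nll_loss(Tensor(emissions), tags).item()

    tr = model.trans.data
    start, stop = C, C + 1

    def path_score(path):
        sc = tr[start, path[0]] + emissions[0, path[0]]
        for t in range(1, T):
            sc += tr[path[t - 1], path[t]] + emissions[t, path[t]]
        return sc + tr[path[-1], stop]

    scores = [path_score(p) for p in itertools.product(range(C), repeat=T)]
    logz = np.log(np.exp(scores - np.max(scores)).sum()) + np.max(scores)
    oracle = logz - path_score(tags)
    assert abs(nll - oracle) < 1e-8


def test_model_save_load_round_trip(vocab, scheme, tmp_path):
    model = make_model(vocab, scheme, "embed", multitask=True)
    s = example_sentence()
    tags1, _ = model.predict([s])
    path = model.save(tmp_path / "m")
    back = NERModel.load(path)
    tags2, _ = back.predict([s])
    assert tags1 == tags2
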