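"""Attention extraction, importance scores, motifs, DNA->taxonomy analysis."""

import math

import numpy as np
import pandas as pd
import pytest

import methyllm as ml
from methyllm._transformer import TransformerEncoder
from methyllm.finetuning import FineTunedModel
from methyllm.pretraining import LanguageModelHandle


@pytest.fixture(scope="module")
def sample6():
    # from the small_corpus generator settings (seed 17): every 6-mer is
    # in-vocabulary for the small tokenizer used by the oracle models
    ds, _ = ml.generate_dataset(30, 30, "6mA", seed=17)
    return ds.samples[0]


@pytest.fixture(scope="module")
def hand_model(small_tokenizer):
    """A 1-layer, 1-head model with fixed random weights for oracle checks."""
    cfg = ml.ModelConfig(family="bert", n_layers=1, n_heads=1, hidden_size=8,
                         ffn_size=16, vocab_size=len(small_tokenizer),
                         max_positions=100)
    handle = LanguageModelHandle(
        config=cfg, tokenizer=small_tokenizer,
        encoder=TransformerEncoder(cfg, seed=5), stage="pretrained",
    )
    return FineTunedModel(handle=handle, methyl_type="6mA", provenance="init")


@pytest.fixture(scope="module")
def uniform_model(small_tokenizer):
    """Zeroed Q/K projections: every attention row is uniform over content."""
    cfg = ml.ModelConfig(family="bert", n_layers=1, n_heads=4, hidden_size=8,
                         ffn_size=16, vocab_size=len(small_tokenizer),
                         max_positions=100)
    enc = TransformerEncoder(cfg, seed=6)
    enc.params["l0_Wq"][:] = 0.0
    enc.params["l0_bq"][:] = 0.0
    enc.params["l0_Wk"][:] = 0.0
    enc.params["l0_bk"][:] = 0.0
    handle = LanguageModelHandle(config=cfg, tokenizer=small_tokenizer,
                                 encoder=enc, stage="pretrained")
    return FineTunedModel(handle=handle, methyl_type="6mA", provenance="init")


# ---------------------------------------------------------------------------
# dense straight-line oracle (independent recomputation)

def _dense_layer_norm(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    return g * (x - mu) / np.sqrt(var + eps) + b


def _dense_attention_and_embedding(model, sample):
    """Recompute attention and the [CLS] embedding with plain dense algebra."""
    handle = model.handle
    p = handle.encoder.params
    cfg = handle.config
    enc = ml.encode(handle.tokenizer, ml.build_sentence(sample))
    ids = np.array(enc.token_ids)
    mask = np.array(enc.attention_mask, dtype=float)
    T = len(ids)
    dk = cfg.hidden_size // cfg.n_heads

    x = p["emb_tok"][ids] + p["emb_pos"][:T]
    x = _dense_layer_norm(x, p["emb_ln_g"], p["emb_ln_b"])
    attn_all = []
    for l in range(cfg.n_layers):
        y = _dense_layer_norm(x, p[f"l{l}_ln1_g"], p[f"l{l}_ln1_b"])
        Q = y @ p[f"l{l}_Wq"] + p[f"l{l}_bq"]
        K = y @ p[f"l{l}_Wk"] + p[f"l{l}_bk"]
        V = y @ p[f"l{l}_Wv"] + p[f"l{l}_bv"]
        heads = []
        ctx_cols = []
        for h in range(cfg.n_heads):
            sl = slice(h * dk, (h + 1) * dk)
            S = Q[:, sl] @ K[:, sl].T / math.sqrt(dk)
            S = S + (1.0 - mask)[None, :] * -1e9
            A = np.exp(S - S.max(-1, keepdims=True))
            A = A / A.sum(-1, keepdims=True)
            heads.append(A)
            ctx_cols.append(A @ V[:, sl])
        attn_all.append(np.stack(heads))
        ctx = np.concatenate(ctx_cols, axis=1)
        o = ctx @ p[f"l{l}_Wo"] + p[f"l{l}_bo"]
        x1 = x + o
        z = _dense_layer_norm(x1, p[f"l{l}_ln2_g"], p[f"l{l}_ln2_b"])
        a = z @ p[f"l{l}_W1"] + p[f"l{l}_b1"]
        g = 0.5 * a * (1 + np.tanh(math.sqrt(2 / math.pi) * (a + 0.044715 * a**3)))
        x = x1 + g @ p[f"l{l}_W2"] + p[f"l{l}_b2"]
    h_final = _dense_layer_norm(x, p["ln_f_g"], p["ln_f_b"])
    return np.stack(attn_all), h_final[0]


# ---------------------------------------------------------------------------
# attention contracts

def test_attention_rows_sum_to_one(bert6, heldout6):
    ds, _ = heldout6
    attn = ml.attention_matrices(bert6, ds.samples[0])
    sums = attn.values.sum(axis=-1)
    assert np.allclose(sums, 1.0, atol=1e-5)
    assert (attn.values >= 0).all()


def test_attention_matches_dense_oracle(hand_model, sample6):
    attn = ml.attention_matrices(hand_model, sample6)
    oracle_attn, _ = _dense_attention_and_embedding(hand_model, sample6)
    assert np.allclose(attn.values, oracle_attn, atol=1e-10)


def test_cls_attention_ignores_padding(bert6, heldout6):
    ds, _ = heldout6
    attn = ml.attention_matrices(bert6, ds.samples[0])
    content = np.array(attn.encoded.attention_mask, dtype=bool)
    assert np.allclose(attn.values[..., ~content], 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# token importance

def test_token_importance_totals_number_of_heads(bert6, heldout6):
    ds, _ = heldout6
    scores, _ = ml.token_importance(bert6, ds.samples[0])
    assert (scores >= 0).all()
    assert scores.sum() == pytest.approx(bert6.handle.config.n_heads, abs=1e-6)


def test_uniform_attention_ties_all_content_tokens(uniform_model, sample6):
    scores, enc = ml.token_importance(uniform_model, sample6)
    content = np.array(enc.attention_mask, dtype=bool)
    assert np.allclose(scores[content], scores[content][0], atol=1e-12)
    assert np.allclose(scores[~content], 0.0, atol=1e-12)


def test_token_importance_equals_tensor_slice_sum(bert6, heldout6):
    ds, _ = heldout6
    attn = ml.attention_matrices(bert6, ds.samples[1])
    scores, _ = ml.token_importance(bert6, ds.samples[1], attn=attn)
    # brute-force slice-and-sum over the raw tensor, head by head
    brute = np.zeros(attn.values.shape[-1])
    for h in range(attn.values.shape[1]):
        brute += attn.values[-1, h, 0, :]
    assert np.allclose(scores, brute, atol=1e-12)


def test_cls_key_direction_sums_columns(bert6, heldout6):
    ds, _ = heldout6
    attn = ml.attention_matrices(bert6, ds.samples[2])
    scores, _ = ml.token_importance(bert6, ds.samples[2], direction="cls-key",
                                    attn=attn)
    brute = attn.values[-1, :, :, 0].sum(axis=0)
    assert np.allclose(scores, brute, atol=1e-12)


def test_mulan_importance_single_model_identity(bert6, sample6):
    avg, enc = ml.mulan_token_importance([bert6], sample6)
    scores, enc2 = ml.token_importance(bert6, sample6)
    assert np.allclose(avg, ml.word_scores(scores, enc2), atol=1e-12)


def test_mulan_importance_identical_models_mean(bert6, sample6):
    one, _ = ml.mulan_token_importance([bert6], sample6)
    three, _ = ml.mulan_token_importance([bert6, bert6, bert6], sample6)
    assert np.allclose(one, three, atol=1e-12)


def test_mulan_importance_rejects_non_wordwise_family(small_corpus, sample6):
    tok = ml.train_tokenizer(small_corpus, "albert", 4000)
    cfg = ml.ModelConfig.tiny("albert", vocab_size=len(tok))
    handle = LanguageModelHandle(config=cfg, tokenizer=tok,
                                 encoder=TransformerEncoder(cfg, seed=1),
                                 stage="pretrained")
    model = FineTunedModel(handle=handle, methyl_type="6mA", provenance="x")
    with pytest.raises(ValueError, match="word-wise"):
        ml.mulan_token_importance([model], sample6)


# ---------------------------------------------------------------------------
# position merging

def test_constant_word_scores_give_constant_profile():
    profile = ml.position_importance(np.full(36, 3.5))
    assert np.allclose(profile, 3.5)


def test_single_nonzero_word_covers_positions_one_to_six():
    scores = np.zeros(36)
    scores[0] = 2.0
    profile = ml.position_importance(scores)
    assert (profile[:6] > 0).all()
    assert np.allclose(profile[6:], 0.0)


def test_position_merging_matches_coverage_enumeration():
    rng = np.random.default_rng(9)
    scores = rng.random(36)
    for merge in ("mean", "sum"):
        profile = ml.position_importance(scores, merge=merge)
        for p in range(1, 42):
            cover = [w for w in range(1, 37) if w <= p <= w + 5]
            vals = [scores[w - 1] for w in cover]
            expected = np.mean(vals) if merge == "mean" else np.sum(vals)
            assert profile[p - 1] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# DNA -> taxonomy attention

def test_dna_to_taxonomy_shape_and_slicing(bert6, heldout6):
    ds, _ = heldout6
    sample = ds.samples[3]
    mat = ml.dna_to_taxonomy_attention(bert6, sample)
    assert mat.shape == (36, 8)
    assert list(mat.columns) == list(ml.RANKS)
    # brute-force double slice oracle for one cell
    attn = ml.attention_matrices(bert6, sample)
    enc = attn.encoded
    last = attn.values[-1]
    wi = enc.dna_word_indices[0]
    toks = [t for t, w in enumerate(enc.word_ids) if w == wi]
    lo, hi = enc.taxonomy_token_spans["species"]
    expected = sum(
        last[h, a, b] for h in range(last.shape[0])
        for a in toks for b in range(lo, hi)
    )
    assert mat.iloc[0]["species"] == pytest.approx(expected, abs=1e-12)


def test_uniform_attention_scales_with_span_length(uniform_model, sample6):
    mat = ml.dna_to_taxonomy_attention(uniform_model, sample6)
    attn = ml.attention_matrices(uniform_model, sample6)
    enc = attn.encoded
    n_content = sum(enc.attention_mask)
    n_heads = uniform_model.handle.config.n_heads
    for rank in ml.RANKS:
        lo, hi = enc.taxonomy_token_spans[rank]
        expected = n_heads * (hi - lo) / n_content  # per DNA word (1 token each)
        assert np.allclose(mat[rank].to_numpy(), expected, atol=1e-9)


# ---------------------------------------------------------------------------
# motif table

def test_dominant_word_ranks_first():
    ds, _ = ml.generate_dataset(3, 0, "6mA", seed=40)
    scores = []
    for s in ds:
        sc = np.ones(36) * 0.1
        # the word starting at the center (position 21) dominates
        sc[20] = 5.0
        scores.append(sc)
    table = ml.top_motifs(ds.samples, scores, n=10)
    top_kmers = {s.sequence[20:26] for s in ds}
    assert table.iloc[0]["motif"] in top_kmers


def test_motif_table_matches_groupby_oracle():
    ds, _ = ml.generate_dataset(10, 0, "6mA", seed=41)
    rng = np.random.default_rng(42)
    scores = [rng.random(36) for _ in ds]
    table = ml.top_motifs(ds.samples, scores, n=10)
    rows = []
    for s, sc in zip(ds, scores):
        for k in range(36):
            rows.append({"motif": s.sequence[k : k + 6], "score": sc[k]})
    oracle = (
        pd.DataFrame(rows).groupby("motif")["score"]
        .agg(["mean", "count"]).sort_values(
            ["mean", "count"], ascending=[False, False])
    )
    assert np.allclose(table["mean_score"], oracle["mean"].to_numpy()[:10])
    assert table.iloc[0]["motif"] == oracle.index[0]
    assert table["count"].sum() <= 360


def test_motif_table_is_sorted_descending(wordwise6, heldout6):
    ds, _ = heldout6
    positives = [s for s in ds if s.label == 1][:15]
    scores = [ml.importance_profile(wordwise6, s)[0] for s in positives]
    table = ml.top_motifs(positives, scores, n=10)
    assert (np.diff(table["mean_score"]) <= 1e-12).all()


def test_planted_motif_recovered_by_shared_models(wordwise6, heldout6):
    """The planted consensus should surface in the top-10 motif table."""
    ds, truth = heldout6
    positives = [s for s in ds if s.label == 1][:30]
    scores = [ml.importance_profile(wordwise6, s)[0] for s in positives]
    table = ml.top_motifs(positives, scores, n=10)
    assert truth.motif.consensus in set(table["motif"])


# ---------------------------------------------------------------------------
# [CLS] embedding

def test_cls_embedding_length_and_determinism(bert6, sample6):
    v1 = ml.cls_embedding(bert6, sample6)
    v2 = ml.cls_embedding(bert6, sample6)
    assert v1.shape == (bert6.handle.config.hidden_size,)
    assert np.array_equal(v1, v2)


def test_cls_embedding_matches_dense_forward_oracle(hand_model, sample6):
    got = ml.cls_embedding(hand_model, sample6)
    _, expected = _dense_attention_and_embedding(hand_model, sample6)
    assert np.allclose(got, expected, atol=1e-10)
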