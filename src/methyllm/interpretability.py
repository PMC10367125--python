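"""Attention-based interpretability: token importance, motifs, DNA->taxonomy.

For a fine-tuned model, the classifier consumes the [CLS] representation,
so the last encoder layer's attention distribution anchored at [CLS],
summed over heads, is read as each token's contribution to the prediction.
Because the WordPiece-style tokenizers (BERT, DistilBERT, ELECTRA) produce
word-aligned tokens, their scores can be aggregated to 6-mer words,
averaged across the three submodels, and merged position-wise into a
length-41 per-nucleotide importance profile.  Ranking 6-mers by mean
importance over positive samples surfaces candidate methylation motifs,
and slicing the attention tensor from DNA-word tokens to taxonomic-rank
tokens quantifies how strongly the sequence attends to each lineage rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data_model import (
    KMER_SIZE,
    N_KMERS,
    RANKS,
    WINDOW_LENGTH,
    MethylSample,
    build_sentence,
)
from .finetuning import FineTunedModel, _as_handle
from .pretraining import LanguageModelHandle
from .tokenization import EncodedSample, WORDPIECE_FAMILIES, encode

ModelLike = Union[LanguageModelHandle, FineTunedModel]


@dataclass
class AttentionMatrix:
    """Per-layer, per-head attention over one encoded sample.

    ``values[l, h, i, j]`` is the weight that query token i places on key
    token j in layer l, head h; each (l, h, i) row sums to 1.
    """

    values: np.ndarray  # (n_layers, n_heads, T, T)
    encoded: EncodedSample
    d_k: int


def _encode_for(model: ModelLike, sample: MethylSample) -> EncodedSample:
    handle = _as_handle(model)
    return encode(handle.tokenizer, build_sentence(sample), handle.config.max_positions)


def attention_matrices(model: ModelLike, sample: MethylSample) -> AttentionMatrix:
    """Full attention tensor of the encoder over one sample."""
    handle = _as_handle(model)
    enc = _encode_for(model, sample)
    ids = np.array(enc.token_ids, dtype=np.int64)[None, :]
    mask = np.array(enc.attention_mask, dtype=np.float64)[None, :]
    _, attns, _ = handle.encoder.forward(ids, mask, store_attn=True)
    values = np.stack([a[0] for a in attns])  # (L, H, T, T)
    return AttentionMatrix(values=values, encoded=enc, d_k=handle.config.d_k)


def token_importance(
    model: ModelLike,
    sample: MethylSample,
    direction: str = "cls-query",
    attn: Optional[AttentionMatrix] = None,
) -> Tuple[np.ndarray, EncodedSample]:
    """Per-token contribution scores from the last layer's [CLS] attention.

    ``direction="cls-query"`` (default) reads the attention distribution
    that [CLS] as Query places over all Key tokens — the distribution the
    classifier head consumes — summed over heads.  ``"cls-key"`` instead
    sums each token's (as Query) attention toward [CLS] as Key.
    """
    if direction not in ("cls-query", "cls-key"):
        raise ValueError(f"unknown direction {direction!r}")
    if attn is None:
        attn = attention_matrices(model, sample)
    last = attn.values[-1]  # (H, T, T)
    if direction == "cls-query":
        scores = last[:, 0, :].sum(axis=0)
    else:
        scores = last[:, :, 0].sum(axis=0)
    return scores, attn.encoded


def word_scores(token_scores: np.ndarray, encoded: EncodedSample) -> np.ndarray:
    """Aggregate token scores to word level (sum over each word's pieces)."""
    n_words = len(encoded.words)
    out = np.zeros(n_words)
    for score, wi in zip(token_scores, encoded.word_ids):
        if wi >= 0:
            out[wi] += score
    return out


def dna_word_scores(token_scores: np.ndarray, encoded: EncodedSample) -> np.ndarray:
    """Scores of the 36 DNA 6-mer words of a 41-nt sample."""
    ws = word_scores(token_scores, encoded)
    scores = ws[encoded.dna_word_indices]
    if len(scores) != N_KMERS:
        raise ValueError(
            f"expected {N_KMERS} DNA words, found {len(scores)}"
        )
    return scores


def mulan_token_importance(
    models: Sequence[ModelLike],
    sample: MethylSample,
    direction: str = "cls-query",
) -> Tuple[np.ndarray, EncodedSample]:
    """Word-aligned average of per-model token importance scores.

    Intended for the word-wise-tokenizer submodels (BERT, DistilBERT,
    ELECTRA) fine-tuned for the sample's methylation type; raises if the
    models' word-level tokenizations disagree.
    """
    if not models:
        raise ValueError("need at least one model")
    per_model: List[np.ndarray] = []
    ref_encoded: Optional[EncodedSample] = None
    for m in models:
        fam = _as_handle(m).config.family
        if fam not in WORDPIECE_FAMILIES:
            raise ValueError(
                f"family {fam!r} does not produce word-wise tokens; "
                f"word-aligned importance uses {WORDPIECE_FAMILIES}"
            )
        scores, enc2 = token_importance(m, sample, direction)
        if ref_encoded is None:
            ref_encoded = enc2
        elif enc2.words != ref_encoded.words:
            raise ValueError("models tokenize the sample into different words; cannot align")
        per_model.append(word_scores(scores, enc2))
    return np.mean(per_model, axis=0), ref_encoded


def position_importance(
    dna_word_scores_: np.ndarray, merge: str = "mean"
) -> np.ndarray:
    """Merge 36 6-mer word scores into a length-41 per-position profile.

    Position p (1..41) is covered by the 6-mers starting at
    max(1, p-5)..min(36, p); the profile value is the mean (default) or
    sum of the covering word scores.
    """
    if merge not in ("mean", "sum"):
        raise ValueError(f"unknown merge rule {merge!r}")
    scores = np.asarray(dna_word_scores_, dtype=float)
    if scores.shape != (N_KMERS,):
        raise ValueError(f"expected {N_KMERS} word scores, got shape {scores.shape}")
    out = np.zeros(WINDOW_LENGTH)
    for p in range(1, WINDOW_LENGTH + 1):
        lo = max(1, p - KMER_SIZE + 1)
        hi = min(N_KMERS, p)
        cover = scores[lo - 1 : hi]
        out[p - 1] = cover.mean() if merge == "mean" else cover.sum()
    return out


def importance_profile(
    models: Sequence[ModelLike],
    sample: MethylSample,
    direction: str = "cls-query",
    merge: str = "mean",
):
    """Convenience: word-averaged scores and the 41-position profile."""
    wscores, enc2 = mulan_token_importance(models, sample, direction)
    dna = wscores[enc2.dna_word_indices]
    if len(dna) != N_KMERS:
        raise ValueError(f"expected {N_KMERS} DNA words, found {len(dna)}")
    return dna, position_importance(dna, merge), enc2


def dna_to_taxonomy_attention(
    model: ModelLike, sample: MethylSample
) -> pd.DataFrame:
    """36 x 8 matrix of last-layer attention from DNA words to rank names.

    Cell (w, r) sums, over heads and over the token pairs, the attention
    that DNA word w's tokens (as Query) place on rank r's name tokens.
    """
    attn = attention_matrices(model, sample)
    enc = attn.encoded
    last = attn.values[-1].sum(axis=0)  # (T, T), head-summed
    missing = [r for r in RANKS if r not in enc.taxonomy_token_spans]
    if missing:
        raise ValueError(f"sample has no recorded token span for ranks {missing}")

    word_tokens: Dict[int, List[int]] = {}
    for t, wi in enumerate(enc.word_ids):
        if wi >= 0:
            word_tokens.setdefault(wi, []).append(t)

    mat = np.zeros((N_KMERS, len(RANKS)))
    for k, wi in enumerate(enc.dna_word_indices[:N_KMERS]):
        toks = word_tokens.get(wi, [])
        for r, rank in enumerate(RANKS):
            lo, hi = enc.taxonomy_token_spans[rank]
            mat[k, r] = last[np.ix_(toks, range(lo, hi))].sum()
    if len(enc.dna_word_indices) != N_KMERS:
        raise ValueError(
            f"expected {N_KMERS} DNA words, found {len(enc.dna_word_indices)}"
        )
    kmers = [enc.words[wi] for wi in enc.dna_word_indices]
    return pd.DataFrame(mat, index=kmers, columns=list(RANKS))


def top_motifs(
    samples: Sequence[MethylSample],
    word_score_list: Sequence[np.ndarray],
    n: int = 10,
) -> pd.DataFrame:
    """Rank 6-mers by mean importance over a set of (positive) samples.

    ``word_score_list[i]`` holds the 36 DNA-word scores of ``samples[i]``.
    Returns the top-n motifs sorted by descending mean score with their
    occurrence counts.
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    if len(samples) != len(word_score_list):
        raise ValueError("samples and score lists differ in length")
    totals: Dict[str, float] = {}
    counts: Dict[str, int] = {}
    for s, scores in zip(samples, word_score_list):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (N_KMERS,):
            raise ValueError(f"expected {N_KMERS} scores per sample")
        for k in range(N_KMERS):
            kmer = s.sequence[k : k + KMER_SIZE]
            totals[kmer] = totals.get(kmer, 0.0) + float(scores[k])
            counts[kmer] = counts.get(kmer, 0) + 1
    rows = [
        {"motif": kmer, "mean_score": totals[kmer] / counts[kmer], "count": counts[kmer]}
        for kmer in totals
    ]
    df = pd.DataFrame(rows).sort_values(
        ["mean_score", "count", "motif"], ascending=[False, False, True]
    )
    return df.head(n).reset_index(drop=True)


def cls_embedding(model: ModelLike, sample: MethylSample) -> np.ndarray:
    """Final-layer hidden state at the [CLS] position (length hidden_size)."""
    handle = _as_handle(model)
    enc = _encode_for(model, sample)
    ids = np.array(enc.token_ids, dtype=np.int64)[None, :]
    mask = np.array(enc.attention_mask, dtype=np.float64)[None, :]
    hidden, _, _ = handle.encoder.forward(ids, mask)
    return hidden[0, 0, :]
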