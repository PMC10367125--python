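"""Custom tokenizers trained on the DNA + taxonomy corpus.

Each of the five model families gets its own tokenizer trained on the
pretraining corpus.  Vocabulary induction is frequency based: special
tokens, then single characters (as fallback pieces), then whole
whitespace-level words in descending corpus frequency up to the target
vocabulary size.  Segmentation of out-of-vocabulary words is greedy
longest-match.  The families differ in their subword convention:

* BERT / DistilBERT / ELECTRA — WordPiece style: continuation pieces carry
  a ``##`` prefix, so tokens are word-aligned whenever the word is in
  vocabulary.
* ALBERT / XLNet — SentencePiece style: word-initial pieces carry a ``▁``
  marker.

On a corpus of 6-mer DNA sentences the practical effect is identical for
all families at realistic vocabulary sizes: every one of the 4^6 = 4096
6-mers and every lineage word becomes a single token.

Encoded samples are ``[CLS] content [SEP]`` padded with ``[PAD]`` to a
fixed length of 100, with word/token alignment and the token spans of the
36 DNA words and of each taxonomic rank name recorded for interpretability.
"""

from __future__ import annotations

import json
import os
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .data_model import (
    Corpus,
    ProcessedSentence,
    RANKS,
    parse_lineage_sentence,
)

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP, MASK)

FAMILIES = ("bert", "distilbert", "albert", "xlnet", "electra")
WORDPIECE_FAMILIES = ("bert", "distilbert", "electra")
SENTENCEPIECE_FAMILIES = ("albert", "xlnet")

_WORD_RE = re.compile(r"[a-z0-9]+(?:['_-][a-z0-9]+)*|[^\sa-z0-9]")

DEFAULT_MAX_LEN = 100


def normalize_family(family: str) -> str:
    fam = family.strip().lower()
    if fam not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    return fam


def pretokenize(text: str) -> List[str]:
    """Lowercase and split into whitespace-level words and punctuation marks."""
    return _WORD_RE.findall(text.lower())


@dataclass
class TokenizerHandle:
    """A trained tokenizer: vocabulary, specials and segmentation rules."""

    family: str
    vocab: Dict[str, int]
    vocab_size_target: int
    lowercase: bool = True
    id_to_token: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.family = normalize_family(self.family)
        if not self.id_to_token:
            self.id_to_token = [""] * len(self.vocab)
            for tok, i in self.vocab.items():
                self.id_to_token[i] = tok
        for sp in SPECIAL_TOKENS:
            if sp not in self.vocab:
                raise ValueError(f"special token {sp} missing from vocabulary")
        ids = [self.vocab[sp] for sp in SPECIAL_TOKENS]
        if len(set(ids)) != len(ids):
            raise ValueError("special tokens must have distinct ids")
        if len(self.vocab) > self.vocab_size_target:
            raise ValueError(
                f"vocabulary size {len(self.vocab)} exceeds target {self.vocab_size_target}"
            )

    # -- id helpers ---------------------------------------------------------
    @property
    def pad_id(self) -> int:
        return self.vocab[PAD]

    @property
    def unk_id(self) -> int:
        return self.vocab[UNK]

    @property
    def cls_id(self) -> int:
        return self.vocab[CLS]

    @property
    def sep_id(self) -> int:
        return self.vocab[SEP]

    @property
    def mask_id(self) -> int:
        return self.vocab[MASK]

    @property
    def special_ids(self) -> Tuple[int, ...]:
        return tuple(self.vocab[sp] for sp in SPECIAL_TOKENS)

    @property
    def is_word_piece(self) -> bool:
        return self.family in WORDPIECE_FAMILIES

    def __len__(self) -> int:
        return len(self.vocab)

    # -- segmentation -------------------------------------------------------
    def tokenize_word(self, word: str) -> List[str]:
        """Segment one pre-token into vocabulary pieces (greedy longest match)."""
        word = word.lower() if self.lowercase else word
        if self.is_word_piece:
            return self._wordpiece(word)
        return self._sentencepiece(word)

    def _wordpiece(self, word: str) -> List[str]:
        pieces: List[str] = []
        i = 0
        while i < len(word):
            prefix = "##" if i > 0 else ""
            j = len(word)
            found = None
            while j > i:
                cand = prefix + word[i:j]
                if cand in self.vocab:
                    found = cand
                    break
                j -= 1
            if found is None:
                return [UNK]
            pieces.append(found)
            i = j
        return pieces or [UNK]

    def _sentencepiece(self, word: str) -> List[str]:
        pieces: List[str] = []
        i = 0
        while i < len(word):
            j = len(word)
            found = None
            while j > i:
                cand = ("▁" + word[i:j]) if i == 0 else word[i:j]
                if cand in self.vocab:
                    found = cand
                    break
                j -= 1
            if found is None:
                return [UNK]
            pieces.append(found)
            i = j
        return pieces or [UNK]

    def decode_pieces(self, pieces: List[str]) -> str:
        """Join pieces back into a word string (inverse of tokenize_word)."""
        out = []
        for p in pieces:
            if p in SPECIAL_TOKENS:
                continue
            if p.startswith("##"):
                out.append(p[2:])
            elif p.startswith("▁"):
                out.append(p[1:])
            else:
                out.append(p)
        return "".join(out)

    # -- persistence --------------------------------------------------------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "vocab.txt"), "w", encoding="utf-8") as fh:
            for tok in self.id_to_token:
                fh.write(tok + "\n")
        with open(
            os.path.join(directory, "tokenizer_config.json"), "w", encoding="utf-8"
        ) as fh:
            json.dump(
                {
                    "family": self.family,
                    "vocab_size_target": self.vocab_size_target,
                    "lowercase": self.lowercase,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, directory: str) -> "TokenizerHandle":
        with open(os.path.join(directory, "tokenizer_config.json"), encoding="utf-8") as fh:
            cfg = json.load(fh)
        with open(os.path.join(directory, "vocab.txt"), encoding="utf-8") as fh:
            tokens = [line.rstrip("\n") for line in fh]
        vocab = {tok: i for i, tok in enumerate(tokens)}
        return cls(
            family=cfg["family"],
            vocab=vocab,
            vocab_size_target=cfg["vocab_size_target"],
            lowercase=cfg.get("lowercase", True),
            id_to_token=tokens,
        )


def train_tokenizer(
    corpus: Corpus, family: str, vocab_size: Optional[int] = None
) -> TokenizerHandle:
    """Train a per-family tokenizer on the corpus.

    Deterministic for a fixed corpus and settings: words enter the
    vocabulary in descending frequency, ties broken lexicographically.
    """
    fam = normalize_family(family)
    if vocab_size is None:
        vocab_size = corpus.vocab_size_target
    if len(corpus) == 0:
        raise ValueError("cannot train a tokenizer on an empty corpus")
    if vocab_size <= len(SPECIAL_TOKENS):
        raise ValueError(
            f"vocab_size {vocab_size} must exceed the {len(SPECIAL_TOKENS)} special tokens"
        )

    counts: Counter = Counter()
    chars: set = set()
    for sentence in corpus.sentences:
        for word in pretokenize(sentence):
            counts[word] += 1
            chars.update(word)

    tokens: List[str] = list(SPECIAL_TOKENS)
    if fam in WORDPIECE_FAMILIES:
        fallback = sorted(chars) + ["##" + c for c in sorted(chars)]
        whole = lambda w: w  # noqa: E731
    else:
        fallback = ["▁" + c for c in sorted(chars)] + sorted(chars)
        whole = lambda w: "▁" + w  # noqa: E731
    tokens.extend(fallback)

    budget = vocab_size - len(tokens)
    for word, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if budget <= 0:
            break
        tok = whole(word)
        if tok in fallback:  # single-character word already present
            continue
        tokens.append(tok)
        budget -= 1

    vocab = {tok: i for i, tok in enumerate(tokens)}
    return TokenizerHandle(
        family=fam, vocab=vocab, vocab_size_target=vocab_size, id_to_token=tokens
    )


# ---------------------------------------------------------------------------
# Encoding

@dataclass
class EncodedSample:
    """A tokenized sample, fixed length, with word/token alignment.

    ``word_ids[i]`` is the index of the source word for token i, or -1 for
    special/padding tokens.  ``dna_token_span`` is the half-open token
    index range covering the DNA 6-mer words; ``taxonomy_token_spans`` maps
    each rank to the half-open range of its *name* tokens.
    """

    token_ids: List[int]
    attention_mask: List[int]
    token_strings: List[str]
    word_ids: List[int]
    words: List[str]
    dna_word_indices: List[int]
    dna_token_span: Optional[Tuple[int, int]]
    taxonomy_token_spans: Dict[str, Tuple[int, int]]
    source_id: str = ""

    @property
    def n_content_tokens(self) -> int:
        return sum(self.attention_mask)


def _classify_words(words: List[str]):
    """Tag each pre-token as DNA 6-mer, rank-name word, or template filler.

    Returns (tags, dna_word_indices) where tags[i] is ("dna", k),
    ("rank", rank_name) or ("tmpl", None).
    """
    tags: List[Tuple[str, object]] = [("tmpl", None)] * len(words)

    # locate the lineage clause marker "for this organism"
    marker = None
    for i in range(len(words) - 2):
        if words[i : i + 3] == ["for", "this", "organism"]:
            marker = i
            break

    dna_end = marker if marker is not None else len(words)
    dna_idx: List[int] = []
    for i in range(dna_end):
        if set(words[i]) <= set("acgt"):
            tags[i] = ("dna", len(dna_idx))
            dna_idx.append(i)
        # anything else before the clause stays template/filler

    if marker is not None:
        i = marker + 3  # past "for this organism"
        for r, rank in enumerate(RANKS):
            # skip ", its <rank> is"
            while i < len(words) and words[i] != rank:
                i += 1
            i += 1  # past the rank keyword
            if i < len(words) and words[i] == "is":
                i += 1
            # name words run until ", its <next rank>" or the final "."
            name_start = i
            while i < len(words):
                if words[i] == "," and i + 1 < len(words) and words[i + 1] == "its":
                    break
                if rank == RANKS[-1] and words[i] == "." and i == len(words) - 1:
                    break
                i += 1
            for j in range(name_start, min(i, len(words))):
                tags[j] = ("rank", rank)
    return tags, dna_idx


def encode(
    tokenizer: TokenizerHandle,
    sentence: ProcessedSentence,
    max_len: int = DEFAULT_MAX_LEN,
) -> EncodedSample:
    """Tokenize a processed sentence to exactly ``max_len`` token ids.

    Layout: ``[CLS] tokens... [SEP] [PAD]...``.  If the tokenized content
    overflows, pieces are dropped from the tail of the taxonomy clause
    first; DNA tokens are truncated only as a last resort.
    """
    if max_len < 2:
        raise ValueError(f"max_len {max_len} too small for [CLS] + [SEP]")
    words = pretokenize(sentence.text)
    tags, dna_word_idx = _classify_words(words)

    pieces: List[Tuple[str, int]] = []  # (piece, word_index)
    for wi, word in enumerate(words):
        for p in tokenizer.tokenize_word(word):
            pieces.append((p, wi))

    budget = max_len - 2
    if len(pieces) > budget:
        dna_words = {i for i, t in enumerate(tags) if t[0] == "dna"}
        keep = list(pieces)
        # drop non-DNA pieces from the tail first
        i = len(keep) - 1
        while len(keep) > budget and i >= 0:
            if keep[i][1] not in dna_words:
                del keep[i]
            i -= 1
        while len(keep) > budget:  # still over: truncate DNA tail
            keep.pop()
        pieces = keep

    token_strings = [CLS] + [p for p, _ in pieces] + [SEP]
    word_ids = [-1] + [wi for _, wi in pieces] + [-1]
    token_ids = [tokenizer.vocab.get(p, tokenizer.unk_id) for p in token_strings]
    attention_mask = [1] * len(token_ids)
    while len(token_ids) < max_len:
        token_ids.append(tokenizer.pad_id)
        token_strings.append(PAD)
        word_ids.append(-1)
        attention_mask.append(0)

    # spans (token indices, half-open)
    dna_positions = [
        i for i, wi in enumerate(word_ids) if wi >= 0 and tags[wi][0] == "dna"
    ]
    dna_span = (dna_positions[0], dna_positions[-1] + 1) if dna_positions else None
    rank_spans: Dict[str, Tuple[int, int]] = {}
    for rank in RANKS:
        pos = [
            i
            for i, wi in enumerate(word_ids)
            if wi >= 0 and tags[wi] == ("rank", rank)
        ]
        if pos:
            rank_spans[rank] = (pos[0], pos[-1] + 1)

    return EncodedSample(
        token_ids=token_ids,
        attention_mask=attention_mask,
        token_strings=token_strings,
        word_ids=word_ids,
        words=words,
        dna_word_indices=dna_word_idx,
        dna_token_span=dna_span,
        taxonomy_token_spans=rank_spans,
        source_id=sentence.source_id,
    )


def decode(tokenizer: TokenizerHandle, encoded: EncodedSample) -> List[str]:
    """Recover the word strings from an encoded sample (specials dropped)."""
    words: Dict[int, List[str]] = {}
    for piece, wi in zip(encoded.token_strings, encoded.word_ids):
        if wi < 0:
            continue
        words.setdefault(wi, []).append(piece)
    return [tokenizer.decode_pieces(words[wi]) for wi in sorted(words)]
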