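"""Self-supervised pretraining of the five model families on the corpus.

The default objective is masked language modelling: 15% of the non-special
WordPiece tokens of each sample are selected as masking candidates; of
these, 80% are replaced by [MASK], 10% by a random vocabulary token, and
10% are left unchanged, and the original tokens are predicted.  Following
their published pretraining recipes, the ELECTRA family instead trains a
replaced-token-detection discriminator on randomly corrupted inputs, and
the XLNet family predicts the tail of a random factorisation order of each
sample (permutation-derived partial prediction).

Two presets are provided: ``paper`` (12 layers, 768 hidden, 12 heads — the
published configuration, impractical to train on a laptop) and ``tiny``
(2 layers, 64 hidden, 4 heads) for desk-scale experiments.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._transformer import IGNORE_INDEX, Adam, TransformerEncoder
from .data_model import Corpus, ProcessedSentence
from .tokenization import EncodedSample, TokenizerHandle, encode, normalize_family

STAGES = ("pretrained", "finetuned-6mA", "finetuned-4mC", "finetuned-5hmC")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of one transformer family."""

    family: str
    n_layers: int
    n_heads: int
    hidden_size: int
    ffn_size: int
    vocab_size: int
    max_positions: int = 100
    preset: str = "custom"
    initializer_range: float = 0.02

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", normalize_family(self.family))
        if self.hidden_size % self.n_heads != 0:
            raise ValueError(
                f"hidden_size {self.hidden_size} not divisible by n_heads {self.n_heads}"
            )

    @property
    def d_k(self) -> int:
        return self.hidden_size // self.n_heads

    @classmethod
    def paper(cls, family: str, vocab_size: int = 25_000) -> "ModelConfig":
        """The published base configuration: 12 layers, 768 hidden, 12 heads."""
        return cls(family=family, n_layers=12, n_heads=12, hidden_size=768,
                   ffn_size=3072, vocab_size=vocab_size, preset="paper")

    @classmethod
    def tiny(cls, family: str, vocab_size: int) -> "ModelConfig":
        """Desk-scale configuration: 2 layers, 64 hidden, 4 heads."""
        return cls(family=family, n_layers=2, n_heads=4, hidden_size=64,
                   ffn_size=128, vocab_size=vocab_size, preset="tiny")


@dataclass(frozen=True)
class MaskingPolicy:
    """The 15% / 80% / 10% / 10% masking policy."""

    select_rate: float = 0.15
    mask_rate: float = 0.80
    random_rate: float = 0.10
    keep_rate: float = 0.10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.select_rate <= 1.0:
            raise ValueError("select_rate must be in [0, 1]")
        total = self.mask_rate + self.random_rate + self.keep_rate
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mask_rate + random_rate + keep_rate must equal 1, got {total}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Published defaults: pretraining 8 epochs, batch 64, lr 5e-4, 100 warmup
    steps; fine-tuning max 32 epochs, batch 64, lr 1e-5, 100 warmup steps,
    early stopping.
    """

    epochs: int = 8
    batch_size: int = 64
    learning_rate: float = 5e-4
    warmup_steps: int = 100
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0; batch_size and learning_rate positive")
        if self.warmup_steps < 0 or self.patience <= 0:
            raise ValueError("warmup_steps must be >= 0 and patience positive")

    @classmethod
    def pretraining_default(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=8, batch_size=64, learning_rate=5e-4,
                   warmup_steps=100, seed=seed)

    @classmethod
    def finetuning_default(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=32, batch_size=64, learning_rate=1e-5,
                   warmup_steps=100, patience=3, seed=seed)


@dataclass
class LanguageModelHandle:
    """A (pre)trained model: config + tokenizer + encoder parameters."""

    config: ModelConfig
    tokenizer: TokenizerHandle
    encoder: TransformerEncoder
    stage: str = "pretrained"
    history: Dict[str, List[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown training stage {self.stage!r}")

    def clone(self) -> "LanguageModelHandle":
        return LanguageModelHandle(
            config=self.config,
            tokenizer=self.tokenizer,
            encoder=self.encoder.clone(),
            stage=self.stage,
            history={k: list(v) for k, v in self.history.items()},
        )

    def checkpoint_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.encoder.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.encoder.params[name]).tobytes())
        return h.hexdigest()

    # -- persistence (config + weights + tokenizer directory layout) -------
    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        cfg = {
            "family": self.config.family,
            "n_layers": self.config.n_layers,
            "n_heads": self.config.n_heads,
            "hidden_size": self.config.hidden_size,
            "ffn_size": self.config.ffn_size,
            "vocab_size": self.config.vocab_size,
            "max_positions": self.config.max_positions,
            "preset": self.config.preset,
            "stage": self.stage,
        }
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump(cfg, fh, indent=2)
        np.savez(os.path.join(directory, "weights.npz"), **self.encoder.params)
        self.tokenizer.save(os.path.join(directory, "tokenizer"))

    @classmethod
    def load(cls, directory: str) -> "LanguageModelHandle":
        with open(os.path.join(directory, "config.json")) as fh:
            cfg = json.load(fh)
        stage = cfg.pop("stage", "pretrained")
        config = ModelConfig(**cfg)
        weights = np.load(os.path.join(directory, "weights.npz"))
        params = {k: weights[k] for k in weights.files}
        tokenizer = TokenizerHandle.load(os.path.join(directory, "tokenizer"))
        return cls(config=config, tokenizer=tokenizer,
                   encoder=TransformerEncoder(config, params=params), stage=stage)


# ---------------------------------------------------------------------------
# masking collator

def mask_tokens(
    encoded: EncodedSample,
    policy: MaskingPolicy,
    rng: np.random.Generator,
    tokenizer: TokenizerHandle,
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply the MLM masking policy to one encoded sample.

    Maskable positions are the non-special, non-padding tokens.  Each is
    selected independently with probability ``select_rate``; of the
    selected, ``mask_rate`` become [MASK], ``random_rate`` a random
    non-special vocabulary token, the rest stay unchanged.  Returns
    (masked token ids, labels) where labels hold the original id at
    selected positions and IGNORE_INDEX elsewhere.
    """
    ids = np.array(encoded.token_ids, dtype=np.int64)
    labels = np.full_like(ids, IGNORE_INDEX)
    special = set(tokenizer.special_ids)
    maskable = np.array(
        [m == 1 and t not in special
         for t, m in zip(encoded.token_ids, encoded.attention_mask)]
    )
    if policy.select_rate == 0.0 or not maskable.any():
        return ids, labels

    selected = maskable & (rng.random(len(ids)) < policy.select_rate)
    labels[selected] = ids[selected]

    u = rng.random(len(ids))
    to_mask = selected & (u < policy.mask_rate)
    to_random = selected & (u >= policy.mask_rate) & (u < policy.mask_rate + policy.random_rate)
    ids[to_mask] = tokenizer.mask_id

    n_rand = int(to_random.sum())
    if n_rand:
        non_special = np.array(
            [i for i in range(len(tokenizer)) if i not in special], dtype=np.int64
        )
        ids[to_random] = rng.choice(non_special, size=n_rand)
    return ids, labels


# ---------------------------------------------------------------------------
# objective-specific batch builders

def _mlm_batch(ids_batch, encoded_batch, policy, rng, tokenizer):
    masked, labels = [], []
    for enc in encoded_batch:
        m, l = mask_tokens(enc, policy, rng, tokenizer)
        masked.append(m)
        labels.append(l)
    return np.stack(masked), np.stack(labels)


def _plm_batch(encoded_batch, policy, rng, tokenizer):
    """Permutation partial prediction: targets are the tail of a random
    factorisation order (the last ~select_rate fraction), hidden with [MASK]."""
    special = set(tokenizer.special_ids)
    masked, labels = [], []
    for enc in encoded_batch:
        ids = np.array(enc.token_ids, dtype=np.int64)
        lab = np.full_like(ids, IGNORE_INDEX)
        positions = [
            i for i, (t, m) in enumerate(zip(enc.token_ids, enc.attention_mask))
            if m == 1 and t not in special
        ]
        if positions:
            order = rng.permutation(len(positions))
            n_tgt = max(1, int(round(policy.select_rate * len(positions))))
            tgt = [positions[j] for j in order[-n_tgt:]]
            lab[tgt] = ids[tgt]
            ids[tgt] = tokenizer.mask_id
        masked.append(ids)
        labels.append(lab)
    return np.stack(masked), np.stack(labels)


def _rtd_batch(encoded_batch, policy, rng, tokenizer, unigram_ids, unigram_p):
    """Replaced-token detection: corrupt ~select_rate of content tokens with
    draws from the corpus unigram distribution; label replaced vs original."""
    special = set(tokenizer.special_ids)
    corrupted, labels, positions = [], [], []
    for enc in encoded_batch:
        ids = np.array(enc.token_ids, dtype=np.int64)
        lab = np.zeros_like(ids)
        pos = np.array(
            [m == 1 and t not in special
             for t, m in zip(enc.token_ids, enc.attention_mask)]
        )
        sel = pos & (rng.random(len(ids)) < policy.select_rate)
        n = int(sel.sum())
        if n:
            draws = rng.choice(unigram_ids, size=n, p=unigram_p)
            changed = draws != ids[sel]
            idx = np.flatnonzero(sel)
            ids[idx] = draws
            lab[idx] = changed.astype(np.int64)
        corrupted.append(ids)
        labels.append(lab)
        positions.append(pos)
    return np.stack(corrupted), np.stack(labels), np.stack(positions)


def _unigram_distribution(id_matrix: np.ndarray, tokenizer: TokenizerHandle):
    counts = np.bincount(id_matrix.reshape(-1), minlength=len(tokenizer)).astype(np.float64)
    for i in tokenizer.special_ids:
        counts[i] = 0.0
    if counts.sum() == 0:
        counts[:] = 1.0
        for i in tokenizer.special_ids:
            counts[i] = 0.0
    ids = np.flatnonzero(counts)
    return ids, counts[ids] / counts[ids].sum()


# ---------------------------------------------------------------------------
# pretraining loop

def encode_corpus(
    corpus: Corpus, tokenizer: TokenizerHandle, max_len: int = 100
) -> List[EncodedSample]:
    return [
        encode(tokenizer, ProcessedSentence(text=s, source_id=f"corpus_{i}"), max_len)
        for i, s in enumerate(corpus.sentences)
    ]


def pretrain_mlm(
    corpus: Corpus,
    tokenizer: TokenizerHandle,
    config: ModelConfig,
    train: TrainConfig,
    policy: Optional[MaskingPolicy] = None,
    holdout_fraction: float = 0.1,
) -> LanguageModelHandle:
    """Pretrain one family on the corpus with its family-specific objective.

    A held-out slice of the corpus is used only to evaluate the objective
    loss before training and after each epoch (recorded in ``history``).
    """
    if config.vocab_size != len(tokenizer):
        raise ValueError(
            f"config.vocab_size {config.vocab_size} does not match tokenizer "
            f"vocabulary size {len(tokenizer)}; the input embedding must match"
        )
    if policy is None:
        policy = MaskingPolicy()
    objective = {"electra": "rtd", "xlnet": "plm"}.get(config.family, "mlm")

    encoded = encode_corpus(corpus, tokenizer, config.max_positions)
    rng = np.random.default_rng(train.seed)

    n = len(encoded)
    n_holdout = max(1, int(round(holdout_fraction * n))) if n >= 5 else 0
    perm = rng.permutation(n)
    holdout = [encoded[i] for i in perm[:n_holdout]]
    train_set = [encoded[i] for i in perm[n_holdout:]]
    if not train_set:
        train_set, holdout = holdout, []

    model = TransformerEncoder(config, seed=train.seed)
    handle = LanguageModelHandle(config=config, tokenizer=tokenizer,
                                 encoder=model, stage="pretrained",
                                 history={"train_loss": [], "eval_loss": []})
    unigram_ids, unigram_p = _unigram_distribution(
        np.stack([np.array(e.token_ids) for e in train_set]), tokenizer
    )

    def batch_loss_and_grads(batch: List[EncodedSample], eval_rng, train_mode=True):
        mask = np.stack([np.array(e.attention_mask, dtype=np.float64) for e in batch])
        if objective == "mlm":
            ids, labels = _mlm_batch(None, batch, policy, eval_rng, tokenizer)
            hidden, _, cache = model.forward(ids, mask)
            loss, dh, hg = model.mlm_loss(hidden, labels)
        elif objective == "plm":
            ids, labels = _plm_batch(batch, policy, eval_rng, tokenizer)
            hidden, _, cache = model.forward(ids, mask)
            loss, dh, hg = model.mlm_loss(hidden, labels)
        else:  # rtd
            ids, labels, pos = _rtd_batch(batch, policy, eval_rng, tokenizer,
                                          unigram_ids, unigram_p)
            hidden, _, cache = model.forward(ids, mask)
            loss, dh, hg = model.disc_loss(hidden, labels, pos)
        if not train_mode:
            return loss, None
        grads = model.backward(cache, dh)
        grads.update(hg)
        return loss, grads

    def eval_loss() -> float:
        if not holdout:
            return float("nan")
        erng = np.random.default_rng(train.seed + 7919)
        losses = []
        for i in range(0, len(holdout), train.batch_size):
            loss, _ = batch_loss_and_grads(
                holdout[i : i + train.batch_size], erng, train_mode=False
            )
            losses.append(loss)
        return float(np.mean(losses))

    handle.history["eval_loss"].append(eval_loss())
    if train.epochs == 0:
        return handle

    opt = Adam(model.params, lr=train.learning_rate, warmup_steps=train.warmup_steps)
    for _ in range(train.epochs):
        order = rng.permutation(len(train_set))
        for i in range(0, len(order), train.batch_size):
            batch = [train_set[j] for j in order[i : i + train.batch_size]]
            loss, grads = batch_loss_and_grads(batch, rng)
            opt.step(model.params, grads)
            handle.history["train_loss"].append(loss)
        handle.history["eval_loss"].append(eval_loss())
    return handle
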