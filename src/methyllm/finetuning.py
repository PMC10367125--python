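"""Cascaded supervised fine-tuning and per-sample probability prediction.

Each methylation type gets its own classifier, fine-tuned in a cascade
ordered by decreasing training-set size: the 6mA model is fine-tuned from
the pretrained model, the 4mC model from the 6mA model, and the 5hmC model
from the 4mC model.  A 2-way softmax head on the [CLS] representation
scores each 41-nt window; training uses an internal stratified 8:2
train/validation split with early stopping on validation loss, returning
the best-validation checkpoint.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._transformer import Adam, softmax
from .data_model import (
    METHYL_TYPES,
    MethylDataset,
    MethylSample,
    build_sentence,
    train_val_split,
)
from .pretraining import LanguageModelHandle, TrainConfig
from .tokenization import EncodedSample, encode

CASCADE_ORDER = ("6mA", "4mC", "5hmC")


@dataclass
class FineTunedModel:
    """A fine-tuned classifier for one methylation type.

    ``provenance`` is the checkpoint hash of the model this one was
    fine-tuned from; ``provenance_chain`` lists the hashes back to the
    pretrained model (length 1 for 6mA, 3 for 5hmC in a full cascade).
    """

    handle: LanguageModelHandle
    methyl_type: str
    provenance: str
    provenance_chain: List[str] = field(default_factory=list)
    history: Dict[str, List[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.methyl_type not in METHYL_TYPES:
            raise ValueError(f"unknown methylation type {self.methyl_type!r}")
        if not self.provenance_chain:
            self.provenance_chain = [self.provenance]

    @property
    def family(self) -> str:
        return self.handle.config.family

    @property
    def tokenizer(self):
        return self.handle.tokenizer

    @property
    def encoder(self):
        return self.handle.encoder

    def checkpoint_hash(self) -> str:
        return self.handle.checkpoint_hash()

    def save(self, directory: str) -> None:
        self.handle.save(directory)
        with open(os.path.join(directory, "finetune_meta.json"), "w") as fh:
            json.dump(
                {
                    "methyl_type": self.methyl_type,
                    "provenance": self.provenance,
                    "provenance_chain": self.provenance_chain,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, directory: str) -> "FineTunedModel":
        handle = LanguageModelHandle.load(directory)
        with open(os.path.join(directory, "finetune_meta.json")) as fh:
            meta = json.load(fh)
        return cls(handle=handle, methyl_type=meta["methyl_type"],
                   provenance=meta["provenance"],
                   provenance_chain=meta["provenance_chain"])


def _as_handle(model: Union[LanguageModelHandle, FineTunedModel]) -> LanguageModelHandle:
    return model.handle if isinstance(model, FineTunedModel) else model


def _encode_samples(
    handle: LanguageModelHandle, samples: Sequence[MethylSample]
) -> List[EncodedSample]:
    return [
        encode(handle.tokenizer, build_sentence(s), handle.config.max_positions)
        for s in samples
    ]


def _batches(n: int, batch_size: int):
    for i in range(0, n, batch_size):
        yield slice(i, i + batch_size)


def finetune(
    model: Union[LanguageModelHandle, FineTunedModel],
    subset: MethylDataset,
    train: Optional[TrainConfig] = None,
) -> FineTunedModel:
    """Fine-tune a model on one methylation type's labelled samples.

    Applies an internal stratified 8:2 train/validation split, optimises
    the [CLS] classifier cross-entropy, early-stops after ``patience``
    epochs without validation-loss improvement, and returns the
    best-validation checkpoint.
    """
    if train is None:
        train = TrainConfig.finetuning_default()
    if len(subset) == 0:
        raise ValueError("cannot fine-tune on an empty dataset")
    types = {s.methyl_type for s in subset}
    if len(types) != 1:
        raise ValueError(
            f"fine-tuning subset must contain a single methylation type, got {sorted(types)}"
        )
    methyl_type = types.pop()
    if any(s.label is None for s in subset):
        raise ValueError("fine-tuning requires labelled samples")

    parent = _as_handle(model)
    parent_hash = parent.checkpoint_hash()
    parent_chain = (
        model.provenance_chain if isinstance(model, FineTunedModel) else []
    )
    handle = parent.clone()
    handle.stage = f"finetuned-{methyl_type}"
    handle.history = {"train_loss": [], "val_loss": []}
    result = FineTunedModel(
        handle=handle,
        methyl_type=methyl_type,
        provenance=parent_hash,
        provenance_chain=list(parent_chain) + [parent_hash],
        history=handle.history,
    )
    if train.epochs == 0:
        return result

    train_ds, val_ds = train_val_split(subset, ratio=0.8, seed=train.seed)
    enc_train = _encode_samples(handle, train_ds.samples)
    enc_val = _encode_samples(handle, val_ds.samples)
    y_train = np.array([s.label for s in train_ds], dtype=np.int64)
    y_val = np.array([s.label for s in val_ds], dtype=np.int64)

    def stack(encs: List[EncodedSample]):
        ids = np.stack([np.array(e.token_ids, dtype=np.int64) for e in encs])
        mask = np.stack([np.array(e.attention_mask, dtype=np.float64) for e in encs])
        return ids, mask

    ids_tr, mask_tr = stack(enc_train)
    ids_va, mask_va = (stack(enc_val) if enc_val else (None, None))
    enc = handle.encoder

    def val_loss() -> float:
        if ids_va is None or len(y_val) == 0:
            return float("nan")
        losses, ns = [], []
        for sl in _batches(len(y_val), train.batch_size):
            hidden, _, _ = enc.forward(ids_va[sl], mask_va[sl])
            loss, _, _ = enc.cls_loss(hidden, y_val[sl])
            losses.append(loss)
            ns.append(len(y_val[sl]))
        return float(np.average(losses, weights=ns))

    rng = np.random.default_rng(train.seed)
    opt = Adam(enc.params, lr=train.learning_rate, warmup_steps=train.warmup_steps)
    best_loss = val_loss()
    best_params = {k: v.copy() for k, v in enc.params.items()}
    handle.history["val_loss"].append(best_loss)
    bad_epochs = 0

    for _ in range(train.epochs):
        order = rng.permutation(len(y_train))
        for sl in _batches(len(order), train.batch_size):
            idx = order[sl]
            hidden, _, cache = enc.forward(ids_tr[idx], mask_tr[idx])
            loss, dh, head_grads = enc.cls_loss(hidden, y_train[idx])
            grads = enc.backward(cache, dh)
            grads.update(head_grads)
            opt.step(enc.params, grads)
            handle.history["train_loss"].append(loss)
        vloss = val_loss()
        handle.history["val_loss"].append(vloss)
        if np.isnan(vloss) or vloss < best_loss or np.isnan(best_loss):
            best_loss = vloss
            best_params = {k: v.copy() for k, v in enc.params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= train.patience:
                break

    enc.params = best_params
    return result


def cascade_finetune(
    pretrained: LanguageModelHandle,
    subsets: Dict[str, MethylDataset],
    train: Optional[TrainConfig] = None,
) -> Dict[str, FineTunedModel]:
    """Fine-tune the 6mA -> 4mC -> 5hmC cascade from a pretrained model.

    Each stage starts from the previous stage's fine-tuned model; empty or
    missing subsets are skipped with a warning, and the next stage then
    starts from the last model that was actually trained.
    """
    models: Dict[str, FineTunedModel] = {}
    current: Union[LanguageModelHandle, FineTunedModel] = pretrained
    for mtype in CASCADE_ORDER:
        subset = subsets.get(mtype)
        if subset is None or len(subset) == 0:
            warnings.warn(f"cascade: no {mtype} samples; stage skipped")
            continue
        stage_train = train
        models[mtype] = finetune(current, subset, stage_train)
        current = models[mtype]
    return models


@dataclass(frozen=True)
class PredictionError:
    """Record of a sample that could not be scored."""

    index: int
    sample_id: str
    message: str


def predict_proba(
    model: FineTunedModel,
    samples: Sequence[MethylSample],
    batch_size: int = 64,
    return_errors: bool = False,
):
    """Positive-class probability for each sample (NaN on encoding failure).

    Deterministic: evaluation involves no randomness.  With
    ``return_errors`` a list of per-sample error records is also returned.
    """
    handle = _as_handle(model)
    probs = np.full(len(samples), np.nan)
    errors: List[PredictionError] = []
    encoded: List[Tuple[int, EncodedSample]] = []
    for i, s in enumerate(samples):
        try:
            encoded.append(
                (i, encode(handle.tokenizer, build_sentence(s), handle.config.max_positions))
            )
        except ValueError as exc:
            errors.append(PredictionError(index=i, sample_id=s.id, message=str(exc)))

    enc = handle.encoder
    for j in range(0, len(encoded), batch_size):
        chunk = encoded[j : j + batch_size]
        ids = np.stack([np.array(e.token_ids, dtype=np.int64) for _, e in chunk])
        mask = np.stack([np.array(e.attention_mask, dtype=np.float64) for _, e in chunk])
        hidden, _, _ = enc.forward(ids, mask)
        p = softmax(enc.cls_logits(hidden))[:, 1]
        for (i, _), pi in zip(chunk, p):
            probs[i] = pi

    if return_errors:
        return probs, errors
    return probs
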