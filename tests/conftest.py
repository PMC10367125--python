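"""Shared fixtures: synthetic datasets and trained tiny models.

Training fixtures are session-scoped because fine-tuning even the tiny
preset takes tens of seconds; every test that needs a trained model shares
the same fixed-seed artifacts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import methyllm as ml

# fixed study conditions for the shared trained models
PRETRAIN_CFG = ml.TrainConfig(
    epochs=2, batch_size=16, learning_rate=5e-4, warmup_steps=20, seed=3
)
FINETUNE_CFG = ml.TrainConfig(
    epochs=8, batch_size=16, learning_rate=2e-4, warmup_steps=20, patience=3, seed=3
)
VOCAB_SIZE = 6000
WORDWISE = ("bert", "distilbert", "electra")


@pytest.fixture(scope="session")
def train_data():
    """Per-type noiseless planted-motif training datasets with truths."""
    d6, t6 = ml.generate_dataset(200, 200, "6mA", seed=1, id_prefix="a6_")
    d4, t4 = ml.generate_dataset(120, 120, "4mC", seed=2, id_prefix="c4_")
    d5, t5 = ml.generate_dataset(120, 120, "5hmC", seed=3, id_prefix="h5_")
    return {
        "6mA": (d6, t6),
        "4mC": (d4, t4),
        "5hmC": (d5, t5),
    }


@pytest.fixture(scope="session")
def combined_dataset(train_data):
    samples = []
    for mtype in ml.METHYL_TYPES:
        samples.extend(train_data[mtype][0].samples)
    return ml.MethylDataset(samples)


@pytest.fixture(scope="session")
def corpus(combined_dataset):
    return ml.build_corpus(combined_dataset, ml.DEFAULT_LINEAGES)


@pytest.fixture(scope="session")
def bert_tokenizer(corpus):
    return ml.train_tokenizer(corpus, "bert", VOCAB_SIZE)


@pytest.fixture(scope="session")
def family_models(corpus, train_data):
    """Pretrained handle + full fine-tuning cascade for each word-wise family."""
    subsets = {mtype: train_data[mtype][0] for mtype in ml.METHYL_TYPES}
    out = {}
    for fam in WORDWISE:
        tok = ml.train_tokenizer(corpus, fam, VOCAB_SIZE)
        cfg = ml.ModelConfig.tiny(fam, vocab_size=len(tok))
        pretrained = ml.pretrain_mlm(corpus, tok, cfg, PRETRAIN_CFG)
        cascade = ml.cascade_finetune(pretrained, subsets, FINETUNE_CFG)
        out[fam] = {"pretrained": pretrained, **cascade}
    return out


@pytest.fixture(scope="session")
def ensembles(family_models):
    """One 3-member ensemble per methylation type."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mtype in ml.METHYL_TYPES:
            out[mtype] = ml.EnsembleModel(
                members={fam: family_models[fam][mtype] for fam in WORDWISE},
                methyl_type=mtype,
            )
    return out


@pytest.fixture(scope="session")
def ensemble6(ensembles):
    return ensembles["6mA"]


@pytest.fixture(scope="session")
def wordwise6(family_models):
    """The three word-wise 6mA models, for importance averaging."""
    return [family_models[fam]["6mA"] for fam in WORDWISE]


@pytest.fixture(scope="session")
def bert6(family_models):
    return family_models["bert"]["6mA"]


@pytest.fixture(scope="session")
def heldout6():
    ds, truth = ml.generate_dataset(100, 100, "6mA", seed=99, id_prefix="t6_")
    return ds, truth


@pytest.fixture(scope="session")
def small_corpus():
    """A small corpus for cheap tokenizer unit tests."""
    ds, _ = ml.generate_dataset(30, 30, "6mA", seed=17)
    return ml.build_corpus(ds, ml.DEFAULT_LINEAGES)


@pytest.fixture(scope="session")
def small_tokenizer(small_corpus):
    return ml.train_tokenizer(small_corpus, "bert", 4000)


@pytest.fixture(scope="session")
def untrained_handle(small_corpus, small_tokenizer):
    """A freshly initialised (0-epoch) model for cheap structural tests."""
    cfg = ml.ModelConfig.tiny("bert", vocab_size=len(small_tokenizer))
    train = ml.TrainConfig(epochs=0, batch_size=16, seed=11)
    return ml.pretrain_mlm(small_corpus, small_tokenizer, cfg, train)
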