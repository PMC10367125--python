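"""Domain types, sentence encoding, splitting and corpus assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import methyllm as ml
from methyllm.data_model import UNKNOWN_RANK


def make_lineage(i: int = 0) -> ml.TaxonomicLineage:
    return ml.TaxonomicLineage(
        species=f"Genus species{i}", genus=f"Genus{i}", family=f"Famil{i}idae",
        order=f"Ord{i}ales", class_=f"Class{i}ia", phylum=f"Phyl{i}a",
        kingdom=f"King{i}dom", domain="Eukaryota",
    )


def make_sample(seq: str, label=1, methyl_type="6mA", sid="s1", lineage=None):
    return ml.MethylSample(
        id=sid, sequence=seq, label=label, methyl_type=methyl_type,
        lineage=lineage or make_lineage(),
    )


def pos_sequence(methyl_type="6mA", seed=0) -> str:
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), 41)))
    seq[20] = ml.TARGET_BASE[methyl_type]
    return "".join(seq)


# ---------------------------------------------------------------------------
# k-mer extraction

def test_41nt_window_yields_exactly_36_six_mers():
    kmers = ml.extract_kmers(pos_sequence(), 6)
    assert len(kmers) == 36


@pytest.mark.parametrize(
    "seq,k,expected",
    [
        ("ACGTAC", 6, ["ACGTAC"]),
        ("ACGTACGT", 6, ["ACGTAC", "CGTACG", "GTACGT"]),  # hand enumeration
        ("ACGT", 1, ["A", "C", "G", "T"]),
    ],
)
def test_extract_kmers_enumerates_all_offsets(seq, k, expected):
    assert ml.extract_kmers(seq, k) == expected


def test_extract_kmers_too_short_names_both_lengths():
    with pytest.raises(ValueError, match="5.*6|6.*5"):
        ml.extract_kmers("ACGTA", 6)


@settings(max_examples=100, deadline=None)
@given(
    seq=st.text(alphabet="ACGT", min_size=1, max_size=80),
    k=st.integers(min_value=1, max_value=12),
)
def test_kmer_count_property(seq, k):
    if len(seq) < k:
        with pytest.raises(ValueError):
            ml.extract_kmers(seq, k)
        return
    kmers = ml.extract_kmers(seq, k)
    assert len(kmers) == len(seq) - k + 1
    assert all(seq[i : i + k] == km for i, km in enumerate(kmers))


# ---------------------------------------------------------------------------
# lineage sentence

def test_lineage_sentence_follows_template():
    text = ml.lineage_sentence(make_lineage(0))
    assert text.startswith("For this organism, its species is Genus species0, its genus is")
    assert text.endswith("its domain is Eukaryota.")


def test_all_unknown_lineage_renders_eight_placeholders():
    text = ml.lineage_sentence(ml.TaxonomicLineage())
    assert text.count(UNKNOWN_RANK) == 8


@given(
    names=st.lists(
        st.text(alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ",
                min_size=1, max_size=12),
        min_size=8, max_size=8,
    )
)
@settings(max_examples=50, deadline=None)
def test_lineage_sentence_round_trips(names):
    lineage = ml.TaxonomicLineage(*names)
    recovered = ml.parse_lineage_sentence(ml.lineage_sentence(lineage))
    assert recovered is not None
    assert recovered.as_tuple() == lineage.as_tuple()


def test_empty_rank_becomes_unknown():
    lin = ml.TaxonomicLineage(species="", genus="  ")
    assert lin.species == UNKNOWN_RANK
    assert lin.genus == UNKNOWN_RANK


# ---------------------------------------------------------------------------
# build_sentence

def test_sentence_dna_part_has_36_words():
    sent = ml.build_sentence(make_sample(pos_sequence()))
    dna_part = sent.text.split(" For this organism")[0]
    assert len(dna_part.split()) == 36


def test_sentence_word_count_is_36_plus_lineage_words():
    sample = make_sample(pos_sequence())
    sent = ml.build_sentence(sample)
    lineage_words = ml.lineage_sentence(sample.lineage).split()
    assert len(sent.text.split()) == 36 + len(lineage_words)


def test_same_sequence_different_lineage_differs_only_after_dna():
    seq = pos_sequence()
    s1 = ml.build_sentence(make_sample(seq, lineage=make_lineage(1)))
    s2 = ml.build_sentence(make_sample(seq, lineage=make_lineage(2)))
    assert s1.text[: 36 * 7 - 1] == s2.text[: 36 * 7 - 1]
    assert s1.text != s2.text


def test_sequence_with_n_rejected_at_sentence_encoding():
    seq = pos_sequence()[:5] + "N" + pos_sequence()[6:]
    sample = make_sample(seq, label=0)  # accepted at parse time
    with pytest.raises(ValueError, match="N"):
        ml.build_sentence(sample)


# ---------------------------------------------------------------------------
# sample validation

def test_sample_invariants():
    with pytest.raises(ValueError, match="length"):
        make_sample("ACGT")
    with pytest.raises(ValueError, match="invalid characters"):
        make_sample(pos_sequence()[:-1] + "X", label=0)
    # positive 6mA sample must have A at position 21
    bad = pos_sequence("4mC")  # C at center
    with pytest.raises(ValueError, match="position 21"):
        make_sample(bad, label=1, methyl_type="6mA")
    make_sample(bad, label=1, methyl_type="4mC")  # fine for 4mC


def test_dataset_rejects_duplicate_ids():
    s = make_sample(pos_sequence())
    with pytest.raises(ValueError, match="duplicate"):
        ml.MethylDataset([s, s])


# ---------------------------------------------------------------------------
# splitting

def test_split_by_type_partitions(train_data):
    mixed = ml.MethylDataset(
        train_data["6mA"][0].samples + train_data["4mC"][0].samples
    )
    parts = ml.split_by_type(mixed)
    assert sum(len(p) for p in parts.values()) == len(mixed)
    assert len(parts["5hmC"]) == 0
    # independent tally
    for mtype in ml.METHYL_TYPES:
        expected = sum(1 for s in mixed if s.methyl_type == mtype)
        assert len(parts[mtype]) == expected
    # concatenation is a permutation of the input
    ids = sorted(s.id for p in parts.values() for s in p)
    assert ids == sorted(s.id for s in mixed)


def test_train_val_split_sizes_and_determinism():
    ds, _ = ml.generate_dataset(5, 5, "6mA", seed=4)
    train, val = ml.train_val_split(ds, ratio=0.8, seed=7)
    assert (len(train), len(val)) == (8, 2)
    train2, val2 = ml.train_val_split(ds, ratio=0.8, seed=7)
    assert [s.id for s in train] == [s.id for s in train2]
    assert [s.id for s in val] == [s.id for s in val2]
    assert {s.id for s in train}.isdisjoint({s.id for s in val})


@pytest.mark.parametrize("n_pos,n_neg,ratio", [(7, 13, 0.8), (10, 10, 0.5), (3, 17, 0.7)])
def test_train_val_split_is_stratified(n_pos, n_neg, ratio):
    ds, _ = ml.generate_dataset(n_pos, n_neg, "6mA", seed=5)
    train, val = ml.train_val_split(ds, ratio=ratio, seed=1)
    n = n_pos + n_neg
    assert len(train) == math.ceil(ratio * n)
    for label, n_class in [(1, n_pos), (0, n_neg)]:
        got = sum(1 for s in train if s.label == label)
        assert abs(got - ratio * n_class) <= 1  # per-class share within 1


def test_split_empty_dataset_errors():
    with pytest.raises(ValueError, match="empty"):
        ml.train_val_split(ml.MethylDataset([]), 0.8, 0)


# ---------------------------------------------------------------------------
# corpus assembly

def test_corpus_without_extras_matches_dataset_size(train_data):
    ds = train_data["6mA"][0]
    corpus = ml.build_corpus(ds, [])
    assert len(corpus) == len(ds)


def test_corpus_deduplicates_lineages_by_exact_tuple(train_data):
    ds = train_data["6mA"][0]
    training_lineage = ds.samples[0].lineage
    novel = [make_lineage(100), make_lineage(101), make_lineage(100)]
    corpus = ml.build_corpus(ds, [training_lineage] + novel)
    # set-difference oracle: duplicates of training lineages and of each
    # other are not added
    training_tuples = {s.lineage.as_tuple() for s in ds}
    expected_novel = {
        l.as_tuple() for l in novel if l.as_tuple() not in training_tuples
    }
    assert len(corpus) == len(ds) + len(expected_novel)


def test_corpus_rejects_empty_sentences():
    with pytest.raises(ValueError, match="empty"):
        ml.Corpus(["ok", ""])


# ---------------------------------------------------------------------------
# I/O

def test_sample_tsv_round_trip(tmp_path, train_data):
    ds = train_data["4mC"][0]
    path = tmp_path / "samples.tsv"
    ml.write_samples_tsv(ds, path)
    back = ml.read_samples_tsv(path)
    assert [s.id for s in back] == [s.id for s in ds]
    assert all(
        (a.sequence, a.label, a.methyl_type, a.lineage.as_tuple())
        == (b.sequence, b.label, b.methyl_type, b.lineage.as_tuple())
        for a, b in zip(back, ds)
    )
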