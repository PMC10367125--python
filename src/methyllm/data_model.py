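"""Domain types and sample-to-sentence encoding for methylation-site prediction.

A prediction unit is a 41-nt DNA window centered on a candidate methylated
base (A for 6mA, C for 4mC/5hmC) together with the 8-rank taxonomic lineage
of the source organism.  Each sample is rendered as a natural-language
sentence: the 36 overlapping 6-mers of the window (a sliding window of
length 6 over 41 nt yields 41 - 6 + 1 = 36 "words"), followed by a templated
English description of the lineage.  These sentences feed the tokenizer,
the pretraining corpus, and the fine-tuning datasets.

Coordinates are 1-based internally ("position 21" is the center of a
41-mer); conversion to 0-based happens only at I/O boundaries (BED output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Constants

WINDOW_LENGTH = 41
CENTER_POS = 21  # 1-based center of a 41-nt window
KMER_SIZE = 6
N_KMERS = WINDOW_LENGTH - KMER_SIZE + 1  # 36

METHYL_TYPES = ("6mA", "4mC", "5hmC")
#: the base that must sit at the window center for each methylation type
TARGET_BASE = {"6mA": "A", "4mC": "C", "5hmC": "C"}

RANKS = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
    "domain",
)

UNKNOWN_RANK = "unknown"

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


# ---------------------------------------------------------------------------
# Types

@dataclass(frozen=True)
class TaxonomicLineage:
    """An 8-rank lineage, species -> domain; missing ranks hold "unknown"."""

    species: str = UNKNOWN_RANK
    genus: str = UNKNOWN_RANK
    family: str = UNKNOWN_RANK
    order: str = UNKNOWN_RANK
    class_: str = UNKNOWN_RANK
    phylum: str = UNKNOWN_RANK
    kingdom: str = UNKNOWN_RANK
    domain: str = UNKNOWN_RANK

    def __post_init__(self) -> None:
        for rank in RANKS:
            if not self.name_for(rank) or not self.name_for(rank).strip():
                # empty names are normalised to the explicit placeholder
                object.__setattr__(
                    self, "class_" if rank == "class" else rank, UNKNOWN_RANK
                )

    def name_for(self, rank: str) -> str:
        return getattr(self, "class_" if rank == "class" else rank)

    def as_tuple(self) -> Tuple[str, ...]:
        return tuple(self.name_for(r) for r in RANKS)

    @classmethod
    def from_dict(cls, d: Dict[str, str]) -> "TaxonomicLineage":
        kw = {}
        for rank in RANKS:
            key = "class_" if rank == "class" else rank
            val = d.get(rank, d.get(key, UNKNOWN_RANK))
            if val is None or (isinstance(val, float) and math.isnan(val)):
                val = UNKNOWN_RANK
            val = str(val).strip()
            kw[key] = val if val else UNKNOWN_RANK
        return cls(**kw)


@dataclass(frozen=True)
class MethylSample:
    """One 41-nt window: the atomic training / prediction unit.

    ``label`` is 1 (methylated / positive), 0 (negative) or None for
    unlabeled windows (e.g. candidates produced by a genome scan).
    """

    id: str
    sequence: str
    label: Optional[int]
    methyl_type: str
    lineage: TaxonomicLineage

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) != WINDOW_LENGTH:
            raise ValueError(
                f"sample {self.id!r}: sequence length {len(seq)} != {WINDOW_LENGTH}"
            )
        if not set(seq) <= _DNA_N:
            bad = sorted(set(seq) - _DNA_N)
            raise ValueError(f"sample {self.id!r}: invalid characters {bad}")
        if self.methyl_type not in METHYL_TYPES:
            raise ValueError(
                f"sample {self.id!r}: methyl_type {self.methyl_type!r} not one of {METHYL_TYPES}"
            )
        if self.label not in (0, 1, None):
            raise ValueError(f"sample {self.id!r}: label must be 0, 1 or None")
        if self.label == 1:
            want = TARGET_BASE[self.methyl_type]
            got = seq[CENTER_POS - 1]
            if got != want:
                raise ValueError(
                    f"sample {self.id!r}: positive {self.methyl_type} sample must "
                    f"have {want} at position {CENTER_POS}, found {got}"
                )

    @property
    def center_base(self) -> str:
        return self.sequence[CENTER_POS - 1]


@dataclass(frozen=True)
class ProcessedSentence:
    """Textual form of a sample: 36 six-mer words + templated lineage clause."""

    text: str
    source_id: str = ""


@dataclass
class MethylDataset:
    """A collection of samples with unique ids."""

    samples: List[MethylSample]
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValueError(f"duplicate sample ids: {sorted(dups)[:5]}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[MethylSample]:
        return iter(self.samples)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])


@dataclass
class Corpus:
    """Pretraining corpus: one sentence per line, order-preserving."""

    sentences: List[str]
    vocab_size_target: int = 25_000
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not s for s in self.sentences):
            raise ValueError("corpus contains an empty sentence")
        self.metadata.setdefault("n_sentences", len(self.sentences))

    def __len__(self) -> int:
        return len(self.sentences)


# ---------------------------------------------------------------------------
# Sentence encoding

def extract_kmers(sequence: str, k: int) -> List[str]:
    """All contiguous k-mers of ``sequence``, left to right.

    A sequence of length L yields exactly L - k + 1 k-mers.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    seq = sequence.upper()
    if not set(seq) <= _DNA_N:
        bad = sorted(set(seq) - _DNA_N)
        raise ValueError(f"invalid characters in sequence: {bad}")
    if len(seq) < k:
        raise ValueError(
            f"sequence length {len(seq)} is shorter than k-mer size {k}"
        )
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


LINEAGE_TEMPLATE = (
    "For this organism, its species is {species}, its genus is {genus}, "
    "its family is {family}, its order is {order}, its class is {class_}, "
    "its phylum is {phylum}, its kingdom is {kingdom}, its domain is {domain}."
)


def lineage_sentence(lineage: TaxonomicLineage) -> str:
    """Render the lineage as the fixed English template sentence."""
    return LINEAGE_TEMPLATE.format(
        species=lineage.species,
        genus=lineage.genus,
        family=lineage.family,
        order=lineage.order,
        class_=lineage.class_,
        phylum=lineage.phylum,
        kingdom=lineage.kingdom,
        domain=lineage.domain,
    )


def parse_lineage_sentence(text: str) -> Optional[TaxonomicLineage]:
    """Inverse of :func:`lineage_sentence`; returns None if no match.

    Case-insensitive so it works on lowercased (tokenizer-side) text.
    """
    import re

    pattern = (
        r"for this organism, its species is (?P<species>.+?), "
        r"its genus is (?P<genus>.+?), its family is (?P<family>.+?), "
        r"its order is (?P<order>.+?), its class is (?P<class_>.+?), "
        r"its phylum is (?P<phylum>.+?), its kingdom is (?P<kingdom>.+?), "
        r"its domain is (?P<domain>.+?)\.\s*$"
    )
    m = re.search(pattern, text, flags=re.IGNORECASE)
    if m is None:
        return None
    return TaxonomicLineage(**{k: v.strip() for k, v in m.groupdict().items()})


def build_sentence(sample: MethylSample) -> ProcessedSentence:
    """Render a sample as "36 six-mer words" + lineage clause.

    Sequences containing N are rejected here (the 6-mer vocabulary is
    defined over A/C/G/T only) even though they are accepted at parse time.
    """
    if "N" in sample.sequence:
        raise ValueError(
            f"sample {sample.id!r}: sequence contains N; cannot encode as 6-mer words"
        )
    kmers = extract_kmers(sample.sequence, KMER_SIZE)
    text = " ".join(kmers) + " " + lineage_sentence(sample.lineage)
    return ProcessedSentence(text=text, source_id=sample.id)


# ---------------------------------------------------------------------------
# Splitting

def split_by_type(dataset: MethylDataset) -> Dict[str, MethylDataset]:
    """Partition a dataset into the three methylation types."""
    parts: Dict[str, List[MethylSample]] = {t: [] for t in METHYL_TYPES}
    for s in dataset:
        parts[s.methyl_type].append(s)
    return {
        t: MethylDataset(samples, metadata={"methyl_type": t})
        for t, samples in parts.items()
    }


def train_val_split(
    dataset: MethylDataset, ratio: float = 0.8, seed: int = 0
) -> Tuple[MethylDataset, MethylDataset]:
    """Stratified train/validation split.

    The training part has exactly ceil(ratio * n) samples overall, and each
    label class is represented within +/- 1 sample of its exact proportional
    share.  Reproducible for a fixed seed.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    n_train = math.ceil(ratio * n)

    rng = np.random.default_rng(seed)
    by_class: Dict[object, List[int]] = {}
    for i, s in enumerate(dataset.samples):
        by_class.setdefault(s.label, []).append(i)

    # per-class floor allocation, remainder to the largest fractional parts
    classes = sorted(by_class, key=lambda c: str(c))
    base = {c: math.floor(ratio * len(by_class[c])) for c in classes}
    frac = {c: ratio * len(by_class[c]) - base[c] for c in classes}
    remainder = n_train - sum(base.values())
    for c in sorted(classes, key=lambda c: (-frac[c], str(c))):
        if remainder <= 0:
            break
        if base[c] < len(by_class[c]):
            base[c] += 1
            remainder -= 1

    train_idx: List[int] = []
    val_idx: List[int] = []
    for c in classes:
        idx = np.array(by_class[c])
        rng.shuffle(idx)
        train_idx.extend(idx[: base[c]].tolist())
        val_idx.extend(idx[base[c] :].tolist())
    train_idx.sort()
    val_idx.sort()

    meta = dict(dataset.metadata)
    return (
        MethylDataset([dataset.samples[i] for i in train_idx], {**meta, "split": "train"}),
        MethylDataset([dataset.samples[i] for i in val_idx], {**meta, "split": "val"}),
    )


# ---------------------------------------------------------------------------
# Corpus assembly

def build_corpus(
    processed_training: MethylDataset,
    extra_lineages: Sequence[TaxonomicLineage] = (),
    vocab_size_target: int = 25_000,
) -> Corpus:
    """Assemble the pretraining corpus.

    The corpus is every processed training sentence (in dataset order),
    plus one lineage sentence per extra lineage whose 8-rank tuple does not
    already occur among the training samples.  Deduplication is by exact
    8-tuple; sentence-level deduplication is deliberately not performed.
    """
    sentences = [build_sentence(s).text for s in processed_training]
    seen = {s.lineage.as_tuple() for s in processed_training}
    n_novel = 0
    for lin in extra_lineages:
        key = lin.as_tuple()
        if key in seen:
            continue
        seen.add(key)
        sentences.append(lineage_sentence(lin))
        n_novel += 1
    return Corpus(
        sentences,
        vocab_size_target=vocab_size_target,
        metadata={
            "n_sentences": len(sentences),
            "n_training_sentences": len(processed_training),
            "n_extra_lineages": n_novel,
        },
    )


# ---------------------------------------------------------------------------
# TSV / text I/O

_LABEL_STR = {1: "positive", 0: "negative", None: "unknown"}
_STR_LABEL = {"positive": 1, "negative": 0, "1": 1, "0": 0, "unknown": None}

SAMPLE_COLUMNS = ["id", "sequence", "label", "methyl_type"] + list(RANKS)


def write_samples_tsv(dataset: MethylDataset, path) -> None:
    rows = []
    for s in dataset:
        row = {
            "id": s.id,
            "sequence": s.sequence,
            "label": _LABEL_STR[s.label],
            "methyl_type": s.methyl_type,
        }
        for rank in RANKS:
            row[rank] = s.lineage.name_for(rank)
        rows.append(row)
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> MethylDataset:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNKNOWN_RANK)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} is missing columns {missing}")
    samples = []
    for _, row in df.iterrows():
        lineage = TaxonomicLineage.from_dict({r: row[r] for r in RANKS})
        label = _STR_LABEL.get(str(row["label"]).lower())
        samples.append(
            MethylSample(
                id=str(row["id"]),
                sequence=str(row["sequence"]),
                label=label,
                methyl_type=str(row["methyl_type"]),
                lineage=lineage,
            )
        )
    return MethylDataset(samples, metadata={"source": str(path)})


def read_lineages_tsv(path) -> List[TaxonomicLineage]:
    """Read a lineage list: TSV with the 8 rank columns (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNKNOWN_RANK)
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValueError(f"lineage table {path} is missing rank columns {missing}")
    return [
        TaxonomicLineage.from_dict({r: row[r] for r in RANKS})
        for _, row in df.iterrows()
    ]


def write_corpus(corpus: Corpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in corpus.sentences:
            fh.write(s + "\n")


def read_corpus(path, vocab_size_target: int = 25_000) -> Corpus:
    with open(path, encoding="utf-8") as fh:
        sentences = [line.rstrip("\n") for line in fh if line.strip()]
    return Corpus(sentences, vocab_size_target=vocab_size_target)
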