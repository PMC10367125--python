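"""Synthetic labelled datasets and chromosomes with planted motifs.

The generator emulates the structure of the public 41-nt methylation
benchmarks: balanced positive/negative windows, positives centered on a
methylatable base (A for 6mA, C for 4mC/5hmC) and carrying a plantable
6-mer motif overlapping the center, every sample tagged with an 8-rank
taxonomic lineage.  Background composition is uniform over A/C/G/T.

Negatives also have the target base forced at the center — the class
signal is the motif, not the center base — and are rejection-sampled so
they never contain the exact consensus.  Degenerate (substituted) matches
are deliberately allowed in negatives to keep the task honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data_model import (
    CENTER_POS,
    KMER_SIZE,
    TARGET_BASE,
    WINDOW_LENGTH,
    MethylDataset,
    MethylSample,
    TaxonomicLineage,
)

BASES = np.array(list("ACGT"))

#: default planted motifs; each contains the target base at several offsets
#: so positives show positional variety while keeping the consensus intact
DEFAULT_MOTIFS = {
    "6mA": "AGACAT",
    "4mC": "TCCGCA",
    "5hmC": "TCCGCA",
}

#: a small set of built-in lineages for round-robin tagging
DEFAULT_LINEAGES = (
    TaxonomicLineage("Homo sapiens", "Homo", "Hominidae", "Primates",
                     "Mammalia", "Chordata", "Metazoa", "Eukaryota"),
    TaxonomicLineage("Arabidopsis thaliana", "Arabidopsis", "Brassicaceae",
                     "Brassicales", "Magnoliopsida", "Streptophyta",
                     "Viridiplantae", "Eukaryota"),
    TaxonomicLineage("Escherichia coli", "Escherichia", "Enterobacteriaceae",
                     "Enterobacterales", "Gammaproteobacteria",
                     "Pseudomonadota", "unknown", "Bacteria"),
)


@dataclass(frozen=True)
class MotifSpec:
    """A plantable consensus 6-mer with optional per-position noise.

    ``offset_choices`` are the 0-based window offsets at which the motif
    may start; when None they are derived so that a consensus position
    holding the target base lands exactly on the window center, which
    keeps the planted consensus intact after the center base is forced.
    """

    consensus: str
    substitution_prob: float = 0.0
    offset_choices: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not set(self.consensus.upper()) <= set("ACGT"):
            raise ValueError(f"consensus {self.consensus!r} must be over ACGT")
        object.__setattr__(self, "consensus", self.consensus.upper())
        if not 0.0 <= self.substitution_prob < 1.0:
            raise ValueError("substitution_prob must be in [0, 1)")
        if len(self.consensus) > WINDOW_LENGTH:
            raise ValueError(
                f"motif length {len(self.consensus)} exceeds window {WINDOW_LENGTH}"
            )

    def center_offsets(self, methyl_type: str) -> Tuple[int, ...]:
        """Offsets placing a target-base consensus position at the center."""
        if self.offset_choices is not None:
            return self.offset_choices
        target = TARGET_BASE[methyl_type]
        center0 = CENTER_POS - 1
        offsets = tuple(
            center0 - i
            for i, base in enumerate(self.consensus)
            if base == target and 0 <= center0 - i <= WINDOW_LENGTH - len(self.consensus)
        )
        if not offsets:
            raise ValueError(
                f"consensus {self.consensus!r} has no {target} position that "
                f"can coincide with the window center"
            )
        return offsets


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset or chromosome."""

    motif: MotifSpec
    methyl_type: str
    seed: int
    site_positions: Dict[str, List[int]] = field(default_factory=dict)
    motif_offsets: Dict[str, int] = field(default_factory=dict)  # sample id -> offset
    params: Dict[str, object] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def _plant_motif(
    window: np.ndarray, motif: MotifSpec, offset: int, rng: np.random.Generator
) -> None:
    for i, base in enumerate(motif.consensus):
        if motif.substitution_prob and rng.random() < motif.substitution_prob:
            alt = [b for b in "ACGT" if b != base]
            window[offset + i] = alt[rng.integers(0, 3)]
        else:
            window[offset + i] = base


def _positive_window(
    methyl_type: str, motif: MotifSpec, rng: np.random.Generator
) -> Tuple[str, int]:
    offsets = motif.center_offsets(methyl_type)
    offset = int(offsets[rng.integers(0, len(offsets))])
    window = _random_seq(rng, WINDOW_LENGTH)
    _plant_motif(window, motif, offset, rng)
    window[CENTER_POS - 1] = TARGET_BASE[methyl_type]
    return "".join(window), offset


def _negative_window(
    methyl_type: str, motif: MotifSpec, rng: np.random.Generator,
    max_tries: int = 1000,
) -> str:
    for _ in range(max_tries):
        window = _random_seq(rng, WINDOW_LENGTH)
        window[CENTER_POS - 1] = TARGET_BASE[methyl_type]
        seq = "".join(window)
        if motif.consensus not in seq:
            return seq
    raise RuntimeError("could not sample a consensus-free negative window")


def generate_dataset(
    n_pos: int,
    n_neg: int,
    methyl_type: str,
    motif: Optional[MotifSpec] = None,
    lineages: Optional[Sequence[TaxonomicLineage]] = None,
    seed: int = 0,
    id_prefix: str = "",
) -> Tuple[MethylDataset, SyntheticTruth]:
    """Generate a balanced-by-construction labelled dataset.

    Positives are uniform-random 41-mers with the motif written at an
    offset overlapping the center and the center base forced to the
    target; negatives are uniform-random 41-mers with the target center
    base, rejection-sampled to exclude the exact consensus.  Lineages are
    assigned round-robin.  Byte-identical output for a fixed seed.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be non-negative")
    if motif is None:
        motif = MotifSpec(DEFAULT_MOTIFS[methyl_type])
    if lineages is None or not lineages:
        lineages = DEFAULT_LINEAGES
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        motif=motif, methyl_type=methyl_type, seed=seed,
        params={"n_pos": n_pos, "n_neg": n_neg},
    )

    samples: List[MethylSample] = []
    for i in range(n_pos):
        seq, offset = _positive_window(methyl_type, motif, rng)
        sid = f"{id_prefix}pos_{i:05d}"
        truth.motif_offsets[sid] = offset
        samples.append(
            MethylSample(id=sid, sequence=seq, label=1, methyl_type=methyl_type,
                         lineage=lineages[i % len(lineages)])
        )
    for i in range(n_neg):
        seq = _negative_window(methyl_type, motif, rng)
        samples.append(
            MethylSample(id=f"{id_prefix}neg_{i:05d}", sequence=seq, label=0,
                         methyl_type=methyl_type,
                         lineage=lineages[i % len(lineages)])
        )
    return MethylDataset(samples, metadata={"synthetic": True, "seed": seed}), truth


def generate_genome(
    length: int,
    n_sites: int,
    methyl_type: str,
    motif: Optional[MotifSpec] = None,
    seed: int = 0,
    contig: str = "chr_synth",
    min_spacing: int = WINDOW_LENGTH,
) -> Tuple[str, SyntheticTruth]:
    """A random chromosome with motif-bearing 41-nt segments planted.

    Site centers lie in [21, length-20] with pairwise spacing of at least
    ``min_spacing``; true centers are recorded in the returned truth.
    """
    if motif is None:
        motif = MotifSpec(DEFAULT_MOTIFS[methyl_type])
    if length < WINDOW_LENGTH and n_sites > 0:
        raise ValueError(f"length {length} cannot hold any {WINDOW_LENGTH}-nt window")
    rng = np.random.default_rng(seed)

    lo, hi = CENTER_POS, length - (CENTER_POS - 1)
    if n_sites > 0 and (hi - lo + 1) < n_sites * min_spacing - (min_spacing - 1):
        raise ValueError(
            f"cannot place {n_sites} sites with spacing {min_spacing} "
            f"in a sequence of length {length}"
        )

    centers: List[int] = []
    max_tries = 10000
    tries = 0
    while len(centers) < n_sites:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"failed to place {n_sites} non-overlapping sites in length {length}"
            )
        c = int(rng.integers(lo, hi + 1))
        if all(abs(c - c0) >= min_spacing for c0 in centers):
            centers.append(c)
    centers.sort()

    seq = _random_seq(rng, length)
    truth = SyntheticTruth(
        motif=motif, methyl_type=methyl_type, seed=seed,
        site_positions={contig: centers},
        params={"length": length, "n_sites": n_sites},
    )
    for c in centers:
        window, offset = _positive_window(methyl_type, motif, rng)
        start = c - CENTER_POS  # 0-based window start
        seq[start : start + WINDOW_LENGTH] = list(window)
        truth.motif_offsets[f"{contig}:{c}"] = offset
    return "".join(seq), truth


def write_fasta(sequence: str, path, contig: str = "chr_synth") -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


def write_truth_bed(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        for contig, centers in truth.site_positions.items():
            for c in centers:
                fh.write(f"{contig}\t{c - 1}\t{c}\tplanted_site\n")
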