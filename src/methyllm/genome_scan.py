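"""Whole-sequence methylation-site calling.

Candidate 41-nt windows are extracted around every occurrence of the
target base (A for 6mA, C for 4mC/5hmC) whose full window fits inside the
contig.  The ensemble scores each window; windows at or above the decision
threshold are then filtered by importance analysis: a call is retained
only when the attention-derived 41-position importance profile attains its
maximum at the window center.  This center-max filter resolves overlapping
predictions along the sequence.

Only the given strand is scanned by default; ``both_strands=True`` also
scans the reverse complement and reports the strand of each call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CENTER_POS,
    TARGET_BASE,
    WINDOW_LENGTH,
    MethylSample,
    TaxonomicLineage,
)
from .ensemble_eval import EnsembleModel, ensemble_predict
from .interpretability import importance_profile
from .tokenization import WORDPIECE_FAMILIES

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CandidateWindow:
    """A 41-nt window centered (1-based) on a target base of a contig."""

    contig: str
    position: int  # 1-based center position on the contig
    sequence: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"window at {self.contig}:{self.position} has length "
                f"{len(self.sequence)} != {WINDOW_LENGTH}"
            )

    @property
    def center_base(self) -> str:
        return self.sequence[CENTER_POS - 1]


@dataclass(frozen=True)
class SiteCall:
    """A predicted methylation site with its filter status."""

    contig: str
    position: int  # 1-based
    probability: float
    retained: bool
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")


def extract_windows(
    sequence: str, methyl_type: str, contig: str = "seq", strand: str = "+"
) -> List[CandidateWindow]:
    """All 41-nt windows centered on the target base.

    Valid centers are positions 21..L-20 (1-based); windows containing a
    non-ACGT character are skipped (the skip count is logged).
    """
    target = TARGET_BASE[methyl_type]
    seq = sequence.upper()
    if len(seq) < WINDOW_LENGTH:
        warnings.warn(
            f"{contig}: sequence length {len(seq)} < {WINDOW_LENGTH}; no windows"
        )
        return []
    windows: List[CandidateWindow] = []
    n_skipped = 0
    half = CENTER_POS - 1  # 20
    for center in range(CENTER_POS, len(seq) - half + 1):
        if seq[center - 1] != target:
            continue
        win = seq[center - CENTER_POS : center + half]
        if set(win) - set("ACGT"):
            n_skipped += 1
            continue
        windows.append(
            CandidateWindow(contig=contig, position=center, sequence=win, strand=strand)
        )
    if n_skipped:
        logger.info("%s: skipped %d windows containing non-ACGT characters",
                    contig, n_skipped)
    return windows


def _windows_to_samples(
    windows: Sequence[CandidateWindow],
    lineage: TaxonomicLineage,
    methyl_type: str,
) -> List[MethylSample]:
    return [
        MethylSample(
            id=f"{w.contig}:{w.position}:{w.strand}",
            sequence=w.sequence,
            label=None,
            methyl_type=methyl_type,
            lineage=lineage,
        )
        for w in windows
    ]


def scan(
    sequence: str,
    lineage: TaxonomicLineage,
    methyl_type: str,
    ensemble: EnsembleModel,
    importance_models: Optional[Sequence] = None,
    contig: str = "seq",
    strict_center: bool = False,
    both_strands: bool = False,
    center_tol: float = 1e-12,
) -> List[SiteCall]:
    """Scan a sequence: ensemble prediction then the center-max filter.

    Step 1: score every candidate window and keep those with probability
    >= the ensemble threshold.  Step 2: compute each kept window's
    41-position importance profile (averaged over the word-wise submodels)
    and flag it retained when the center position attains the profile
    maximum (ties retain by default; ``strict_center`` requires a unique
    maximum).  All threshold-passing calls are returned with their flags.
    """
    if importance_models is None:
        importance_models = [
            m for fam, m in sorted(ensemble.members.items())
            if fam in WORDPIECE_FAMILIES
        ]
        if not importance_models:
            raise ValueError(
                "no word-wise (WordPiece-family) members available for the "
                "importance filter; pass importance_models explicitly"
            )

    strands = ["+"]
    seqs = {"+": sequence.upper()}
    if both_strands:
        strands.append("-")
        seqs["-"] = reverse_complement(sequence)

    calls: List[SiteCall] = []
    for strand in strands:
        seq = seqs[strand]
        windows = extract_windows(seq, methyl_type, contig=contig, strand=strand)
        if not windows:
            continue
        samples = _windows_to_samples(windows, lineage, methyl_type)
        probs = ensemble_predict(ensemble, samples)
        for w, s, p in zip(windows, samples, probs):
            if not p >= ensemble.threshold:
                continue
            _, profile, _ = importance_profile(importance_models, s)
            center_score = profile[CENTER_POS - 1]
            peak = profile.max()
            if strict_center:
                at_max = np.sum(profile >= peak - center_tol) == 1 and (
                    center_score >= peak - center_tol
                )
            else:
                at_max = center_score >= peak - center_tol
            position = w.position
            if strand == "-":
                # map back to forward-strand coordinates
                position = len(sequence) - w.position + 1
            calls.append(
                SiteCall(contig=contig, position=position, probability=float(p),
                         retained=bool(at_max), strand=strand)
            )
    calls.sort(key=lambda c: (c.contig, c.position, c.strand))
    return calls


SITE_COLUMNS = ["contig", "position", "strand", "probability", "retained"]


def write_sites(calls: Sequence[SiteCall], path, format: str = "tsv") -> None:
    """Write calls as TSV (1-based) or BED (0-based half-open, single base)."""
    if format == "tsv":
        pd.DataFrame(
            [
                {
                    "contig": c.contig,
                    "position": c.position,
                    "strand": c.strand,
                    "probability": c.probability,
                    "retained": c.retained,
                }
                for c in calls
            ],
            columns=SITE_COLUMNS,
        ).to_csv(path, sep="\t", index=False)
    elif format == "bed":
        with open(path, "w") as fh:
            for c in calls:
                fh.write(
                    f"{c.contig}\t{c.position - 1}\t{c.position}\t"
                    f"methyl_site\t{c.probability:.6f}\t{c.strand}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'bed'")


def read_sites_tsv(path) -> List[SiteCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        SiteCall(
            contig=str(row["contig"]),
            position=int(row["position"]),
            probability=float(row["probability"]),
            retained=bool(row["retained"]),
            strand=str(row["strand"]),
        )
        for _, row in df.iterrows()
    ]
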