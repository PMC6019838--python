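"""Coding-potential scoring and the three-scorer noncoding consensus.

Candidate lincRNAs must lack coding capacity. Three independent signals are
scored per transcript — longest open reading frame, the Fickett TESTCODE
statistic, and a hexamer-usage log-likelihood ratio — each thresholded into
a coding/noncoding label, and a transcript is accepted as noncoding only by
consensus of all three (the intersection rule; a discard-only-if-all-coding
variant is available).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CodingPotentialReport",
    "HexamerTable",
    "longest_orf",
    "fickett_score",
    "train_hexamer_table",
    "hexamer_llr",
    "consensus_call",
    "score_transcript",
    "score_transcripts",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

# Fickett (1982) TESTCODE lookup tables. For each base, the position
# parameter is the max over the three codon phases of that base's count
# divided by (min count + 1); the content parameter is the base's fraction
# of the sequence. Each parameter maps through decreasing thresholds to a
# coding probability, and the eight probabilities combine with fixed weights.
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_EDGES = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


@dataclass(frozen=True)
class CodingPotentialReport:
    """Per-transcript scores, per-scorer labels and the consensus decision."""

    transcript_id: str
    orf_length: int
    orf_coverage: float
    fickett_score: float
    hexamer_llr: float
    orf_label: str
    fickett_label: str
    hexamer_label: str
    consensus_noncoding: bool

    @property
    def per_scorer_labels(self) -> tuple[str, str, str]:
        return (self.orf_label, self.fickett_label, self.hexamer_label)


@dataclass(frozen=True)
class HexamerTable:
    """Hexamer frequency tables for coding and noncoding training sets."""

    coding: Mapping[str, float]
    noncoding: Mapping[str, float]
    pseudocount: float


def longest_orf(sequence: str) -> tuple[int, int]:
    """Longest ATG→stop ORF over the three forward frames.

    Returns 1-based start position and ORF length in nt (stop codon
    included; length is a multiple of 3). ``(0, 0)`` if the sequence holds
    no complete ORF or is shorter than 6 nt. Ties break to the smallest
    start position.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 6:
        return (0, 0)
    best_start, best_len = 0, 0
    for frame in range(3):
        orf_start = None  # 0-based index of the pending ATG
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if orf_start is None:
                if codon == "ATG":
                    orf_start = i
            elif codon in STOP_CODONS:
                length = i + 3 - orf_start
                if length > best_len or (length == best_len and orf_start + 1 < best_start):
                    best_start, best_len = orf_start + 1, length
                orf_start = None
    return (best_start, best_len)


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE coding-potential statistic (higher = coding-like).

    Published interpretation: > 0.95 coding, < 0.74 noncoding. Requires at
    least 50 nt; the discovery pipeline guarantees >= 200.
    """
    seq = sequence.upper()
    if len(seq) < 50:
        raise ValueError(f"TESTCODE undefined below 50 nt (got {len(seq)})")
    total = 0.0
    n = len(seq)
    for base in "ACGT":
        phase_counts = [seq[p::3].count(base) for p in range(3)]
        position = max(phase_counts) / (min(phase_counts) + 1)
        content = seq.count(base) / n
        pos_idx = next(i for i, edge in enumerate(_POSITION_EDGES) if position >= edge)
        con_idx = next(i for i, edge in enumerate(_CONTENT_EDGES) if content >= edge)
        total += _POSITION_PROB[base][pos_idx] * _POSITION_WEIGHT[base]
        total += _CONTENT_PROB[base][con_idx] * _CONTENT_WEIGHT[base]
    return total


def _count_hexamers(seqs: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - 5):
            hexamer = seq[i : i + 6]
            if "N" in hexamer:
                continue
            counts[hexamer] = counts.get(hexamer, 0) + 1
    return counts


def train_hexamer_table(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Train hexamer frequency tables from two sets of sequences.

    All overlapping (step-1) hexamers are counted, N-containing windows
    skipped, a pseudocount added over the full 4**6 alphabet, and each table
    normalized to sum to 1.
    """
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training sets must be non-empty")
    all_hexamers = ["".join(k) for k in itertools.product("ACGT", repeat=6)]
    tables = []
    for seqs in (coding_seqs, noncoding_seqs):
        counts = _count_hexamers(seqs)
        total = sum(counts.values()) + pseudocount * len(all_hexamers)
        tables.append({h: (counts.get(h, 0) + pseudocount) / total for h in all_hexamers})
    return HexamerTable(coding=tables[0], noncoding=tables[1], pseudocount=pseudocount)


def hexamer_llr(sequence: str, table: HexamerTable) -> float:
    """Mean log2(coding/noncoding) frequency ratio over all hexamer windows.

    Positive values are coding-like. N-containing windows are skipped; a
    sequence with no valid window is an error.
    """
    seq = sequence.upper()
    ratios = []
    for i in range(len(seq) - 5):
        hexamer = seq[i : i + 6]
        if "N" in hexamer:
            continue
        ratios.append(math.log2(table.coding[hexamer] / table.noncoding[hexamer]))
    if not ratios:
        raise ValueError("no valid hexamer window in sequence")
    return sum(ratios) / len(ratios)


def consensus_call(
    transcript_id: str,
    orf_length: int,
    orf_coverage: float,
    fickett: float,
    llr: float,
    min_orf_length: int = 300,
    min_orf_coverage: float = 0.5,
    fickett_cutoff: float = 0.95,
    llr_cutoff: float = 0.0,
    rule: str = "all_noncoding",
) -> CodingPotentialReport:
    """Combine the three scores into per-scorer labels and a consensus.

    Scorer labels: ORF scorer is coding iff ``orf_length >= min_orf_length``
    or ``orf_coverage >= min_orf_coverage``; Fickett scorer coding iff score
    ``>= fickett_cutoff``; hexamer scorer coding iff LLR ``> llr_cutoff``.

    ``rule="all_noncoding"`` (default) accepts a transcript as noncoding only
    when all three scorers agree it is noncoding; ``rule="not_all_coding"``
    rejects only transcripts called coding by all three.
    """
    orf_label = (
        "coding"
        if (orf_length >= min_orf_length or orf_coverage >= min_orf_coverage)
        else "noncoding"
    )
    fickett_label = "coding" if fickett >= fickett_cutoff else "noncoding"
    hexamer_label = "coding" if llr > llr_cutoff else "noncoding"
    labels = (orf_label, fickett_label, hexamer_label)
    if rule == "all_noncoding":
        consensus = all(lab == "noncoding" for lab in labels)
    elif rule == "not_all_coding":
        consensus = not all(lab == "coding" for lab in labels)
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")
    return CodingPotentialReport(
        transcript_id=transcript_id,
        orf_length=orf_length,
        orf_coverage=orf_coverage,
        fickett_score=fickett,
        hexamer_llr=llr,
        orf_label=orf_label,
        fickett_label=fickett_label,
        hexamer_label=hexamer_label,
        consensus_noncoding=consensus,
    )


def score_transcript(
    transcript_id: str, sequence: str, table: HexamerTable, **thresholds
) -> CodingPotentialReport:
    """Compute all three scores for one sequence and call the consensus."""
    _start, orf_len = longest_orf(sequence)
    coverage = orf_len / len(sequence) if sequence else 0.0
    return consensus_call(
        transcript_id,
        orf_len,
        coverage,
        fickett_score(sequence),
        hexamer_llr(sequence, table),
        **thresholds,
    )


def score_transcripts(
    sequences: Mapping[str, str], table: HexamerTable, **thresholds
) -> dict[str, CodingPotentialReport]:
    return {
        tid: score_transcript(tid, seq, table, **thresholds)
        for tid, seq in sequences.items()
    }
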