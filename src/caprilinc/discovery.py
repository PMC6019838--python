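"""Candidate classification against a reference annotation and the lincRNA
filter cascade.

The cascade retains, in order: intergenic ('u') transcripts, multi-exon
transcripts, transcripts reliably expressed (FPKM >= 0.5), transcripts at
least 500 bp from any protein-coding gene, transcripts of spliced length
>= 200 bp, and transcripts called noncoding by the three-scorer consensus.
Each stage's input/removed/output counts are recorded in an audit trail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, TranscriptModel
from .codpot import CodingPotentialReport

__all__ = [
    "ClassifiedTranscript",
    "FilterAudit",
    "classify_vs_reference",
    "merge_transcripts",
    "apply_filter_cascade",
    "feature_stats",
    "FeatureStats",
]

logger = logging.getLogger(__name__)

NEAR_THRESHOLD = 500  # bp: intergenic transcripts must be at least this far


@dataclass(frozen=True)
class ClassifiedTranscript:
    """A candidate with its positional class relative to the reference.

    ``class_code``: 'u' intergenic (>= 500 bp from any coding gene), 'near'
    intergenic but < 500 bp away, 'i' intronic, 'o' exonic overlap.
    ``distance_to_nearest_coding`` is the bp gap to the nearest coding gene
    span (0 when overlapping, +inf when the chromosome holds no reference
    gene).
    """

    transcript: TranscriptModel
    class_code: str
    distance_to_nearest_coding: float


@dataclass
class FilterAudit:
    """Ordered per-stage (name, n_in, n_removed, n_out) records."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if self.stages and self.stages[-1][3] != n_in:
            raise ValueError("audit stages do not chain")
        self.stages.append((name, n_in, n_in - n_out, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_removed", "n_out"])

    def removed(self, stage: str) -> int:
        for name, _n_in, n_removed, _n_out in self.stages:
            if name == stage:
                return n_removed
        raise KeyError(stage)


def _span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """bp gap between two 1-based inclusive intervals; 0 if they overlap."""
    if a[0] <= b[1] and b[0] <= a[1]:
        return 0
    return b[0] - a[1] - 1 if b[0] > a[1] else a[0] - b[1] - 1


def classify_vs_reference(
    candidates: AnnotationSet, reference: AnnotationSet
) -> list[ClassifiedTranscript]:
    """Assign each candidate a positional class code vs the reference genes.

    Overlap ('o') means any candidate exon shares >= 1 bp with any reference
    exon, on either strand — "intergenic" is positional, so strand is
    ignored. Intronic ('i') candidates sit inside a reference gene span with
    no exon overlap. 'near' candidates overlap nothing but lie < 500 bp
    from a gene span; everything else is 'u'. A candidate on a chromosome
    absent from the reference is 'u' with infinite distance (warned).
    """
    gene_spans = reference.gene_spans()
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _gid, (chrom, s, e) in gene_spans.items():
        spans_by_chrom.setdefault(chrom, []).append((s, e))

    out = []
    for tx in candidates:
        if tx.chrom not in reference.chromosomes:
            logger.warning(
                "candidate %s on chromosome %s absent from reference",
                tx.transcript_id, tx.chrom,
            )
            out.append(ClassifiedTranscript(tx, "u", math.inf))
            continue
        tree = reference.exon_tree(tx.chrom)
        exonic_overlap = any(tree.overlap(s, e + 1) for s, e in tx.exons)
        span = tx.span
        distance = min(
            (_span_gap(span, g) for g in spans_by_chrom.get(tx.chrom, [])),
            default=math.inf,
        )
        if exonic_overlap:
            out.append(ClassifiedTranscript(tx, "o", 0))
        elif distance == 0:
            # inside a gene span but clear of every exon: intronic
            out.append(ClassifiedTranscript(tx, "i", 0))
        elif distance < NEAR_THRESHOLD:
            out.append(ClassifiedTranscript(tx, "near", distance))
        else:
            out.append(ClassifiedTranscript(tx, "u", distance))
    return out


def merge_transcripts(per_sample_sets: Sequence[AnnotationSet]) -> AnnotationSet:
    """Collapse per-sample assemblies into one non-redundant annotation.

    Transcripts with identical intron chains (identical exon chains for
    single-exon transcripts) collapse to one representative — the member
    with the longest spliced length, ties broken by transcript id. Same-
    strand transcripts whose exons overlap by >= 1 bp group into one gene.
    Gene/transcript ids are reassigned deterministically by genomic order.
    """
    # group duplicates by structure key
    by_key: dict[tuple, list[TranscriptModel]] = {}
    for aset in per_sample_sets:
        for tx in aset:
            if tx.n_exons == 1:
                key = (tx.chrom, tx.strand, "exons", tx.exons)
            else:
                key = (tx.chrom, tx.strand, "introns", tx.introns)
            by_key.setdefault(key, []).append(tx)
    reps = [
        max(group, key=lambda t: (t.spliced_length, t.transcript_id))
        for group in by_key.values()
    ]
    reps.sort(key=lambda t: (t.chrom, t.span[0], t.span[1], t.transcript_id))

    # union-find over same-strand exonic overlap
    parent = list(range(len(reps)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = reps[i], reps[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if b.span[0] > a.span[1]:
                break  # sorted by start: no later j can overlap a
            if any(
                s1 <= e2 and s2 <= e1
                for s1, e1 in a.exons
                for s2, e2 in b.exons
            ):
                union(i, j)

    roots: dict[int, int] = {}
    merged = AnnotationSet()
    for i, tx in enumerate(reps):
        root = find(i)
        if root not in roots:
            roots[root] = len(roots)
        gene_n = roots[root]
        merged.add(
            replace(
                tx,
                transcript_id=f"TCONS_{i:06d}",
                gene_id=f"XLOC_{gene_n:06d}",
            )
        )
    return merged


_STAGE_NAMES = (
    "class_u", "multi_exon", "min_fpkm", "distance", "length", "noncoding",
)


def apply_filter_cascade(
    candidates: Sequence[ClassifiedTranscript],
    expression: pd.DataFrame,
    coding_calls: Mapping[str, CodingPotentialReport],
    min_fpkm: float = 0.5,
    min_distance: int = 500,
    min_length: int = 200,
    fpkm_mode: str = "max",
    stage_order: Sequence[str] | None = None,
) -> tuple[AnnotationSet, FilterAudit]:
    """Run the ordered filter cascade and return the lincRNA catalogue.

    Survival rules (inclusive at each printed threshold): class 'u'; exon
    count >= 2; FPKM >= ``min_fpkm`` in at least one sample
    (``fpkm_mode="max"``) or in every sample (``fpkm_mode="all"``);
    distance to the nearest coding gene >= ``min_distance``; spliced length
    >= ``min_length``; consensus noncoding. Raises if a candidate lacks an
    expression row or a coding-potential report at the stage that needs it.

    ``stage_order`` may permute the stages after ``class_u`` (which always
    runs first); the final catalogue is order-invariant, the audit counts
    are not.
    """
    if fpkm_mode not in ("max", "all"):
        raise ValueError("fpkm_mode must be 'max' or 'all'")
    order = list(stage_order) if stage_order is not None else list(_STAGE_NAMES[1:])
    if sorted(order) != sorted(_STAGE_NAMES[1:]):
        raise ValueError(f"stage_order must permute {_STAGE_NAMES[1:]}")
    audit = FilterAudit()
    current = list(candidates)

    def stage(name: str, predicate) -> None:
        nonlocal current
        n_in = len(current)
        current = [c for c in current if predicate(c)]
        audit.record(name, n_in, len(current))
        logger.info("%s: %d -> %d", name, n_in, len(current))

    def fpkm_ok(c: ClassifiedTranscript) -> bool:
        tid = c.transcript.transcript_id
        if tid not in expression.index:
            raise KeyError(f"no expression row for transcript {tid}")
        values = expression.loc[tid]
        return (values.max() if fpkm_mode == "max" else values.min()) >= min_fpkm

    def noncoding_ok(c: ClassifiedTranscript) -> bool:
        tid = c.transcript.transcript_id
        if tid not in coding_calls:
            raise KeyError(f"no coding-potential report for transcript {tid}")
        return coding_calls[tid].consensus_noncoding

    predicates = {
        "multi_exon": lambda c: c.transcript.n_exons >= 2,
        "min_fpkm": fpkm_ok,
        "distance": lambda c: c.distance_to_nearest_coding >= min_distance,
        "length": lambda c: c.transcript.spliced_length >= min_length,
        "noncoding": noncoding_ok,
    }
    stage("class_u", lambda c: c.class_code == "u")
    for name in order:
        stage(name, predicates[name])

    lincs = AnnotationSet()
    for c in current:
        lincs.add(replace(c.transcript, biotype="lincRNA"))
    return lincs, audit


@dataclass(frozen=True)
class FeatureStats:
    """Catalogue summary statistics (gene-level and per-transcript)."""

    n_transcripts: int
    n_genes: int
    mean_exons_per_gene: float
    mean_exons_per_transcript: float
    mean_transcripts_per_gene: float
    mean_transcript_length: float
    exons_per_gene: tuple[int, ...]
    exons_per_transcript: tuple[int, ...]
    transcripts_per_gene: tuple[int, ...]
    transcript_lengths: tuple[int, ...]


def feature_stats(lincs: AnnotationSet) -> FeatureStats:
    """Summarize exon counts, transcripts per gene and spliced lengths.

    Exons per gene counts the distinct exonic intervals over all the gene's
    transcripts; the per-transcript exon count is also reported.
    """
    if len(lincs) == 0:
        raise ValueError("empty annotation set")
    gene_index = lincs.gene_index
    exons_per_gene = []
    transcripts_per_gene = []
    for gene_id, tids in sorted(gene_index.items()):
        distinct = {exon for tid in tids for exon in lincs[tid].exons}
        exons_per_gene.append(len(distinct))
        transcripts_per_gene.append(len(tids))
    exons_per_tx = [tx.n_exons for tx in lincs]
    lengths = [tx.spliced_length for tx in lincs]
    return FeatureStats(
        n_transcripts=len(lincs),
        n_genes=len(gene_index),
        mean_exons_per_gene=float(np.mean(exons_per_gene)),
        mean_exons_per_transcript=float(np.mean(exons_per_tx)),
        mean_transcripts_per_gene=float(np.mean(transcripts_per_gene)),
        mean_transcript_length=float(np.mean(lengths)),
        exons_per_gene=tuple(exons_per_gene),
        exons_per_transcript=tuple(exons_per_tx),
        transcripts_per_gene=tuple(transcripts_per_gene),
        transcript_lengths=tuple(lengths),
    )
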