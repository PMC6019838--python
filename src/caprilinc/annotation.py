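"""Transcript models, GTF/FASTA/BLAST-tabular I/O, and interval primitives.

Coordinates are 1-based inclusive throughout (GTF convention). A transcript
is an ordered chain of non-overlapping exon intervals on one strand of one
chromosome; a gene is a set of transcripts sharing a ``gene_id``.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "TranscriptModel",
    "AnnotationSet",
    "BlastHit",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "read_blast_tabular",
    "filter_blast_hits",
]

BIOTYPES = ("coding", "linc_candidate", "lincRNA", "other")


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an exon chain on a chromosome strand.

    ``exons`` are 1-based inclusive ``(start, end)`` intervals, sorted
    ascending and non-overlapping.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str = "."
    exons: tuple[tuple[int, int], ...] = ()
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        object.__setattr__(self, "exons", tuple((int(s), int(e)) for s, e in self.exons))
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon {start}-{end} has start > end"
                )
            if start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (1-based inclusive) between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )


@dataclass
class AnnotationSet:
    """A collection of transcripts with gene and per-chromosome interval indexes."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._exon_trees: dict[str, IntervalTree] | None = None

    def add(self, tx: TranscriptModel) -> None:
        if tx.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {tx.transcript_id!r}")
        self.transcripts[tx.transcript_id] = tx
        self._exon_trees = None

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.transcripts == other.transcripts

    @property
    def gene_index(self) -> dict[str, list[str]]:
        """gene_id -> sorted member transcript_ids."""
        idx: dict[str, list[str]] = defaultdict(list)
        for tx in self:
            idx[tx.gene_id].append(tx.transcript_id)
        return {g: sorted(ts) for g, ts in idx.items()}

    @property
    def chromosomes(self) -> set[str]:
        return {tx.chrom for tx in self}

    def gene_span(self, gene_id: str) -> tuple[str, int, int]:
        """(chrom, start, end) covering every transcript of the gene."""
        members = [self.transcripts[t] for t in self.gene_index[gene_id]]
        chroms = {m.chrom for m in members}
        if len(chroms) != 1:
            raise ValueError(f"gene {gene_id} spans multiple chromosomes")
        return (
            members[0].chrom,
            min(m.span[0] for m in members),
            max(m.span[1] for m in members),
        )

    def gene_spans(self) -> dict[str, tuple[str, int, int]]:
        return {g: self.gene_span(g) for g in self.gene_index}

    def exon_tree(self, chrom: str) -> IntervalTree:
        """Interval tree of exons on ``chrom``; data = (transcript_id, strand).

        Tree intervals are half-open ``[start, end+1)`` as intervaltree
        requires; queries must use the same convention.
        """
        if self._exon_trees is None:
            trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
            for tx in self:
                for s, e in tx.exons:
                    trees[tx.chrom].addi(s, e + 1, (tx.transcript_id, tx.strand))
            self._exon_trees = dict(trees)
        return self._exon_trees.get(chrom, IntervalTree())

    def subset(self, transcript_ids: Iterable[str]) -> "AnnotationSet":
        sub = AnnotationSet()
        for tid in transcript_ids:
            sub.add(self.transcripts[tid])
        return sub

    def with_biotype(self, biotype: str) -> "AnnotationSet":
        out = AnnotationSet()
        for tx in self:
            out.add(replace(tx, biotype=biotype))
        return out


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read a GTF file into an :class:`AnnotationSet`.

    Only ``exon`` feature rows contribute geometry; other feature types are
    ignored. Coordinates are kept 1-based inclusive. Besides plain GTF text
    the reader accepts a one-column row-per-line table export (each line one
    whole GTF row), as found in spreadsheet-wrapped supplementary tables.
    """
    path = Path(path)
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                # table export: whole GTF row in a single cell, internal
                # whitespace-separated; resplit on runs of whitespace into 9
                fields = line.split(None, 8)
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-numeric coordinates {start_s!r}/{end_s!r}"
                ) from None
            attrs = _parse_gtf_attributes(attr_s)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"{path.name}:{lineno}: missing transcript_id attribute")
            tid = attrs["transcript_id"]
            rec = per_tx.get(tid)
            if rec is None:
                rec = {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand if strand in ("+", "-") else ".",
                    "biotype": attrs.get("biotype", "other"),
                    "exons": [],
                }
                per_tx[tid] = rec
                order.append(tid)
            rec["exons"].append((start, end))
    out = AnnotationSet()
    for tid in order:
        rec = per_tx[tid]
        out.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                biotype=rec["biotype"],
            )
        )
    return out


def write_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    """Write one exon row per exon, deterministically ordered.

    Rows are sorted by (chrom, span start, transcript_id); attributes carry
    gene_id, transcript_id and biotype, so read/write round-trips.
    """
    txs = sorted(annotation, key=lambda t: (t.chrom, t.span[0], t.transcript_id))
    with open(path, "w") as fh:
        for tx in txs:
            for s, e in tx.exons:
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'biotype "{tx.biotype}";'
                )
                fh.write(
                    f"{tx.chrom}\tcaprilinc\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: uppercased sequence}``.

    The id is the first whitespace-delimited header token. Characters outside
    A/C/G/T/N raise a warning but are retained; duplicate ids are an error.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        if set(seq) - set("ACGTN"):
            warnings.warn(f"sequence {record.id}: characters outside ACGTN retained")
        seqs[record.id] = seq
    return seqs


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output (outfmt 6/7, standard 12 columns)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    evalue: float = 0.0
    bit_score: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length < 1")
        if self.mismatches < 0 or self.gap_opens < 0:
            raise ValueError("negative mismatch/gap count")


def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse BLAST tabular output (outfmt 6 or 7; '#' comment lines skipped)."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            hits.append(
                BlastHit(
                    query_id=f[0],
                    subject_id=f[1],
                    percent_identity=float(f[2]),
                    alignment_length=int(f[3]),
                    mismatches=int(f[4]),
                    gap_opens=int(f[5]),
                    evalue=float(f[10]) if len(f) > 10 else 0.0,
                    bit_score=float(f[11]) if len(f) > 11 else 0.0,
                )
            )
    return hits


def filter_blast_hits(
    hits: Sequence[BlastHit],
    max_mismatches: int = 3,
    min_identity: float = 98.0,
    max_gap_opens: int = 6,
    min_alignment_length: int = 200,
    length_on: str = "alignment",
    transcript_lengths: Mapping[str, int] | None = None,
) -> list[BlastHit]:
    """Keep hits passing the homology-comparison cutoffs.

    All four inequalities are strict: mismatches < ``max_mismatches``,
    identity > ``min_identity``, gap opens < ``max_gap_opens``, and length >
    ``min_alignment_length``. The length criterion applies to the alignment
    length by default; with ``length_on="transcript"`` it instead applies to
    the query transcript's length looked up in ``transcript_lengths``.
    """
    if length_on not in ("alignment", "transcript"):
        raise ValueError("length_on must be 'alignment' or 'transcript'")
    if length_on == "transcript" and transcript_lengths is None:
        raise ValueError("transcript_lengths required when length_on='transcript'")

    kept = []
    for h in hits:
        if length_on == "alignment":
            length = h.alignment_length
        else:
            length = transcript_lengths[h.query_id]
        if (
            h.mismatches < max_mismatches
            and h.percent_identity > min_identity
            and h.gap_opens < max_gap_opens
            and length > min_alignment_length
        ):
            kept.append(h)
    return kept
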