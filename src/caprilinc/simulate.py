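"""Synthetic annotations, sequences, expression and Ct tables with planted truth.

Every downstream stage of the pipeline (classification, filter cascade,
coding-potential consensus, tissue-specificity, HF enrichment, time-course
DE, clustering, neighbor co-expression, qPCR) is exercisable on data this
module generates, with ground-truth labels recording exactly what was
planted. The default configuration mirrors the study design the pipeline
targets: an eleven-tissue panel (ten organs plus hair follicle) and a
five-time-point skin series (May, Jun, Aug, Sep, Oct) with three biological
replicates, where temporal structure is concentrated at the May–June versus
August–October transition.

Expression is generated directly as FPKM. The noise model is additive
Gaussian on log2(FPKM+1), back-transformed and clamped at zero, matching
the transform used throughout the analysis modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, TranscriptModel, write_gtf

__all__ = [
    "SimConfig",
    "TruthLabels",
    "CLUSTER_TEMPLATES",
    "generate_annotation",
    "generate_expression",
    "generate_qpcr",
    "generate_time_course",
    "make_training_sets",
    "write_outputs",
]

TISSUES = (
    "lymph", "lung", "spleen", "kidney", "liver",
    "muscle", "heart", "brain", "bladder", "ovary", "HF",
)
TIME_POINTS = ("May", "Jun", "Aug", "Sep", "Oct")
BLOCK_EARLY = ("May", "Jun")
BLOCK_LATE = ("Aug", "Sep", "Oct")

CANDIDATE_CLASSES = (
    "intergenic_far", "intergenic_near", "exon_overlap",
    "intronic", "single_exon", "short",
)

# Shape templates (unit log2 offsets per time point) for the five planted
# co-expression clusters: three down-regulated across the season transition,
# two up-regulated, with distinct shapes so correlation distance separates
# them.
CLUSTER_TEMPLATES: dict[str, tuple[float, ...]] = {
    "K1": (1.0, 1.0, 0.0, 0.0, 0.0),  # high early, drop at the transition
    "K2": (1.0, 0.0, 0.0, 0.0, 0.0),  # early peak only
    "K3": (1.0, 1.0, 1.0, 0.0, 0.0),  # late decline
    "K4": (0.0, 0.0, 1.0, 1.0, 1.0),  # rise at the transition
    "K5": (0.0, 0.0, 0.0, 1.0, 1.0),  # late rise
}

_DEFAULT_CLASS_MIX = {
    "intergenic_far": 0.40,
    "intergenic_near": 0.10,
    "exon_overlap": 0.15,
    "intronic": 0.10,
    "single_exon": 0.15,
    "short": 0.10,
}


@dataclass
class SimConfig:
    """Configuration for one synthetic dataset (all randomness from ``seed``)."""

    seed: int = 0
    n_coding_genes: int = 80
    n_candidates: int = 150
    genome: tuple[tuple[str, int], ...] = (("chr1", 4_000_000), ("chr2", 4_000_000))
    class_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CLASS_MIX))
    frac_coding_like: float = 0.20
    tissues: tuple[str, ...] = TISSUES
    time_points: tuple[str, ...] = TIME_POINTS
    n_replicates: int = 3
    n_tissue_reps: int = 1
    n_tissue_specific: int = 10
    n_hf_high: int = 8
    n_de: int = 20
    de_log2fc: float = 2.0
    n_clusters: int = 5
    cluster_size: int = 8
    n_corr_pairs: int = 8
    pair_target_r: float = 0.9
    n_spatiotemporal: int = 2
    st_pair_r: float = 0.95
    noise_sd: float = 0.2
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions sum to {total}, expected 1")
        for key in self.class_mix:
            if key not in CANDIDATE_CLASSES:
                raise ValueError(f"unknown candidate class {key!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("n_coding_genes", "n_candidates", "n_tissue_specific",
                     "n_hf_high", "n_de", "n_corr_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def class_counts(self) -> dict[str, int]:
        """Integer candidate counts per class (largest-remainder rounding)."""
        raw = {c: self.class_mix.get(c, 0.0) * self.n_candidates for c in CANDIDATE_CLASSES}
        counts = {c: int(np.floor(v)) for c, v in raw.items()}
        short = self.n_candidates - sum(counts.values())
        for c in sorted(raw, key=lambda c: raw[c] - np.floor(raw[c]), reverse=True)[:short]:
            counts[c] += 1
        return counts


@dataclass
class TruthLabels:
    """Planted ground truth emitted alongside a synthetic dataset."""

    candidate_class: dict[str, str] = field(default_factory=dict)
    coding_like: set[str] = field(default_factory=set)
    pair_partner: dict[str, tuple[str, float]] = field(default_factory=dict)
    st_pairs: dict[str, tuple[str, float]] = field(default_factory=dict)
    # exact per-comparison significance for features whose fold changes are
    # not template-shaped (the spatiotemporal partners); filled by
    # generate_expression
    partner_significant: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    tissue_specific: dict[str, str] = field(default_factory=dict)
    hf_high: set[str] = field(default_factory=set)
    de_log2fc: dict[str, float] = field(default_factory=dict)
    cluster: dict[str, str] = field(default_factory=dict)
    profiles: dict[str, tuple[float, ...]] = field(default_factory=dict)
    time_points: tuple[str, ...] = TIME_POINTS

    def expected_lincrnas(self) -> set[str]:
        """Candidates that should survive the full discovery cascade."""
        return {
            tid
            for tid, cls in self.candidate_class.items()
            if cls == "intergenic_far" and tid not in self.coding_like
        }

    def significant_comparisons(self, feature: str) -> set[tuple[str, str]]:
        """Time-point pairs expected significant for a planted feature."""
        if feature in self.partner_significant:
            return set(self.partner_significant[feature])
        prof = self.profiles.get(feature)
        if prof is None:
            return set()
        tps = self.time_points
        return {
            (tps[i], tps[j])
            for i in range(len(tps))
            for j in range(i + 1, len(tps))
            if prof[i] != prof[j]
        }

    def expected_time_specific(self) -> set[str]:
        features = set(self.profiles) | set(self.partner_significant)
        return {f for f in features if self.significant_comparisons(f)}

    def expected_transition(self) -> set[str]:
        """Features whose planted DE is confined to cross-block comparisons."""
        cross = {(a, b) for a in BLOCK_EARLY for b in BLOCK_LATE}
        cross |= {(b, a) for a, b in cross}
        out = set()
        for f in set(self.profiles) | set(self.partner_significant):
            sig = self.significant_comparisons(f)
            if sig and sig <= cross:
                out.add(f)
        return out

    def to_json(self) -> str:
        d = asdict(self)
        d["coding_like"] = sorted(self.coding_like)
        d["hf_high"] = sorted(self.hf_high)
        d["pair_partner"] = {k: list(v) for k, v in self.pair_partner.items()}
        d["st_pairs"] = {k: list(v) for k, v in self.st_pairs.items()}
        d["partner_significant"] = {
            k: sorted(list(c) for c in v) for k, v in self.partner_significant.items()
        }
        d["profiles"] = {k: list(v) for k, v in self.profiles.items()}
        d["time_points"] = list(self.time_points)
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# sequence regimes

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in ("TAA", "TAG", "TGA")]
# GC-rich codon bias for the coding regime; the noncoding regime is AT-rich.
_CODON_W = np.array([3.0 ** sum(x in "GC" for x in cod) for cod in _CODONS])
_CODON_P = _CODON_W / _CODON_W.sum()
_NONCODING_P = np.array([0.35, 0.15, 0.15, 0.35])  # A, C, G, T


# 11-mer carrying a stop codon in all three reading frames (TAG at offsets
# 0, 4 and 8, i.e. one per frame whatever the block's alignment); sprinkling
# it through random filler bounds every possible ORF to under ~45 nt.
_STOP_BLOCK = "TAGATAGATAG"


def _noncoding_seq(rng: np.random.Generator, length: int) -> str:
    """AT-rich random sequence with all ORFs kept short by planted stops."""
    bases = np.array(list("ACGT"))
    parts: list[str] = []
    remaining = length
    while remaining > 0:
        fill = min(remaining, int(rng.integers(18, 31)))
        parts.append("".join(rng.choice(bases, size=fill, p=_NONCODING_P)))
        remaining -= fill
        if remaining > 0:
            block = _STOP_BLOCK[: min(remaining, len(_STOP_BLOCK))]
            parts.append(block)
            remaining -= len(block)
    return "".join(parts)


def _coding_seq(rng: np.random.Generator, length: int) -> str:
    """Sequence with a long central ORF of GC-biased codons (~70% coverage)."""
    orf_len = max(300, 3 * int(0.7 * length / 3))
    if orf_len + 6 > length:
        raise ValueError(f"coding-like sequence needs length > {orf_len + 6}")
    n_codons = orf_len // 3 - 2  # minus start and stop
    body = "".join(rng.choice(_CODONS, size=n_codons, p=_CODON_P))
    utr_total = length - orf_len
    utr5 = int(rng.integers(0, utr_total + 1))
    head = _noncoding_seq(rng, utr5) if utr5 else ""
    tail_len = utr_total - utr5
    tail = _noncoding_seq(rng, tail_len) if tail_len else ""
    return head + "ATG" + body + "TAA" + tail


def make_training_sets(
    rng: np.random.Generator, n: int = 150, length: int = 600
) -> tuple[list[str], list[str]]:
    """Training sequences for the hexamer tables, one list per regime."""
    coding = [_coding_seq(rng, length) for _ in range(n)]
    noncoding = [_noncoding_seq(rng, length) for _ in range(n)]
    return coding, noncoding


# ---------------------------------------------------------------------------
# annotation geometry

def _make_gene(rng: np.random.Generator, chrom: str, start: int,
               gene_id: str) -> TranscriptModel:
    n_exons = int(rng.integers(4, 10))
    exons = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(120, 301))
        exons.append((pos, pos + length - 1))
        pos = pos + length + int(rng.integers(500, 2501))
    return TranscriptModel(
        transcript_id=f"{gene_id}.1",
        gene_id=gene_id,
        chrom=chrom,
        strand="+" if rng.random() < 0.5 else "-",
        exons=tuple(exons),
        biotype="coding",
    )


def _exon_chain(rng: np.random.Generator, start: int, n_exons: int,
                exon_range: tuple[int, int],
                intron_range: tuple[int, int] = (200, 1500)) -> tuple[tuple[int, int], ...]:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(exon_range[0], exon_range[1] + 1))
        exons.append((pos, pos + length - 1))
        if i < n_exons - 1:
            pos = pos + length + int(rng.integers(intron_range[0], intron_range[1] + 1))
    return tuple(exons)


def _min_gap_to_genes(chrom: str, span: tuple[int, int],
                      gene_spans: Sequence[tuple[str, int, int]]) -> float:
    """Minimum bp gap from span to any gene span (0 if overlapping)."""
    best = np.inf
    for g_chrom, g_start, g_end in gene_spans:
        if g_chrom != chrom:
            continue
        if span[0] <= g_end and g_start <= span[1]:
            return 0
        gap = g_start - span[1] - 1 if g_start > span[1] else span[0] - g_end - 1
        best = min(best, gap)
    return best


class _Placer:
    """Rejection-sampling placement of candidates subject to class geometry."""

    def __init__(self, rng: np.random.Generator, config: SimConfig,
                 reference: AnnotationSet):
        self.rng = rng
        self.config = config
        self.genes = list(reference)
        self.gene_spans = [(g.chrom, *g.span) for g in self.genes]
        self.placed: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in config.genome}
        self.chrom_len = dict(config.genome)
        self.used_partners: set[str] = set()

    def _free(self, chrom: str, span: tuple[int, int]) -> bool:
        if span[0] < 1 or span[1] > self.chrom_len[chrom]:
            return False
        return all(not (span[0] <= e and s <= span[1]) for s, e in self.placed[chrom])

    def _commit(self, chrom: str, span: tuple[int, int]) -> None:
        self.placed[chrom].append(span)

    def place(self, cls: str, coding_like: bool = False,
              pair_anchor: bool = False, max_tries: int = 3000):
        """Return (chrom, exons, partner_gene_id or None) realizing ``cls``."""
        rng = self.rng
        for _ in range(max_tries):
            if cls in ("intergenic_far", "intergenic_near", "single_exon", "short"):
                result = self._try_intergenic(cls, coding_like, pair_anchor)
            elif cls == "exon_overlap":
                result = self._try_exon_overlap()
            elif cls == "intronic":
                result = self._try_intronic()
            else:
                raise ValueError(f"unknown class {cls!r}")
            if result is not None:
                return result
        raise RuntimeError(f"infeasible placement for candidate class {cls!r}")

    def _try_intergenic(self, cls, coding_like, pair_anchor):
        rng = self.rng
        if cls == "single_exon":
            n_exons, exon_range = 1, (300, 1200)
        elif cls == "short":
            n_exons, exon_range = 2, (50, 90)
        elif coding_like:
            n_exons, exon_range = int(rng.integers(2, 4)), (300, 600)
        else:
            n_exons, exon_range = int(rng.integers(2, 5)), (120, 400)
        partner = None
        partner_span = None
        if cls == "intergenic_near":
            g = self.genes[int(rng.integers(len(self.genes)))]
            chrom = g.chrom
            start = g.span[1] + int(rng.integers(50, 450)) + 1
        elif pair_anchor:
            free_genes = [g for g in self.genes if g.gene_id not in self.used_partners]
            if not free_genes:
                raise RuntimeError("no coding genes left to anchor neighbor pairs")
            g = free_genes[int(rng.integers(len(free_genes)))]
            chrom = g.chrom
            partner, partner_span = g.gene_id, g.span
            if rng.random() < 0.5:
                start = g.span[1] + int(rng.integers(600, 6000)) + 1
            else:
                start = g.span[0] - int(rng.integers(3000, 8000))
        else:
            chrom = self.config.genome[int(rng.integers(len(self.config.genome)))][0]
            start = int(rng.integers(1000, self.chrom_len[chrom] - 20000))
        if start < 1:
            return None
        exons = _exon_chain(rng, start, n_exons, exon_range,
                            intron_range=(200, 800) if cls == "short" else (200, 1500))
        span = (exons[0][0], exons[-1][1])
        gap = _min_gap_to_genes(chrom, span, self.gene_spans)
        if cls == "intergenic_near":
            ok = 1 <= gap < 500
        elif pair_anchor:
            ok = gap >= 500 and _gap(span, partner_span) <= 9500
        else:
            ok = gap >= 500
        if ok and self._free(chrom, span):
            self._commit(chrom, span)
            if partner is not None:
                self.used_partners.add(partner)
            return chrom, exons, partner
        return None

    def _try_exon_overlap(self):
        rng = self.rng
        g = self.genes[int(rng.integers(len(self.genes)))]
        exon = g.exons[int(rng.integers(g.n_exons))]
        overlap = int(rng.integers(20, 101))
        e1 = (exon[1] - overlap + 1, exon[1] + 150)
        e2 = (e1[1] + 301, e1[1] + 500)
        exons = (e1, e2)
        span = (e1[0], e2[1])
        if span[0] >= 1 and self._free(g.chrom, span):
            self._commit(g.chrom, span)
            return g.chrom, exons, None
        return None

    def _try_intronic(self):
        rng = self.rng
        g = self.genes[int(rng.integers(len(self.genes)))]
        introns = [iv for iv in g.introns if iv[1] - iv[0] + 1 >= 400]
        if not introns:
            return None
        intron = introns[int(rng.integers(len(introns)))]
        width = intron[1] - intron[0] + 1
        exon_len = int(rng.integers(150, min(width - 20, 350)))
        start = intron[0] + int(rng.integers(10, width - exon_len - 9))
        exons = ((start, start + exon_len - 1),)
        if self._free(g.chrom, exons[0]):
            self._commit(g.chrom, exons[0])
            return g.chrom, exons, None
        return None


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[0] <= b[1] and b[0] <= a[1]:
        return 0
    return b[0] - a[1] - 1 if b[0] > a[1] else a[0] - b[1] - 1


def generate_annotation(
    config: SimConfig,
) -> tuple[AnnotationSet, AnnotationSet, TruthLabels, dict[str, str]]:
    """Generate reference genes, candidate transcripts, truth and sequences.

    Coding genes are placed non-overlapping along the toy genome; every
    candidate's geometry realizes its class label exactly (far candidates at
    >= 500 bp from every gene span, exon-overlap candidates sharing >= 1 bp
    with a coding exon, and so on). Sequences follow two hexamer regimes:
    coding-like (long GC-biased ORF) for planted coding candidates,
    noncoding-like otherwise. Expression-planting labels (tissue-specific,
    HF-high, DE, cluster, neighbor pairs) are assigned here so that
    :func:`generate_expression` can realize them.
    """
    rng = np.random.default_rng(config.seed)
    reference = AnnotationSet()
    n_chroms = len(config.genome)
    per_chrom = [config.n_coding_genes // n_chroms] * n_chroms
    for i in range(config.n_coding_genes % n_chroms):
        per_chrom[i] += 1
    gid = 0
    for (chrom, length), n_genes in zip(config.genome, per_chrom):
        cursor = int(rng.integers(5_000, 20_000))
        for _ in range(n_genes):
            gene = _make_gene(rng, chrom, cursor, f"GENE{gid:04d}")
            gid += 1
            if gene.span[1] > length - 20_000:
                raise RuntimeError("genome too short for requested coding genes")
            reference.add(gene)
            gap = int(rng.integers(1_500, 8_001)) if rng.random() < 0.4 else int(
                rng.integers(15_000, 60_001))
            cursor = gene.span[1] + gap

    truth = TruthLabels(time_points=config.time_points)
    candidates = AnnotationSet()
    sequences: dict[str, str] = {}
    placer = _Placer(rng, config, reference)

    counts = config.class_counts()
    n_far = counts["intergenic_far"]
    n_coding_like = int(round(config.frac_coding_like * n_far))
    n_anchored = config.n_corr_pairs + config.n_spatiotemporal
    if n_anchored > n_far - n_coding_like:
        raise ValueError(
            "n_corr_pairs + n_spatiotemporal exceeds the noncoding intergenic_far pool"
        )

    plan: list[tuple[str, bool, bool]] = []  # (class, coding_like, pair_anchor)
    plan += [("intergenic_far", False, True)] * n_anchored
    plan += [("intergenic_far", True, False)] * n_coding_like
    plan += [("intergenic_far", False, False)] * (n_far - n_coding_like - n_anchored)
    for cls in ("intergenic_near", "exon_overlap", "intronic", "single_exon", "short"):
        plan += [(cls, False, False)] * counts[cls]

    cid = 0
    n_tissue_pairs = 0
    for cls, coding_like, pair_anchor in plan:
        chrom, exons, partner = placer.place(cls, coding_like=coding_like,
                                             pair_anchor=pair_anchor)
        tid = f"CAND{cid:04d}"
        cid += 1
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=tid,  # one transcript per candidate gene
            chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            exons=exons,
            biotype="linc_candidate",
        )
        candidates.add(tx)
        truth.candidate_class[tid] = cls
        if coding_like:
            truth.coding_like.add(tid)
            sequences[tid] = _coding_seq(rng, tx.spliced_length)
        else:
            sequences[tid] = _noncoding_seq(rng, tx.spliced_length)
        if partner is not None:
            if n_tissue_pairs < config.n_corr_pairs:
                truth.pair_partner[tid] = (partner, config.pair_target_r)
                n_tissue_pairs += 1
            else:
                truth.st_pairs[tid] = (partner, config.st_pair_r)

    _assign_expression_truth(config, rng, truth, reference)
    return reference, candidates, truth, sequences


def _assign_expression_truth(config: SimConfig, rng: np.random.Generator,
                             truth: TruthLabels, reference: AnnotationSet) -> None:
    # spatiotemporal lincs: HF-high, up-regulated with the K4 template shape,
    # and time-correlated with their anchored coding neighbor
    for linc in sorted(truth.st_pairs):
        truth.hf_high.add(linc)
        truth.cluster[linc] = "K4"
        truth.profiles[linc] = tuple(
            config.de_log2fc * v for v in CLUSTER_TEMPLATES["K4"])

    pool = sorted(truth.expected_lincrnas()
                  - set(truth.pair_partner) - set(truth.st_pairs))
    need = config.n_tissue_specific + config.n_hf_high + config.n_de // 2
    if len(pool) < need:
        raise ValueError(
            f"only {len(pool)} plain intergenic lincRNAs available for planting "
            f"{need} expression labels; increase n_candidates"
        )
    it = iter(pool)
    for i in range(config.n_tissue_specific):
        truth.tissue_specific[next(it)] = config.tissues[i % (len(config.tissues) - 1)]
    for _ in range(config.n_hf_high):
        truth.hf_high.add(next(it))

    n_de_linc = config.n_de // 2
    n_de_coding = config.n_de - n_de_linc
    de_features = [next(it) for _ in range(n_de_linc)]
    gene_pool = sorted(set(g.gene_id for g in reference)
                       - {p for p, _ in truth.pair_partner.values()}
                       - {p for p, _ in truth.st_pairs.values()})
    n_cluster_feats = config.n_clusters * config.cluster_size
    if len(gene_pool) < n_de_coding + n_cluster_feats:
        raise ValueError("not enough coding genes for planted DE and clusters")
    de_features += gene_pool[:n_de_coding]
    gene_pool = gene_pool[n_de_coding:]

    lfc = config.de_log2fc
    for j, fid in enumerate(de_features):
        if j % 2 == 0:  # up-regulated after the transition
            truth.de_log2fc[fid] = lfc
            truth.profiles[fid] = _block_profile(config.time_points, 0.0, lfc)
        else:
            truth.de_log2fc[fid] = -lfc
            truth.profiles[fid] = _block_profile(config.time_points, lfc, 0.0)

    template_names = list(CLUSTER_TEMPLATES)[: config.n_clusters]
    for k, name in enumerate(template_names):
        for fid in gene_pool[k * config.cluster_size:(k + 1) * config.cluster_size]:
            truth.cluster[fid] = name
            truth.profiles[fid] = tuple(lfc * v for v in CLUSTER_TEMPLATES[name])


def _block_profile(time_points, early: float, late: float) -> tuple[float, ...]:
    return tuple(early if tp in BLOCK_EARLY else late for tp in time_points)


# ---------------------------------------------------------------------------
# expression

REFERENCE_ASSAYS = ("SDHA", "UBC", "YWHAZ")
_REF_LOG2 = 4.0  # constant housekeeping abundance, FPKM = 2^4 = 16


def sample_layout(config: SimConfig) -> pd.DataFrame:
    """Sample metadata: tissue-panel columns then time-course columns."""
    rows = []
    for tissue in config.tissues:
        for r in range(1, config.n_tissue_reps + 1):
            rows.append((f"{tissue}_r{r}", tissue, None, r))
    for tp in config.time_points:
        for r in range(1, config.n_replicates + 1):
            rows.append((f"{tp}_r{r}", None, tp, r))
    meta = pd.DataFrame(rows, columns=["sample", "tissue", "time_point", "replicate"])
    return meta.set_index("sample")


def generate_expression(
    config: SimConfig,
    features: Sequence[str],
    truth: TruthLabels,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix (features x samples) realizing the planted truth.

    At ``noise_sd=0`` every planted property holds exactly: tissue-specific
    features are positive in exactly one tissue and zero elsewhere, HF-high
    features exceed both fold criteria, DE/cluster features follow their
    log2-offset profiles across time points, and target-correlation-1 pairs
    are exactly proportional. Three constant housekeeping features (named
    after the qPCR reference genes) are appended.
    """
    unknown = (set(truth.candidate_class) | set(truth.cluster) | set(truth.de_log2fc)) - set(features)
    if unknown:
        raise ValueError(f"truth references unknown feature ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(config.seed + 1)
    meta = sample_layout(config)
    samples = list(meta.index)
    tissue_of = meta["tissue"]
    tp_of = meta["time_point"]

    all_features = list(features) + list(REFERENCE_ASSAYS)
    log2_clean = pd.DataFrame(0.0, index=all_features, columns=samples)

    base = config.baseline_log2_mean + config.baseline_log2_sd * rng.standard_normal(
        len(features))
    base = np.clip(base, 2.0, None)  # keep planted features well above the 0.5 FPKM cut

    # latent tissue factors for neighbor pairs (one per pair, shared)
    pair_latent: dict[str, np.ndarray] = {}
    for linc, (partner, _r) in truth.pair_partner.items():
        pair_latent[linc] = rng.standard_normal(len(config.tissues))

    partner_of = {p: (l, r) for l, (p, r) in truth.pair_partner.items()}

    for fid, b in zip(features, base):
        row = np.full(len(samples), b)
        if fid in truth.tissue_specific:
            target = truth.tissue_specific[fid]
            level = max(b, 3.0)
            row = np.where(tissue_of.values == target, level, -np.inf)  # FPKM 0 elsewhere
        elif fid in truth.hf_high:
            level = max(b, 6.0)  # >= 64 FPKM, clears 20x pooled and 2.5x each
            others = rng.uniform(0.5, 2.0, size=len(samples))  # FPKM in [0.5, 2]
            row = np.where(tissue_of.values == "HF", level, np.log2(others))
            row = np.where(tissue_of.isna().values, b, row)  # time course flat
        elif fid in truth.pair_partner or fid in partner_of:
            if fid in truth.pair_partner:
                z = pair_latent[fid]
            else:
                linc, rho = partner_of[fid]
                z0 = pair_latent[linc]
                eps = rng.standard_normal(len(z0))
                z = rho * z0 + np.sqrt(max(0.0, 1 - rho ** 2)) * eps
            tissue_offset = dict(zip(config.tissues, z))
            row = np.array([
                b + tissue_offset[t] if isinstance(t, str) else b
                for t in tissue_of.values
            ])
        if fid in truth.profiles:
            prof = dict(zip(config.time_points, truth.profiles[fid]))
            row = np.array([
                row[i] + prof[tp] if isinstance(tp, str) else row[i]
                for i, tp in enumerate(tp_of.values)
            ])
        log2_clean.loc[fid] = row

    # spatiotemporal partners: time profile with exact target correlation to
    # the paired linc's noise-free time profile (on the FPKM scale)
    tp_cols = {
        tp: [s for s, v in tp_of.items() if v == tp] for tp in config.time_points
    }
    for linc, (partner, rho) in truth.st_pairs.items():
        L = np.array([
            float(np.exp2(log2_clean.loc[linc, tp_cols[tp][0]]))
            for tp in config.time_points
        ])
        C = _correlated_profile(L, rho, mean=24.0, sd=6.0)
        for tp, val in zip(config.time_points, C):
            log2_clean.loc[partner, tp_cols[tp]] = np.log2(val)
        truth.partner_significant[partner] = _exact_significance(
            C, config.time_points)

    for ref in REFERENCE_ASSAYS:
        log2_clean.loc[ref] = _REF_LOG2

    # FPKM = 2^value (log-normal baseline); -inf encodes exact zeros
    fpkm_clean = np.exp2(log2_clean)
    fpkm_clean[log2_clean == -np.inf] = 0.0
    if config.noise_sd > 0:
        noise = config.noise_sd * rng.standard_normal(fpkm_clean.shape)
        fpkm = np.exp2(np.log2(fpkm_clean + 1.0) + noise) - 1.0
        fpkm = fpkm.clip(lower=0.0)
    else:
        fpkm = fpkm_clean
    return fpkm, meta


def generate_qpcr(
    expression: pd.DataFrame,
    targets: Sequence[str],
    reference_ids: Sequence[str] = REFERENCE_ASSAYS,
    ct_at_unit_expression: float = 30.0,
    n_technical: int = 3,
    ct_noise_sd: float = 0.0,
    ct_max: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table consistent with the expression matrix.

    ``Ct = ct_at_unit_expression - log2(FPKM + 1)`` per sample (column) and
    assay, with perfect amplification efficiency, ``n_technical`` technical
    replicates, and optional Gaussian Ct noise. Cts above ``ct_max`` are
    capped and flagged. Inverting with the 2^-ddCt method recovers relative
    (FPKM+1)-scale expression exactly in the noise-free case.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for assay in list(targets) + [r for r in reference_ids if r not in targets]:
        abundances = expression.loc[assay] + 1.0
        for sample, ab in abundances.items():
            ct_true = ct_at_unit_expression - np.log2(ab)
            for rep in range(1, n_technical + 1):
                ct = ct_true + (ct_noise_sd * rng.standard_normal() if ct_noise_sd else 0.0)
                capped = bool(ct > ct_max)
                rows.append((sample, assay, min(ct, ct_max), rep, capped))
    return pd.DataFrame(rows, columns=["sample", "assay", "ct", "replicate", "capped"])


def _correlated_profile(L: np.ndarray, rho: float, mean: float, sd: float) -> np.ndarray:
    """A positive profile with Pearson correlation exactly ``rho`` to ``L``.

    Standardizes ``L``, builds a deterministic unit vector orthogonal to it
    (and centered, so correlation is exact), and mixes the two. Requires a
    non-constant ``L`` of length >= 3.
    """
    n = len(L)
    Lz = (L - L.mean())
    norm = np.sqrt((Lz ** 2).mean())
    if norm == 0:
        raise ValueError("cannot correlate against a constant profile")
    Lz = Lz / norm
    for trial in (np.arange(n) % 2 * 2.0 - 1.0, np.arange(n, dtype=float)):
        w = trial - trial.mean()
        w = w - (w @ Lz) / (Lz @ Lz) * Lz
        wnorm = np.sqrt((w ** 2).mean())
        if wnorm > 1e-9:
            Wz = w / wnorm
            break
    else:
        raise ValueError("no orthogonal direction found")
    C = mean + sd * (rho * Lz + np.sqrt(max(0.0, 1 - rho ** 2)) * Wz)
    if (C <= 0).any():
        raise ValueError("correlated profile not positive; increase mean/sd ratio")
    return C


def _exact_significance(
    C: np.ndarray,
    time_points: Sequence[str],
    epsilon: float = 0.1,
    lfc_threshold: float = 1.0,
) -> set[tuple[str, str]]:
    """Noise-free DE outcome for a profile under the default test settings.

    With zero replicate variance the Welch test degenerates to p = 0 for
    unequal means, so a comparison is significant exactly when the means
    differ and the epsilon-stabilized fold change clears the threshold.
    """
    out = set()
    for i in range(len(time_points)):
        for j in range(i + 1, len(time_points)):
            if C[i] == C[j]:
                continue
            lfc = np.log2((C[j] + epsilon) / (C[i] + epsilon))
            if abs(lfc) >= lfc_threshold:
                out.add((time_points[i], time_points[j]))
    return out


def generate_time_course(
    n_features: int,
    n_de: int,
    log2fc: float,
    noise_sd: float,
    seed: int,
    time_points: Sequence[str] = TIME_POINTS,
    n_replicates: int = 3,
    baseline_log2_mean: float = 3.0,
    baseline_log2_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """A bare time-course matrix with ``n_de`` cross-block shifted features.

    Convenience generator for statistical calibration studies (null
    false-positive rate, detection power): the first ``n_de`` features shift
    by ``log2fc`` between the early (May–Jun) and late (Aug–Oct) blocks,
    the rest are flat; noise as in :func:`generate_expression`. Returns
    (matrix, metadata, de feature ids).
    """
    rng = np.random.default_rng(seed)
    samples = [f"{tp}_r{r}" for tp in time_points for r in range(1, n_replicates + 1)]
    meta = pd.DataFrame(
        {
            "tissue": None,
            "time_point": [s.rsplit("_r", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    base = np.clip(
        baseline_log2_mean + baseline_log2_sd * rng.standard_normal(n_features),
        2.0, None,
    )
    late = np.array([tp in BLOCK_LATE for tp in meta["time_point"]])
    log2_clean = np.tile(base[:, None], (1, len(samples)))
    log2_clean[:n_de, late] += log2fc
    fpkm = np.exp2(log2_clean)
    if noise_sd > 0:
        noise = noise_sd * rng.standard_normal(fpkm.shape)
        fpkm = np.clip(np.exp2(np.log2(fpkm + 1.0) + noise) - 1.0, 0.0, None)
    features = [f"F{i:05d}" for i in range(n_features)]
    matrix = pd.DataFrame(fpkm, index=features, columns=samples)
    return matrix, meta, features[:n_de]


# ---------------------------------------------------------------------------
# serialization

def write_outputs(
    outdir: str | Path,
    reference: AnnotationSet,
    candidates: AnnotationSet,
    truth: TruthLabels,
    sequences: Mapping[str, str],
    expression: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    ct_table: pd.DataFrame | None = None,
) -> None:
    """Write the synthetic dataset as GTF/FASTA/TSV/CSV/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(reference, outdir / "reference.gtf")
    write_gtf(candidates, outdir / "candidates.gtf")
    with open(outdir / "candidates.fa", "w") as fh:
        for tid in sorted(sequences):
            fh.write(f">{tid}\n{sequences[tid]}\n")
    (outdir / "truth.json").write_text(truth.to_json())
    if expression is not None:
        expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="feature")
    if metadata is not None:
        metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    if ct_table is not None:
        ct_table.to_csv(outdir / "ct_table.csv", index=False)
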