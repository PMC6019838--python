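"""FPKM handling, tissue-specificity, hair-follicle enrichment and
neighbor-pair co-expression.

An expression matrix is a pandas DataFrame (rows = features, columns =
samples, values = FPKM >= 0); sample metadata is a DataFrame indexed by
sample id with ``tissue``, ``time_point`` and ``replicate`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet

__all__ = [
    "PairRecord",
    "PairAnalysis",
    "validate_matrix",
    "compute_fpkm",
    "log_z_transform",
    "tissue_means",
    "classify_tissue_specific",
    "detect_hf_high",
    "find_neighbor_pairs",
    "coding_coding_pairs",
    "pair_correlation_analysis",
]

logger = logging.getLogger(__name__)


@dataclass
class PairRecord:
    """A proximal feature pair with its genomic gap and (optionally) its
    tissue-profile Pearson correlation."""

    linc_id: str
    coding_id: str
    gap: int
    pair_class: str = "linc-coding"  # or "coding-coding" / "random"
    pearson_r: float | None = None


@dataclass
class PairAnalysis:
    """Correlation distributions per pair class and the KS comparisons."""

    pairs: list[PairRecord]
    ks_vs_coding: tuple[float, float]  # (D, p) linc-coding vs coding-coding
    ks_vs_random: tuple[float, float]  # (D, p) linc-coding vs random

    def r_values(self, pair_class: str) -> np.ndarray:
        return np.array(
            [p.pearson_r for p in self.pairs
             if p.pair_class == pair_class and p.pearson_r is not None]
        )


def validate_matrix(matrix: pd.DataFrame, metadata: pd.DataFrame | None = None) -> None:
    """Check the expression-matrix invariants (finite, >= 0, no missing)."""
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing cells")
    values = matrix.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    if metadata is not None:
        missing = set(matrix.columns) - set(metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    mapped_reads: pd.Series,
) -> pd.DataFrame:
    """FPKM = count / (length in kb) / (mapped reads in millions)."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    if (mapped_reads <= 0).any():
        raise ValueError("mapped-read totals must be > 0")
    kb = lengths.loc[counts.index] / 1e3
    millions = mapped_reads.loc[counts.columns] / 1e6
    return counts.div(kb, axis=0).div(millions, axis=1)


def log_z_transform(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    log_base: int = 2,
    offset: float = 1.0,
    group_by: str | None = "tissue",
) -> pd.DataFrame:
    """log(FPKM + offset) then per-group Z-score across each group's cells.

    Groups are column groups taken from ``metadata[group_by]`` (each sample
    its own group when ``group_by`` is None). A zero-variance group maps to
    Z = 0. This is the heatmap transform (log2 within tissues); temporal
    analyses use log10.
    """
    if log_base == 2:
        logged = np.log2(matrix + offset)
    elif log_base == 10:
        logged = np.log10(matrix + offset)
    else:
        raise ValueError("log_base must be 2 or 10")
    if group_by is None or metadata is None:
        groups = {col: [col] for col in matrix.columns}
    else:
        labels = metadata.loc[matrix.columns, group_by]
        groups = {
            key: list(cols.index)
            for key, cols in labels.groupby(labels, dropna=False)
        }
    out = logged.copy()
    for _key, cols in groups.items():
        block = logged[cols]
        mu = block.to_numpy().mean()
        sd = block.to_numpy().std(ddof=0)
        out[cols] = 0.0 if sd == 0 else (block - mu) / sd
    return out


def tissue_samples(metadata: pd.DataFrame) -> pd.Series:
    """tissue label per sample, restricted to tissue-panel samples."""
    tissues = metadata["tissue"]
    return tissues[tissues.notna()]


def tissue_means(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean FPKM within each tissue (columns = tissues)."""
    labels = tissue_samples(metadata)
    if labels.empty:
        raise ValueError("metadata contains no tissue samples")
    sub = matrix[labels.index]
    return sub.T.groupby(labels).mean().T


def classify_tissue_specific(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    expressed_threshold: float = 0.5,
) -> pd.Series:
    """Label each feature 'not_expressed', a single tissue name, or 'multi'.

    A feature is expressed in a tissue when its mean FPKM there reaches
    ``expressed_threshold``; tissue-specific means expressed in exactly one
    tissue.
    """
    means = tissue_means(matrix, metadata)
    if means.shape[1] < 2:
        raise ValueError("need at least two tissues")
    expressed = means >= expressed_threshold
    n_expr = expressed.sum(axis=1)
    labels = pd.Series("multi", index=matrix.index, dtype=object)
    labels[n_expr == 0] = "not_expressed"
    single = n_expr == 1
    labels[single] = expressed.loc[single].idxmax(axis=1)
    return labels


def detect_hf_high(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    fold_vs_mean: float = 20.0,
    fold_vs_each: float = 2.5,
    hf_tissue: str = "HF",
) -> pd.Series:
    """Hair-follicle-highly-expressed call per feature.

    True iff the HF mean FPKM is at least ``fold_vs_mean`` times the pooled
    mean of the other tissues' means AND at least ``fold_vs_each`` times
    every individual other tissue's mean. Zero denominators pass; a feature
    silent in HF is False.
    """
    means = tissue_means(matrix, metadata)
    if hf_tissue not in means.columns:
        raise ValueError(f"metadata has no {hf_tissue!r} tissue")
    hf = means[hf_tissue]
    others = means.drop(columns=[hf_tissue])
    if others.shape[1] == 0:
        raise ValueError("need at least one non-HF tissue")
    pooled = others.mean(axis=1)
    ok_mean = hf >= fold_vs_mean * pooled
    ok_each = (hf.to_numpy()[:, None] >= fold_vs_each * others.to_numpy()).all(axis=1)
    return (hf > 0) & ok_mean & pd.Series(ok_each, index=means.index)


def _gene_spans_sorted(aset: AnnotationSet) -> list[tuple[str, int, int, str]]:
    spans = [(chrom, s, e, gid) for gid, (chrom, s, e) in aset.gene_spans().items()]
    spans.sort()
    return spans


def _span_gap(a_start, a_end, b_start, b_end) -> int:
    if a_start <= b_end and b_start <= a_end:
        return 0
    return b_start - a_end - 1 if b_start > a_end else a_start - b_end - 1


def find_neighbor_pairs(
    lincs: AnnotationSet,
    codings: AnnotationSet,
    max_gap: int = 10_000,
) -> list[PairRecord]:
    """Every lincRNA gene–coding gene pair within ``max_gap`` bp (inclusive).

    Gaps are measured between gene spans, boundary-inclusive at exactly
    ``max_gap``.
    """
    coding_spans = _gene_spans_sorted(codings)
    pairs = []
    for linc_gid, (chrom, ls, le) in sorted(lincs.gene_spans().items()):
        for c_chrom, cs, ce, c_gid in coding_spans:
            if c_chrom != chrom:
                continue
            gap = _span_gap(ls, le, cs, ce)
            if gap <= max_gap:
                pairs.append(PairRecord(linc_gid, c_gid, gap, "linc-coding"))
    return pairs


def coding_coding_pairs(codings: AnnotationSet, max_gap: int = 10_000) -> list[PairRecord]:
    """Proximal coding–coding gene pairs (the positional null class)."""
    spans = _gene_spans_sorted(codings)
    pairs = []
    for i in range(len(spans)):
        chrom_i, s_i, e_i, gid_i = spans[i]
        for j in range(i + 1, len(spans)):
            chrom_j, s_j, e_j, gid_j = spans[j]
            if chrom_j != chrom_i or s_j - e_i - 1 > max_gap:
                break
            gap = _span_gap(s_i, e_i, s_j, e_j)
            if gap <= max_gap:
                pairs.append(PairRecord(gid_i, gid_j, gap, "coding-coding"))
    return pairs


def pair_correlation_analysis(
    pairs: Sequence[PairRecord],
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    n_random: int = 200,
    seed: int = 0,
    linc_pool: Sequence[str] | None = None,
    coding_pool: Sequence[str] | None = None,
) -> PairAnalysis:
    """Pearson r over tissue-mean vectors per pair, plus KS comparisons.

    Pair members are looked up in the matrix by id (gene-level rows).
    Random pairs (one linc-side id, one coding-side id, drawn without
    replacement under ``seed``) provide the random null. Pairs in which
    either profile has zero variance are dropped with a warning. Returns
    two-sided asymptotic KS tests of the linc-coding r distribution against
    the coding-coding and random distributions.
    """
    means = tissue_means(matrix, metadata)

    def profile_r(a: str, b: str) -> float | None:
        va, vb = means.loc[a].to_numpy(), means.loc[b].to_numpy()
        if va.std() == 0 or vb.std() == 0:
            return None
        return float(np.corrcoef(va, vb)[0, 1])

    scored: list[PairRecord] = []
    for p in pairs:
        r = profile_r(p.linc_id, p.coding_id)
        if r is None:
            logger.warning("pair (%s, %s): zero-variance profile, dropped",
                           p.linc_id, p.coding_id)
            continue
        scored.append(PairRecord(p.linc_id, p.coding_id, p.gap, p.pair_class, r))

    rng = np.random.default_rng(seed)
    linc_ids = sorted(linc_pool) if linc_pool is not None else sorted(
        {p.linc_id for p in pairs})
    coding_ids = sorted(coding_pool) if coding_pool is not None else sorted(
        {p.coding_id for p in pairs})
    existing = {(p.linc_id, p.coding_id) for p in pairs}
    candidates_pool = [
        (a, b) for a in linc_ids for b in coding_ids if (a, b) not in existing
    ]
    n_draw = min(n_random, len(candidates_pool))
    for idx in rng.choice(len(candidates_pool), size=n_draw, replace=False):
        a, b = candidates_pool[idx]
        r = profile_r(a, b)
        if r is not None:
            scored.append(PairRecord(a, b, -1, "random", r))

    def rs(cls: str) -> np.ndarray:
        return np.array([p.pearson_r for p in scored if p.pair_class == cls])

    r_linc, r_cc, r_rand = rs("linc-coding"), rs("coding-coding"), rs("random")

    def ks(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        if len(a) == 0 or len(b) == 0:
            return (np.nan, np.nan)
        res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
        return (float(res.statistic), float(res.pvalue))

    return PairAnalysis(
        pairs=scored,
        ks_vs_coding=ks(r_linc, r_cc),
        ks_vs_random=ks(r_linc, r_rand),
    )
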