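"""Time-course analysis: pairwise differential expression across the five
skin time points, time-specific gene calls, sample PCA, hierarchical
co-expression clustering and hypergeometric set enrichment.

Differential expression uses a Welch two-sample t-test on log2(FPKM+1)
with a stabilizing epsilon on the fold change and Benjamini–Hochberg
correction across features within each comparison; a feature is significant
when |log2FC| >= 1 and q <= 0.05. PCA and clustering work on
log10(FPKM+1), the transform used for the temporal figures (the tissue
heatmap uses log2).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "ClusterAssignment",
    "time_point_order",
    "pairwise_de",
    "time_specific_genes",
    "pca_samples",
    "hierarchical_cluster",
    "hypergeometric_enrichment",
    "spatiotemporal_overlap",
]

logger = logging.getLogger(__name__)

TIME_POINTS = ("May", "Jun", "Aug", "Sep", "Oct")
BLOCK_EARLY = ("May", "Jun")
BLOCK_LATE = ("Aug", "Sep", "Oct")


@dataclass(frozen=True)
class DEResult:
    feature: str
    comparison: tuple[str, str]
    log2_fold_change: float
    p_value: float
    q_value: float
    significant: bool


@dataclass
class ClusterAssignment:
    """feature -> cluster id (1..k, labelled by descending size) + linkage."""

    labels: pd.Series
    linkage_matrix: np.ndarray
    dropped: tuple[str, ...] = ()


def time_point_order(metadata: pd.DataFrame) -> list[str]:
    present = [tp for tp in TIME_POINTS if tp in set(metadata["time_point"].dropna())]
    extra = sorted(set(metadata["time_point"].dropna()) - set(TIME_POINTS))
    return present + extra


def _time_groups(matrix: pd.DataFrame, metadata: pd.DataFrame) -> dict[str, list[str]]:
    tp = metadata.loc[matrix.columns, "time_point"]
    return {key: list(cols.index) for key, cols in tp[tp.notna()].groupby(tp)}


def pairwise_de(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    epsilon: float = 0.1,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    equal_var: bool = True,
) -> list[DEResult]:
    """t-test differential expression for all unordered time-point pairs.

    For comparison (A, B): log2FC = log2((mean_B + eps) / (mean_A + eps)) on
    FPKM; p from a two-sample t-test on log2(FPKM+1) — pooled-variance by
    default, which is exactly calibrated at three replicates under the
    homoscedastic log-scale noise model (``equal_var=False`` gives Welch's
    variant, conservative at such small group sizes); BH across features
    within the comparison. When both groups have zero variance the test
    degenerates: p = 0 for unequal means, 1 for equal means.
    """
    groups = _time_groups(matrix, metadata)
    order = [tp for tp in time_point_order(metadata) if tp in groups]
    if len(order) < 2:
        raise ValueError("need at least two time points")
    for tp, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"time point {tp} has fewer than 2 replicates")

    logged = np.log2(matrix + 1.0)
    results: list[DEResult] = []
    for tp_a, tp_b in itertools.combinations(order, 2):
        a_cols, b_cols = groups[tp_a], groups[tp_b]
        mean_a = matrix[a_cols].mean(axis=1).to_numpy()
        mean_b = matrix[b_cols].mean(axis=1).to_numpy()
        lfc = np.log2((mean_b + epsilon) / (mean_a + epsilon))

        la, lb = logged[a_cols].to_numpy(), logged[b_cols].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # identical noise-free groups degenerate the t statistic; handled below
            warnings.simplefilter("ignore", RuntimeWarning)
            t_res = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var)
        p = np.asarray(t_res.pvalue, dtype=float)
        degenerate = np.isnan(p)
        if degenerate.any():
            equal = np.isclose(la.mean(axis=1), lb.mean(axis=1))
            p[degenerate & equal] = 1.0
            p[degenerate & ~equal] = 0.0
        _rej, q, _a, _b = multipletests(p, method="fdr_bh")
        sig = (np.abs(lfc) >= lfc_threshold) & (q <= q_threshold)
        results.extend(
            DEResult(f, (tp_a, tp_b), float(l), float(pv), float(qv), bool(s))
            for f, l, pv, qv, s in zip(matrix.index, lfc, p, q, sig)
        )
    return results


def de_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature, f"{r.comparison[0]}_vs_{r.comparison[1]}",
             r.log2_fold_change, r.p_value, r.q_value, r.significant)
            for r in results
        ],
        columns=["feature", "comparison", "log2fc", "p", "q", "significant"],
    )


def time_specific_genes(
    results: Sequence[DEResult],
) -> tuple[set[str], pd.Series, set[str]]:
    """Time-specific features, per-comparison significant counts, and the
    transition subset (significant only across the May–Jun / Aug–Oct blocks).
    """
    cross = {(a, b) for a in BLOCK_EARLY for b in BLOCK_LATE}
    cross |= {(b, a) for a, b in cross}
    sig_by_feature: dict[str, set[tuple[str, str]]] = {}
    counts: dict[tuple[str, str], int] = {}
    for r in results:
        counts.setdefault(r.comparison, 0)
        if r.significant:
            counts[r.comparison] += 1
            sig_by_feature.setdefault(r.feature, set()).add(r.comparison)
    time_specific = set(sig_by_feature)
    transition = {f for f, comps in sig_by_feature.items() if comps <= cross}
    count_series = pd.Series(
        {f"{a}_vs_{b}": n for (a, b), n in counts.items()}
    ).sort_index()
    return time_specific, count_series, transition


def pca_samples(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    log_base: int = 10,
    offset: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log(FPKM+1) feature space (features centered).

    Returns (scores indexed by sample, explained-variance fractions summing
    to 1 over all retained components). Restricted to time-course samples
    when metadata is given.
    """
    if metadata is not None:
        cols = metadata.index[metadata["time_point"].notna()]
        matrix = matrix[[c for c in matrix.columns if c in set(cols)]]
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    logged = np.log10(matrix + offset) if log_base == 10 else np.log2(matrix + offset)
    X = logged.T.to_numpy()  # samples x features
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant matrix: PCA undefined")
    pca = PCA()
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores,
        index=logged.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return frame, pca.explained_variance_ratio_


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    k: int = 5,
    log_base: int = 10,
) -> ClusterAssignment:
    """Complete-linkage clustering on 1 - Pearson r between time profiles.

    Feature profiles are per-time-point means of log(FPKM+1); the tree is
    cut to exactly ``k`` clusters, relabelled 1..k by descending size (ties
    by smallest member id). Zero-variance profiles are dropped with a
    warning.
    """
    groups = _time_groups(matrix, metadata)
    order = [tp for tp in time_point_order(metadata) if tp in groups]
    logged = np.log10(matrix + 1.0) if log_base == 10 else np.log2(matrix + 1.0)
    profiles = pd.DataFrame(
        {tp: logged[groups[tp]].mean(axis=1) for tp in order}
    )
    variances = profiles.var(axis=1, ddof=0)
    dropped = tuple(profiles.index[variances == 0])
    if dropped:
        logger.warning("dropping %d zero-variance profiles before clustering",
                       len(dropped))
        profiles = profiles.loc[variances > 0]
    if len(profiles) < k:
        raise ValueError(f"fewer than k={k} usable features")
    dist = pdist(profiles.to_numpy(), metric="correlation")  # 1 - Pearson r
    Z = linkage(dist, method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    raw_series = pd.Series(raw, index=profiles.index)
    sizes = raw_series.value_counts()
    ordered = sorted(
        sizes.index,
        key=lambda c: (-sizes[c], min(raw_series.index[raw_series == c])),
    )
    relabel = {old: new + 1 for new, old in enumerate(ordered)}
    return ClusterAssignment(
        labels=raw_series.map(relabel), linkage_matrix=Z, dropped=dropped
    )


def hypergeometric_enrichment(
    cluster_features: Set[str],
    gene_sets: Mapping[str, Set[str]],
    universe: Set[str],
) -> pd.DataFrame:
    """Over-representation of each gene set in a cluster.

    p = P(X >= overlap) under the hypergeometric null with the given
    universe; BH correction across terms. Gene sets are intersected with
    the universe first.
    """
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_features) & set(universe)
    rows = []
    for term in sorted(gene_sets):
        members = set(gene_sets[term]) & set(universe)
        overlap = len(cluster & members)
        # survival function at overlap-1 gives the upper tail P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members),
                                     len(cluster)))
        rows.append((term, overlap, len(members), min(p, 1.0)))
    frame = pd.DataFrame(rows, columns=["term", "overlap", "set_size", "p"])
    if len(frame):
        frame["q"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    else:
        frame["q"] = []
    return frame


def spatiotemporal_overlap(
    hf_high: Set[str],
    de_lincs: Set[str],
    clusters: ClusterAssignment | None,
    pairs: Sequence,
    matrix: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spatiotemporal lincRNAs: HF-high AND differentially expressed.

    One row per (member, proximal coding neighbor) — or a single row with
    no neighbor — carrying the member's cluster id and, when a matrix is
    given, the Pearson r between member and neighbor over time-point means.
    """
    members = sorted(set(hf_high) & set(de_lincs))
    neighbor_map: dict[str, list] = {m: [] for m in members}
    for p in pairs:
        if p.linc_id in neighbor_map:
            neighbor_map[p.linc_id].append(p)

    tp_means = None
    if matrix is not None and metadata is not None:
        groups = _time_groups(matrix, metadata)
        order = [tp for tp in time_point_order(metadata) if tp in groups]
        tp_means = pd.DataFrame(
            {tp: matrix[groups[tp]].mean(axis=1) for tp in order}
        )

    rows = []
    for m in members:
        cluster_id = None
        if clusters is not None and m in clusters.labels.index:
            cluster_id = int(clusters.labels[m])
        neighbors = neighbor_map[m]
        if not neighbors:
            rows.append((m, cluster_id, None, None, None))
            continue
        for p in neighbors:
            r = None
            if tp_means is not None and m in tp_means.index and p.coding_id in tp_means.index:
                va = tp_means.loc[m].to_numpy()
                vb = tp_means.loc[p.coding_id].to_numpy()
                if va.std() > 0 and vb.std() > 0:
                    r = float(np.corrcoef(va, vb)[0, 1])
            rows.append((m, cluster_id, p.coding_id, p.gap, r))
    return pd.DataFrame(
        rows, columns=["lincRNA", "cluster", "neighbor", "gap", "pearson_r"]
    )
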