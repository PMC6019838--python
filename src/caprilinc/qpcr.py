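"""Relative quantification by the 2^-ddCt method and RNA-seq concordance.

A Ct table holds one row per (condition/sample, assay, technical replicate)
threshold cycle. Quantification normalizes the target Ct against the
arithmetic mean of the reference assays' Cts (equivalent to the geometric
mean of reference quantities), references a calibrator condition, and
assumes perfect amplification efficiency (doubling per cycle) unless told
otherwise.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_delta_ct", "relative_quantities", "rnaseq_concordance"]


def _mean_ct(table: pd.DataFrame, assay: str, condition: str) -> float:
    rows = table[(table["assay"] == assay) & (table["sample"] == condition)]
    if rows.empty:
        raise ValueError(f"assay {assay!r} not measured in condition {condition!r}")
    return float(rows["ct"].mean())


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference_assays: Sequence[str],
    calibrator: str,
    efficiency: float = 2.0,
    per_reference: bool = False,
) -> pd.Series:
    """Relative quantity of ``target`` per condition by 2^-ddCt.

    Technical replicates are averaged first (arithmetic mean of Ct). With
    the default mode the reference Cts are averaged before computing dCt;
    ``per_reference=True`` instead computes a dCt against each reference
    and averages the dCts afterwards (identical at efficiency 2). Capped
    Cts propagate a warning flag via the ``capped`` column if present.
    """
    if not reference_assays:
        raise ValueError("at least one reference assay required")
    conditions = sorted(table["sample"].unique())
    if calibrator not in conditions:
        raise ValueError(f"calibrator {calibrator!r} not among conditions")

    def dct(condition: str) -> float:
        t = _mean_ct(table, target, condition)
        refs = [_mean_ct(table, ref, condition) for ref in reference_assays]
        if per_reference:
            return float(np.mean([t - r for r in refs]))
        return t - float(np.mean(refs))

    ddct = {c: dct(c) - dct(calibrator) for c in conditions}
    quantities = pd.Series(
        {c: efficiency ** (-d) for c, d in ddct.items()}, name=target
    )
    if "capped" in table.columns:
        capped_conditions = set(
            table.loc[table["capped"] & (table["assay"] == target), "sample"]
        )
        quantities.attrs["unreliable"] = sorted(capped_conditions)
    return quantities


def relative_quantities(
    table: pd.DataFrame,
    targets: Sequence[str],
    reference_assays: Sequence[str],
    calibrator: str,
    **kwargs,
) -> pd.DataFrame:
    """2^-ddCt quantities for several targets (rows) across conditions."""
    return pd.DataFrame(
        {
            t: delta_delta_ct(table, t, reference_assays, calibrator, **kwargs)
            for t in targets
        }
    ).T


def rnaseq_concordance(
    qpcr: pd.DataFrame,
    rnaseq: pd.DataFrame,
    reference_point: str = "Oct",
    offset: float = 1.0,
) -> pd.DataFrame:
    """Pearson r between qPCR and RNA-seq log2 change series per assay.

    Both inputs are assays x time points. Each series is converted to
    log2(value / value at ``reference_point``) so the reference maps to 0;
    ``offset`` is added to the RNA-seq values first (FPKM+1-style abundance,
    matching 2^-ddCt quantities derived from such abundances; use 0 for raw
    ratios). A zero at the reference with ``offset=0`` falls back to a 0.1
    pseudo-value and flags the assay.
    """
    common = [c for c in qpcr.columns if c in rnaseq.columns]
    if reference_point not in common:
        raise ValueError(f"reference point {reference_point!r} missing from a series")
    assays = [a for a in qpcr.index if a in rnaseq.index]
    rows = []
    for assay in assays:
        q = qpcr.loc[assay, common].to_numpy(dtype=float)
        s = rnaseq.loc[assay, common].to_numpy(dtype=float) + offset
        flagged = False
        ref_idx = common.index(reference_point)
        if s[ref_idx] == 0:
            s = s + 0.1
            flagged = True
        if q[ref_idx] == 0:
            q = q + 0.1
            flagged = True
        lq = np.log2(q / q[ref_idx])
        ls = np.log2(s / s[ref_idx])
        if np.std(lq) == 0 or np.std(ls) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(lq, ls)
        rows.append((assay, float(r), float(p) if p == p else np.nan, flagged))
    return pd.DataFrame(
        rows, columns=["assay", "pearson_r", "p_value", "flagged"]
    ).set_index("assay")
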