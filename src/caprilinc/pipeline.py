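"""End-to-end orchestration of the lincRNA discovery cascade."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .codpot import HexamerTable, score_transcripts, train_hexamer_table
from .discovery import FilterAudit, apply_filter_cascade, classify_vs_reference
from .simulate import make_training_sets

__all__ = ["default_hexamer_table", "discover_lincrnas"]


def default_hexamer_table(seed: int = 12345, n: int = 150, length: int = 600) -> HexamerTable:
    """Hexamer table trained on generated coding/noncoding regime sequences."""
    coding, noncoding = make_training_sets(np.random.default_rng(seed), n=n, length=length)
    return train_hexamer_table(coding, noncoding)


def discover_lincrnas(
    reference: AnnotationSet,
    candidates: AnnotationSet,
    sequences: Mapping[str, str],
    expression: pd.DataFrame,
    hexamer_table: HexamerTable | None = None,
    **cascade_kwargs,
) -> tuple[AnnotationSet, FilterAudit]:
    """Classify candidates, score coding potential, run the filter cascade.

    Coding potential is only evaluated for transcripts that reach the final
    stage geometrically (class 'u', multi-exon, expressed, distant, long
    enough), which keeps the Fickett minimum-length contract satisfied.
    """
    classified = classify_vs_reference(candidates, reference)
    table = hexamer_table if hexamer_table is not None else default_hexamer_table()

    survivors = [
        c.transcript.transcript_id
        for c in classified
        if c.class_code == "u"
        and c.transcript.n_exons >= 2
        and c.transcript.spliced_length >= 200
    ]
    reports = score_transcripts(
        {tid: sequences[tid] for tid in survivors if tid in sequences}, table
    )
    return apply_filter_cascade(classified, expression, reports, **cascade_kwargs)
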