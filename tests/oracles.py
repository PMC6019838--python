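"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (explicit loops,
published tables restated, no shared code with the package) so that
agreement with the package is a meaningful check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

# --- Fickett TESTCODE, straight from the published lookup tables ----------

_FICKETT = {
    # base: (position probabilities, position weight,
    #        content probabilities, content weight)
    "A": ([0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22], 0.26,
          [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21], 0.11),
    "C": ([0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23], 0.18,
          [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31], 0.12),
    "G": ([0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08], 0.31,
          [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29], 0.15),
    "T": ([0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09], 0.33,
          [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58], 0.14),
}
_POS_CUTS = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CON_CUTS = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]


def fickett_oracle(seq: str) -> float:
    seq = seq.upper()
    score = 0.0
    for base in "ACGT":
        counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                counts[i % 3] += 1
        position = max(counts) / (min(counts) + 1)
        content = sum(1 for ch in seq if ch == base) / len(seq)
        pos_probs, pos_w, con_probs, con_w = _FICKETT[base]
        for idx, cut in enumerate(_POS_CUTS):
            if position >= cut:
                score += pos_probs[idx] * pos_w
                break
        for idx, cut in enumerate(_CON_CUTS):
            if content >= cut:
                score += con_probs[idx] * con_w
                break
    return score


# --- hexamer LLR by explicit window enumeration ---------------------------

def hexamer_llr_oracle(seq: str, coding: dict, noncoding: dict) -> float:
    seq = seq.upper()
    values = []
    for i in range(len(seq) - 5):
        window = seq[i:i + 6]
        if "N" in window:
            continue
        values.append(math.log2(coding[window] / noncoding[window]))
    return sum(values) / len(values)


# --- Benjamini-Hochberg step-up by definition -----------------------------

def bh_oracle(pvalues: list[float]) -> list[float]:
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        q[i] = running
    return q


# --- two-sample KS statistic by ECDF sweep --------------------------------

def ks_oracle(a: list[float], b: list[float]) -> float:
    points = sorted(set(a) | set(b))
    d = 0.0
    for x in points:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


# --- hypergeometric upper tail by exact enumeration -----------------------

def hypergeom_tail_oracle(overlap: int, universe: int, set_size: int,
                          cluster_size: int) -> float:
    """P(X >= overlap) enumerated over all cluster draws (exact rationals)."""
    total = Fraction(math.comb(universe, cluster_size))
    acc = Fraction(0)
    for k in range(overlap, min(set_size, cluster_size) + 1):
        acc += Fraction(
            math.comb(set_size, k) * math.comb(universe - set_size, cluster_size - k)
        )
    return float(acc / total)


# --- Pearson r, textbook closed form --------------------------------------

def pearson_oracle(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - mx) ** 2 for xi in x) * sum((yi - my) ** 2 for yi in y))
    return num / den


# --- spliced length by explicit base counting -----------------------------

def spliced_length_oracle(exons: list[tuple[int, int]]) -> int:
    bases = set()
    for start, end in exons:
        for pos in range(start, end + 1):
            bases.add(pos)
    return len(bases)


# --- all-pairs positional classification ----------------------------------

def classify_oracle(candidate, reference_transcripts) -> tuple[str, float]:
    """Class code and distance for one candidate by exhaustive scanning."""
    cand_span = (candidate.exons[0][0], candidate.exons[-1][1])
    exon_overlap = False
    gene_spans = {}
    for tx in reference_transcripts:
        if tx.chrom != candidate.chrom:
            continue
        for s, e in tx.exons:
            for cs, ce in candidate.exons:
                if cs <= e and s <= ce:
                    exon_overlap = True
        span = gene_spans.get(tx.gene_id)
        tx_span = (tx.exons[0][0], tx.exons[-1][1])
        if span is None:
            gene_spans[tx.gene_id] = tx_span
        else:
            gene_spans[tx.gene_id] = (min(span[0], tx_span[0]), max(span[1], tx_span[1]))
    if exon_overlap:
        return "o", 0
    distance = math.inf
    for s, e in gene_spans.values():
        if cand_span[0] <= e and s <= cand_span[1]:
            distance = 0
        elif s > cand_span[1]:
            distance = min(distance, s - cand_span[1] - 1)
        else:
            distance = min(distance, cand_span[0] - e - 1)
    if distance == 0:
        return "i", 0
    if distance < 500:
        return "near", distance
    return "u", distance


def all_hexamers() -> list[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=6)]
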