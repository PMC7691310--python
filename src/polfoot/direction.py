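"""Promoter directionality from strand-specific nascent transcription.

Genes whose large-footprint signal is positively skewed are expected to be
transcribed almost exclusively in the sense direction, while negatively
skewed genes show divergent (antisense) transcription.  Given two
strand-resolved nascent-coverage tracks (e.g. mNET-seq), this module sums
sense and antisense signal in a window around the short-fragment peak,
condenses them into a bounded directionality index
``di = (sense - antisense) / (sense + antisense)`` in [-1, 1], and compares
di between skew classes with a rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .peaks import PeakCall

__all__ = [
    "DirectionalityRecord",
    "strand_signal",
    "directionality_index",
    "directionality_table",
    "rank_sum",
    "concordance",
]


@dataclass(frozen=True)
class DirectionalityRecord:
    gene: str
    sense_sum: float
    antisense_sum: float
    di: float | None  # None when both sums are 0


def strand_signal(plus_track: CoverageTrack, minus_track: CoverageTrack,
                  peak: PeakCall, strand: str | None = None,
                  halfwidth: int = 750):
    """Sense/antisense nascent sums over +-halfwidth of the peak.

    Sense is the track matching the gene strand.  Absolute values are summed
    because some strand-resolved formats store minus-strand signal negated.
    """
    if plus_track is None or minus_track is None:
        raise ValueError("both a plus- and a minus-strand track are required")
    strand = strand or peak.strand
    p = peak.peak_position
    lo, hi = p - halfwidth, p + halfwidth

    def abs_sum(track):
        if peak.chrom not in track:
            return 0.0
        vals = track.values(peak.chrom, lo, hi)
        return float(np.abs(vals).sum())

    plus = abs_sum(plus_track)
    minus = abs_sum(minus_track)
    return (plus, minus) if strand == "+" else (minus, plus)


def directionality_index(sense: float, antisense: float) -> float | None:
    """(sense - antisense) / (sense + antisense); None if both are 0."""
    if sense < 0 or antisense < 0:
        raise ValueError("sums must be >= 0")
    total = sense + antisense
    if total == 0:
        return None
    return (sense - antisense) / total


def log_ratio_index(sense: float, antisense: float) -> float | None:
    """log10(sense/antisense) alternative; None unless both are positive."""
    if sense <= 0 or antisense <= 0:
        return None
    return math.log10(sense / antisense)


def directionality_table(plus_track, minus_track, peaks: list[PeakCall],
                         halfwidth: int = 750) -> list[DirectionalityRecord]:
    records = []
    for pk in peaks:
        sense, anti = strand_signal(plus_track, minus_track, pk,
                                    halfwidth=halfwidth)
        records.append(DirectionalityRecord(
            pk.gene, sense, anti, directionality_index(sense, anti)))
    return records


def rank_sum(a, b, continuity: bool = True):
    """Two-sample rank-sum comparison of a vs b.

    Returns a dict with the rank sum W of sample ``a`` (midranks), the
    tie-corrected continuity-corrected normal z statistic, its two-sided
    p-value, and — when the pooled size is small enough to enumerate — the
    exact one-sided tail probability P(W' >= W) over all C(n, n_a)
    assignments of the pooled values to the two groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    diff = w - mean
    if var <= 0 or diff == 0:
        z = 0.0
    else:
        cc = 0.5 if continuity else 0.0
        z = (diff - math.copysign(cc, diff)) / math.sqrt(var)
    p_normal = 2 * stats.norm.sf(abs(z))
    exact_tail = None
    if math.comb(n, n1) <= 200_000:
        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if ranks[list(idx)].sum() >= w:
                count += 1
        exact_tail = count / total
    return {"rank_sum": w, "z": z, "p_normal": p_normal,
            "exact_tail_ge": exact_tail, "n_a": n1, "n_b": n2}


def concordance(labels: dict[str, str],
                records: list[DirectionalityRecord]) -> dict:
    """Relate skew classes to nascent directionality.

    Produces per-class summaries of the directionality index, the rank-sum
    comparison of di between the positive and negative skew classes (the
    package's formalization of a contrast the source analysis drew
    visually), and a contingency table of class vs sense-dominance.
    """
    by_class: dict[str, list[float]] = {}
    contingency: dict[str, dict[str, int]] = {}
    for rec in records:
        label = labels.get(rec.gene)
        if label is None or rec.di is None:
            continue
        by_class.setdefault(label, []).append(rec.di)
        cell = contingency.setdefault(label, {
            "sense_dominant": 0, "antisense_or_balanced": 0})
        cell["sense_dominant" if rec.di > 0 else "antisense_or_balanced"] += 1

    def summary(vals):
        arr = np.asarray(vals)
        return {
            "n": int(arr.size),
            "median": float(np.median(arr)),
            "mean": float(arr.mean()),
            "frac_sense_dominant": float((arr > 0).mean()),
        }

    out = {
        "per_class": {k: summary(v) for k, v in sorted(by_class.items())},
        "contingency": contingency,
        "positive_vs_negative": None,
    }
    pos = by_class.get("positive", [])
    neg = by_class.get("negative", [])
    if pos and neg:
        out["positive_vs_negative"] = rank_sum(pos, neg)
    return out


def records_to_frame(records: list[DirectionalityRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "sense_sum": r.sense_sum,
        "antisense_sum": r.antisense_sum, "di": r.di,
    } for r in records])
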