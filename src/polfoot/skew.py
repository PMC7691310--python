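"""Flank skewness of the large-size-class footprints around the peak.

For each gene retained by the peak filters, the large-fragment coverage is
summed over the 500 bp flanks of the short-fragment peak: S- upstream and
S+ downstream in *gene orientation* (the windows partition
``[p-500, p+500)`` as ``[p-500, p)`` and ``[p, p+500)``; for minus-strand
genes the genomic windows swap roles).  The skewness statistic is
``log10(S+ / S-)``, defined only when both flanks are positive.  A gene is
called positively skewed when both large size classes ([120,270) and
[270,440) bp) have skew >= +1, negatively skewed when both <= -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .coverage import CoverageTrack
from .peaks import PeakCall

__all__ = [
    "SkewnessRecord",
    "flank_signals",
    "skewness",
    "classify_skew",
    "skew_table",
]

MID_CLASS = "120-270"
LARGE_CLASS = "270-440"


@dataclass(frozen=True)
class SkewnessRecord:
    gene: str
    s_minus_mid: float
    s_plus_mid: float
    skew_mid: float | None
    s_minus_large: float
    s_plus_large: float
    skew_large: float | None
    label: str  # positive / negative / unclassified / undefined


def flank_signals(track: CoverageTrack, peak: PeakCall, strand: str | None = None,
                  width: int = 500, gene_orientation: bool = True,
                  pseudocount: float = 0.0):
    """Summed coverage in the two flanks of the peak.

    Returns ``(s_minus, s_plus)`` where the minus flank is upstream of the
    gene and the plus flank downstream (``gene_orientation=True``, default);
    with ``gene_orientation=False`` the flanks are left/right in genomic
    coordinates regardless of strand.  Windows running off the contig
    support are effectively clipped (out-of-support bases count 0).
    """
    strand = strand or peak.strand
    p = peak.peak_position
    left = track.sum(peak.chrom, p - width, p)
    right = track.sum(peak.chrom, p, p + width)
    if gene_orientation and strand == "-":
        s_minus, s_plus = right, left
    else:
        s_minus, s_plus = left, right
    return s_minus + pseudocount, s_plus + pseudocount


def skewness(s_plus: float, s_minus: float) -> float | None:
    """log10(S+ / S-), or None when either flank is 0 (gene excluded)."""
    if s_plus < 0 or s_minus < 0:
        raise ValueError("flank sums must be >= 0")
    if s_plus == 0 or s_minus == 0:
        return None
    return math.log10(s_plus / s_minus)


def classify_skew(skew_mid: float | None, skew_large: float | None,
                  threshold: float = 1.0) -> str:
    """Gene label from the two size-class skews.

    positive: both >= threshold; negative: both <= -threshold; undefined if
    either skew is undefined; unclassified otherwise.
    """
    if skew_mid is None or skew_large is None:
        return "undefined"
    if skew_mid >= threshold and skew_large >= threshold:
        return "positive"
    if skew_mid <= -threshold and skew_large <= -threshold:
        return "negative"
    return "unclassified"


def skew_table(track_mid: CoverageTrack, track_large: CoverageTrack,
               peaks: list[PeakCall], width: int = 500, threshold: float = 1.0,
               gene_orientation: bool = True,
               pseudocount: float = 0.0) -> list[SkewnessRecord]:
    """Compute flank sums, skews and labels for a set of retained peaks."""
    records = []
    for pk in peaks:
        sm_m, sp_m = flank_signals(track_mid, pk, width=width,
                                   gene_orientation=gene_orientation,
                                   pseudocount=pseudocount)
        sm_l, sp_l = flank_signals(track_large, pk, width=width,
                                   gene_orientation=gene_orientation,
                                   pseudocount=pseudocount)
        k_m = skewness(sp_m, sm_m)
        k_l = skewness(sp_l, sm_l)
        records.append(SkewnessRecord(
            gene=pk.gene,
            s_minus_mid=sm_m, s_plus_mid=sp_m, skew_mid=k_m,
            s_minus_large=sm_l, s_plus_large=sp_l, skew_large=k_l,
            label=classify_skew(k_m, k_l, threshold),
        ))
    return records


def records_to_frame(records: list[SkewnessRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene,
        "s_minus_mid": r.s_minus_mid, "s_plus_mid": r.s_plus_mid,
        "skew_mid": r.skew_mid,
        "s_minus_large": r.s_minus_large, "s_plus_large": r.s_plus_large,
        "skew_large": r.skew_large,
        "label": r.label,
    } for r in records])


def class_counts(records: list[SkewnessRecord]) -> dict:
    counts = {"positive": 0, "negative": 0, "unclassified": 0, "undefined": 0}
    for r in records:
        counts[r.label] += 1
    counts["total"] = len(records)
    return counts
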