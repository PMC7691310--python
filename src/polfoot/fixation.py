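"""Signal attenuation between assay conditions (fixed vs unfixed).

Formaldehyde fixation multiplicatively attenuates the recovered CUT&RUN
signal.  Per assay, each gene is summarised by the maximum spike-in
normalized coverage within +-1.5 kb of its TSS; conditions are then
compared by (i) an ordinary least-squares line through the paired heights,
(ii) the mean per-gene log10 height ratio, and (iii) for every assay pair,
the Hodges-Lehmann shift of log10 heights (the location estimate associated
with the rank-sum test: the median of all between-sample differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Anchor
from .coverage import CoverageTrack
from .direction import rank_sum

__all__ = [
    "AssayHeights",
    "peak_heights",
    "compare_conditions",
    "hodges_lehmann",
    "pairwise_shift",
]


@dataclass
class AssayHeights:
    """Per-gene peak heights for one assay."""

    assay: str
    condition: str  # unfixed / fixed / control
    heights: pd.Series  # index = gene ids, values >= 0
    antibody: str | None = None

    def __post_init__(self) -> None:
        if (self.heights < 0).any():
            raise ValueError("heights must be >= 0")


def peak_heights(track: CoverageTrack, anchors: list[Anchor], assay: str = "",
                 condition: str = "unfixed", halfwidth: int = 1500,
                 antibody: str | None = None) -> AssayHeights:
    """Max normalized coverage in [tss - halfwidth, tss + halfwidth) per gene."""
    vals = {}
    for a in anchors:
        if a.chrom not in track:
            raise KeyError(f"anchor {a.name}: unknown contig {a.chrom!r}")
        vals[a.name or f"{a.chrom}:{a.position}"] = track.max(
            a.chrom, a.position - halfwidth, a.position + halfwidth)
    return AssayHeights(assay, condition, pd.Series(vals, dtype=float), antibody)


def compare_conditions(a: AssayHeights, b: AssayHeights,
                       min_height: float = 5.0,
                       zero_intercept: bool = False) -> dict:
    """Regression and mean log ratio of b against reference a.

    Genes are filtered on the *reference* assay (a.height > min_height) so
    selection does not act on the attenuated signal.  The mean log ratio is
    mean(log10(b/a)) over retained genes where both heights are positive.
    """
    common = a.heights.index.intersection(b.heights.index)
    x = a.heights.loc[common]
    y = b.heights.loc[common]
    keep = x > min_height
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(
            f"only {len(x)} genes above min_height={min_height} in the "
            "reference assay; need >= 3")
    if zero_intercept:
        beta = float((x * y).sum() / (x * x).sum())
        alpha = 0.0
    else:
        res = stats.linregress(x, y)
        beta, alpha = float(res.slope), float(res.intercept)
    both = (x > 0) & (y > 0)
    log_ratio = np.log10(y[both] / x[both])
    return {
        "reference": a.assay, "other": b.assay,
        "n_genes": int(len(x)),
        "slope": beta, "intercept": alpha,
        "mean_log10_ratio": float(log_ratio.mean()),
        "n_log_ratio": int(both.sum()),
    }


def hodges_lehmann(x, y) -> float:
    """Median of all between-sample differences y_j - x_i."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    return float(np.median(y[:, None] - x[None, :]))


def pairwise_shift(assays: list[AssayHeights], min_height: float = 5.0) -> dict:
    """All-pairs shift estimates of log10 peak heights.

    Genes above ``min_height`` in every assay are retained and heights
    log10-transformed.  For each ordered pair (i, j) the Hodges-Lehmann
    shift (log10 of the fold change from i to j), the arithmetic mean
    difference, and the rank-sum z are reported.  Pairs whose condition
    labels differ are flagged "cross"; the mean cross-condition shift is the
    headline attenuation estimate, with an antibody-matched variant when
    antibody labels are available.
    """
    if len(assays) < 2:
        raise ValueError("need at least 2 assays")
    common = assays[0].heights.index
    for a in assays[1:]:
        common = common.intersection(a.heights.index)
    keep = pd.Series(True, index=common)
    for a in assays:
        keep &= a.heights.loc[common] > min_height
    genes = common[keep]
    if len(genes) == 0:
        raise ValueError("no genes above min_height shared by all assays")
    logs = {a.assay: np.log10(a.heights.loc[genes].to_numpy()) for a in assays}
    pairs = []
    for i, ai in enumerate(assays):
        for aj in assays[i + 1:]:
            xi, xj = logs[ai.assay], logs[aj.assay]
            shift = hodges_lehmann(xi, xj)
            pairs.append({
                "from": ai.assay, "to": aj.assay,
                "conditions": (ai.condition, aj.condition),
                "cross_condition": ai.condition != aj.condition,
                "antibody_matched": (ai.antibody is not None
                                     and ai.antibody == aj.antibody),
                "hl_shift": shift,
                "mean_difference": float(xj.mean() - xi.mean()),
                "rank_sum_z": rank_sum(xj, xi)["z"],
            })
    cross = [p for p in pairs if p["cross_condition"]]
    matched = [p for p in cross if p["antibody_matched"]]

    def signed_mean(ps):
        # orient every pair as (unfixed -> fixed) so shifts share a sign
        vals = []
        for p in ps:
            s = p["hl_shift"]
            if p["conditions"][0] != "unfixed" and p["conditions"][1] == "unfixed":
                s = -s
            vals.append(s)
        return float(np.mean(vals)) if vals else None

    return {
        "n_genes": int(len(genes)),
        "pairs": pairs,
        "mean_cross_condition_shift": signed_mean(cross),
        "mean_antibody_matched_shift": signed_mean(matched),
    }
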