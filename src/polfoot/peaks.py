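"""Short-fragment peak calling by local polynomial regression (LOESS).

The short (<120 bp) fragment class forms a single narrow peak at the TSS.
Per gene, the binned profile is smoothed with classical LOESS — for each bin
the ``ceil(span * n)`` nearest bins are fit with a tricube-weighted
polynomial and the fit is evaluated at that bin — and the peak is the argmax
of the smoothed profile.  Two gene filters follow the analysis design: the
fitted peak height must exceed a background threshold (strict >), and the
peak must lie within a maximum distance of the annotated TSS (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Anchor
from .matrix import MatrixSpec, SignalMatrix

__all__ = [
    "PeakConfig",
    "PeakCall",
    "loess_smooth",
    "call_short_fragment_peak",
    "call_peaks",
    "filter_peaks",
]


@dataclass(frozen=True)
class PeakConfig:
    span: float = 0.05              # fraction of bins per local fit
    degree: int = 2                 # local polynomial degree
    background_threshold: float = 5.0  # normalized-coverage units, strict >
    max_tss_distance: int = 500     # bp, inclusive

    def __post_init__(self) -> None:
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if self.background_threshold < 0:
            raise ValueError("background_threshold must be >= 0")


@dataclass(frozen=True)
class PeakCall:
    gene: str
    chrom: str
    peak_position: int      # genomic bp (bin centre)
    tss_offset: int         # oriented bp, downstream positive
    fitted_height: float    # LOESS-fitted value at the peak, floored at 0
    raw_height: float       # raw bin value at the chosen bin
    passes_background: bool
    passes_distance: bool
    strand: str = "+"

    @property
    def retained(self) -> bool:
        return self.passes_background and self.passes_distance


def loess_smooth(y, cfg: PeakConfig | None = None) -> np.ndarray:
    """Classical LOESS on an evenly spaced profile.

    For each point x, the ``q = ceil(span * n)`` nearest points are fit with
    a degree-``cfg.degree`` polynomial under tricube weights
    ``w(u) = (1 - |u|^3)^3`` with ``u`` = distance / max neighbourhood
    distance, and the fit is evaluated at x.  Constant and linear profiles
    are reproduced exactly (a polynomial of degree >= 1 interpolates them).
    """
    cfg = cfg or PeakConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    q = int(np.ceil(cfg.span * n))
    if n < 7 or q < cfg.degree + 1:
        raise ValueError(
            f"too few points for LOESS (n={n}, neighbourhood={q}); "
            "increase span or supply a longer profile"
        )
    out = np.empty(n)

    def fit_at(i: int) -> float:
        lo = max(0, i - q)
        hi = min(n, i + q + 1)
        window = np.arange(lo, hi)
        d = np.abs(window - i)
        keep = np.argsort(d, kind="stable")[:q]
        idx = window[keep]
        xi = (idx - i).astype(float)
        w = _tricube(d[keep])
        # np.polyfit weights multiply residuals, so pass sqrt of tricube
        coeffs = np.polyfit(xi, y[idx], cfg.degree, w=np.sqrt(w))
        return coeffs[-1]  # polynomial evaluated at xi = 0

    # Interior points all use the same neighbourhood offsets, so the fitted
    # value is a fixed linear filter of y: precompute it and convolve.
    d0 = np.abs(np.arange(-q, q + 1))
    keep0 = np.argsort(d0, kind="stable")[:q]
    offs = np.sort(np.arange(-q, q + 1)[keep0])
    left, right = -int(offs[0]), int(offs[-1])
    if n > left + right:
        w0 = _tricube(np.abs(offs))
        X = np.vander(offs.astype(float), cfg.degree + 1, increasing=True)
        WX = X * w0[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T)  # rows: coeffs as filters of y
        kernel = beta[0][::-1]  # evaluate at 0 => intercept row, as convolution
        interior = np.convolve(y, kernel, mode="valid")
        out[left:n - right] = interior
    for i in range(min(left, n)):
        out[i] = fit_at(i)
    for i in range(max(0, n - right), n):
        out[i] = fit_at(i)
    return out


def _tricube(d: np.ndarray) -> np.ndarray:
    dmax = d.max()
    u = d / dmax if dmax > 0 else np.zeros_like(d, dtype=float)
    w = (1 - u.astype(float) ** 3) ** 3
    return np.maximum(w, 1e-12)  # the farthest point gets weight ~0, keep SPD


def call_short_fragment_peak(row: np.ndarray, anchor: Anchor, spec: MatrixSpec,
                             cfg: PeakConfig | None = None) -> PeakCall:
    """Locate the short-fragment peak for one gene.

    ``row`` must be an *oriented* short-class matrix row (bin 0 upstream).
    The peak is the argmax of the LOESS-smoothed row; ties are broken by
    smallest |TSS offset|, then upstream.  Heights are floored at 0.  An
    all-zero row yields a zero-height call failing both filters.
    """
    cfg = cfg or PeakConfig()
    row = np.asarray(row, dtype=float)
    if row.shape != (spec.n_bins,):
        raise ValueError("row length must match the matrix spec")
    if not row.any():
        return PeakCall(anchor.name, anchor.chrom, anchor.position, 0, 0.0, 0.0,
                        False, False, anchor.strand)
    smooth = np.maximum(loess_smooth(row, cfg), 0.0)
    best = smooth.max()
    candidates = np.flatnonzero(smooth == best)
    offsets = np.array([spec.bin_center_offset(int(j)) for j in candidates])
    order = np.lexsort((offsets, np.abs(offsets)))  # |offset| first, upstream next
    j = int(candidates[order[0]])
    off = spec.bin_center_offset(j)
    if anchor.strand == "+":
        pos = anchor.position + off
    else:
        pos = anchor.position - off
    fitted = float(smooth[j])
    return PeakCall(
        gene=anchor.name,
        chrom=anchor.chrom,
        peak_position=int(pos),
        tss_offset=int(off),
        fitted_height=fitted,
        raw_height=float(row[j]),
        passes_background=fitted > cfg.background_threshold,
        passes_distance=abs(off) <= cfg.max_tss_distance,
        strand=anchor.strand,
    )


def call_peaks(m: SignalMatrix, cfg: PeakConfig | None = None) -> list[PeakCall]:
    """Call the short-fragment peak for every row of an oriented matrix."""
    if not m.spec.orient:
        raise ValueError("peak calling requires an oriented matrix (orient=True)")
    cfg = cfg or PeakConfig()
    return [call_short_fragment_peak(m.row(i), m.anchors[i], m.spec, cfg)
            for i in range(len(m))]


def filter_peaks(calls: list[PeakCall], cfg: PeakConfig | None = None):
    """Retain calls passing both the background and TSS-distance filters.

    Returns ``(retained, counts)`` with the gene count surviving each stage,
    mirroring the stepwise gene selection of the analysis.
    """
    counts = {
        "total": len(calls),
        "above_background": sum(c.passes_background for c in calls),
        "above_background_and_near_tss": sum(c.retained for c in calls),
    }
    return [c for c in calls if c.retained], counts


def calls_to_frame(calls: list[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": c.gene, "chrom": c.chrom, "strand": c.strand,
        "peak_position": c.peak_position, "tss_offset": c.tss_offset,
        "fitted_height": c.fitted_height, "raw_height": c.raw_height,
        "passes_background": c.passes_background,
        "passes_distance": c.passes_distance,
    } for c in calls])
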