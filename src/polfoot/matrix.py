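"""Orientation-aware genes x bins signal matrices around anchors.

The window is addressed as ``[anchor - half_window, anchor + half_window)``;
bin ``half_window / bin_size`` starts exactly at the anchor.  Each bin holds
the *mean* per-base value (so peak heights are bin-size invariant).  With
``orient=True`` rows of minus-strand genes are reversed so that bin 0 is
always the most upstream position in gene orientation; the oriented offset
of the centre of bin j is ``-half_window + (j + 0.5) * bin_size`` bp for
both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Anchor
from .coverage import CoverageTrack

__all__ = ["MatrixSpec", "SignalMatrix", "build_matrix", "metaplot"]


@dataclass(frozen=True)
class MatrixSpec:
    half_window: int = 1500
    bin_size: int = 10
    orient: bool = True

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.half_window % self.bin_size != 0:
            raise ValueError("half_window must be divisible by bin_size")

    @property
    def n_bins(self) -> int:
        return 2 * self.half_window // self.bin_size

    def bin_offsets(self) -> np.ndarray:
        """Oriented start offset of each bin relative to the anchor (bp)."""
        return -self.half_window + np.arange(self.n_bins) * self.bin_size

    def bin_center_offset(self, j: int) -> int:
        """Oriented offset of the centre of bin j (bp, floor of midpoint)."""
        return -self.half_window + j * self.bin_size + self.bin_size // 2


class SignalMatrix:
    """Rows = genes, columns = bins of mean normalized coverage."""

    def __init__(self, values: np.ndarray, gene_ids: list[str],
                 anchors: list[Anchor], spec: MatrixSpec,
                 edge_clipped: np.ndarray | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(gene_ids), spec.n_bins):
            raise ValueError("matrix shape must be (n_genes, n_bins)")
        if len(anchors) != len(gene_ids):
            raise ValueError("one anchor per row required")
        self.values = values
        self.gene_ids = list(gene_ids)
        self.anchors = list(anchors)
        self.spec = spec
        self.edge_clipped = (np.zeros(len(gene_ids), dtype=bool)
                             if edge_clipped is None else np.asarray(edge_clipped))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def row(self, i: int) -> np.ndarray:
        return self.values[i]

    def flipped(self) -> "SignalMatrix":
        """Reverse minus-strand rows (toggles between oriented and genomic)."""
        vals = self.values.copy()
        for i, a in enumerate(self.anchors):
            if a.strand == "-":
                vals[i] = vals[i, ::-1]
        spec = MatrixSpec(self.spec.half_window, self.spec.bin_size,
                          not self.spec.orient)
        return SignalMatrix(vals, self.gene_ids, self.anchors, spec,
                            self.edge_clipped)

    def to_frame(self) -> pd.DataFrame:
        cols = [str(o) for o in self.spec.bin_offsets()]
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=cols)
        df.index.name = "gene"
        return df

    def write_tsv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t")


def build_matrix(track: CoverageTrack, anchors: list[Anchor],
                 spec: MatrixSpec | None = None) -> SignalMatrix:
    """Extract per-gene windows around anchors and bin them.

    Windows extending past the track's contig support contribute 0 (rows are
    flagged in ``edge_clipped``).  Anchors on contigs absent from the track
    are dropped with a warning.
    """
    spec = spec or MatrixSpec()
    rows, ids, kept, clipped = [], [], [], []
    for a in anchors:
        if a.chrom not in track:
            warnings.warn(f"anchor {a.name or a.position} on unknown contig "
                          f"{a.chrom!r}: row dropped")
            continue
        start = a.position - spec.half_window
        end = a.position + spec.half_window
        dense = track.values(a.chrom, start, end)
        binned = dense.reshape(spec.n_bins, spec.bin_size).mean(axis=1)
        if spec.orient and a.strand == "-":
            binned = binned[::-1]
        edges, _ = track.data[a.chrom]
        clipped.append(len(edges) > 0 and (start < edges[0] or end > edges[-1]))
        rows.append(binned)
        ids.append(a.name or f"{a.chrom}:{a.position}")
        kept.append(a)
    vals = np.vstack(rows) if rows else np.zeros((0, spec.n_bins))
    return SignalMatrix(vals, ids, kept, spec, np.asarray(clipped, dtype=bool))


def metaplot(m: SignalMatrix) -> pd.DataFrame:
    """Per-bin mean profile across genes (columns: offset, mean, n)."""
    if len(m) == 0:
        raise ValueError("metaplot of an empty matrix")
    return pd.DataFrame({
        "offset": m.spec.bin_offsets(),
        "mean": m.values.mean(axis=0),
        "n": len(m),
    })
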