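"""Fragment input, filtering, genome routing and size fractionation.

CUT&RUN paired-end sequencing recovers the DNA fragments protected by the
antibody-targeted protein complex; the insert size (SAM template length) is
the footprint length.  This module turns aligned read pairs (SAM/BAM) or
pre-extracted fragment tables (TSV) into :class:`FragmentSet` objects,
applying the standard quality filters (proper pair, MAPQ strictly above a
threshold, no multi-mapping XA/SA tags, canonical contigs), routes fragments
to the target or spike-in genome by contig name, and fractionates them into
footprint size classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Fragment",
    "FragmentSet",
    "SizeClassScheme",
    "FilterConfig",
    "DEFAULT_CONTIGS",
    "read_fragments",
    "fractionate",
    "spikein_scale",
    "write_fragments_tsv",
    "read_fragments_tsv",
]

#: Canonical human contigs used by default for the target genome.
DEFAULT_CONTIGS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

_TSV_COLUMNS = ["chrom", "start", "end", "length"]


@dataclass(frozen=True)
class Fragment:
    """One sequenced fragment as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment interval must be non-empty: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """A collection of fragments from one genome (target or spike-in).

    Stored columnar (pandas DataFrame with chrom/start/end/length) since all
    downstream operations are vectorised.
    """

    def __init__(self, df: pd.DataFrame, genome: str = "target",
                 provenance: dict | None = None):
        if genome not in ("target", "spikein"):
            raise ValueError(f"genome must be 'target' or 'spikein', got {genome!r}")
        df = df.reset_index(drop=True)
        missing = [c for c in _TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("all fragment intervals must satisfy start < end")
        if len(df) and not (df["length"] == df["end"] - df["start"]).all():
            raise ValueError("length column must equal end - start")
        self.df = df[_TSV_COLUMNS].copy()
        self.genome = genome
        self.provenance = dict(provenance or {})

    @classmethod
    def from_arrays(cls, chrom, start, end, genome="target", provenance=None):
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        df = pd.DataFrame({
            "chrom": chrom,
            "start": start,
            "end": end,
            "length": end - start,
        })
        return cls(df, genome=genome, provenance=provenance)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Fragment(row.chrom, int(row.start), int(row.end))

    def contigs(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def total_length(self) -> int:
        return int(self.df["length"].sum())

    def sorted(self) -> "FragmentSet":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        return FragmentSet(df, self.genome, self.provenance)

    def subset(self, mask) -> "FragmentSet":
        return FragmentSet(self.df[mask], self.genome, self.provenance)


@dataclass(frozen=True)
class SizeClassScheme:
    """Ordered fragment-length boundaries defining footprint size classes.

    Defaults to the classes used throughout the analysis: [40,120) bp (short,
    poised-polymerase footprint), [120,270), [270,440) (paused-polymerase
    footprints) and [440,inf).  Classes are left-closed/right-open; the last
    class is open-ended; fragments below the first boundary are dropped.
    """

    boundaries: tuple[int, ...] = (40, 120, 270, 440)

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2:
            raise ValueError("need at least 2 boundaries")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        b = self.boundaries
        inner = tuple(f"{b[i]}-{b[i + 1]}" for i in range(len(b) - 1))
        return inner + (f"{b[-1]}+",)


@dataclass(frozen=True)
class FilterConfig:
    """Read-pair filters applied when extracting fragments from alignments.

    ``min_mapq`` is the minimum *retained* MAPQ: the default 21 keeps records
    with mapping quality strictly greater than 20.  ``exclude_tags`` drops
    records carrying alternative/supplementary alignment tags.  Contigs in
    ``allowed_contigs`` route to the target genome, those matching
    ``spikein_contigs`` (exact names) or ``spikein_prefix`` to the spike-in
    genome; everything else is skipped and counted.
    """

    require_proper_pair: bool = True
    min_mapq: int = 21
    exclude_tags: tuple[str, ...] = ("XA", "SA")
    allowed_contigs: tuple[str, ...] = DEFAULT_CONTIGS
    spikein_contigs: tuple[str, ...] = ()
    spikein_prefix: str = "sacCer"
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.allowed_contigs) & set(self.spikein_contigs)
        if overlap:
            raise ValueError(f"contigs listed as both target and spike-in: {overlap}")

    def route(self, contig: str) -> str | None:
        """Return 'target', 'spikein' or None for a contig name."""
        if contig in self.spikein_contigs or (
            self.spikein_prefix and contig.startswith(self.spikein_prefix)
        ):
            return "spikein"
        if contig in self.allowed_contigs:
            return "target"
        return None


def read_fragments(path, filters: FilterConfig | None = None):
    """Read fragments from a SAM/BAM alignment or a fragment TSV.

    Returns ``(target: FragmentSet, spikein: FragmentSet, qc: dict)`` where
    ``qc`` counts records surviving each filter stage.  For alignments, one
    fragment is emitted per template, taken from the leftmost mate (positive
    template length): the interval is ``[pos, pos + TLEN)``.
    """
    filters = filters or FilterConfig()
    path = str(path)
    if path.endswith((".sam", ".bam", ".cram")):
        return _read_alignment(path, filters)
    return _read_tsv_routed(path, filters)


def _read_alignment(path, filters: FilterConfig):
    qc = {
        "records": 0,
        "not_proper_pair": 0,
        "duplicate": 0,
        "low_mapq": 0,
        "excluded_tag": 0,
        "rightmost_mate": 0,
        "zero_template_length": 0,
        "unknown_contig": 0,
        "target_fragments": 0,
        "spikein_fragments": 0,
    }
    rows = {"target": {"chrom": [], "start": [], "end": []},
            "spikein": {"chrom": [], "start": [], "end": []}}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for rec in af:
            qc["records"] += 1
            if rec.is_unmapped:
                qc["not_proper_pair"] += 1
                continue
            if filters.require_proper_pair and not (
                rec.is_paired and rec.is_proper_pair
            ):
                qc["not_proper_pair"] += 1
                continue
            if filters.drop_duplicates and rec.is_duplicate:
                qc["duplicate"] += 1
                continue
            if rec.mapping_quality < filters.min_mapq:
                qc["low_mapq"] += 1
                continue
            if any(rec.has_tag(t) for t in filters.exclude_tags):
                qc["excluded_tag"] += 1
                continue
            tlen = rec.template_length
            if tlen == 0:
                qc["zero_template_length"] += 1
                continue
            if tlen < 0:  # rightmost mate: the leftmost one carries the fragment
                qc["rightmost_mate"] += 1
                continue
            genome = filters.route(rec.reference_name)
            if genome is None:
                qc["unknown_contig"] += 1
                continue
            rows[genome]["chrom"].append(rec.reference_name)
            rows[genome]["start"].append(rec.reference_start)
            rows[genome]["end"].append(rec.reference_start + tlen)
            qc[f"{genome}_fragments"] += 1
    prov = {"source": path, "filters": _filters_dict(filters)}
    target = FragmentSet.from_arrays(
        rows["target"]["chrom"], rows["target"]["start"], rows["target"]["end"],
        genome="target", provenance=prov)
    spike = FragmentSet.from_arrays(
        rows["spikein"]["chrom"], rows["spikein"]["start"], rows["spikein"]["end"],
        genome="spikein", provenance=prov)
    return target, spike, qc


def _read_tsv_routed(path, filters: FilterConfig):
    df = read_fragments_tsv(path)
    route = df["chrom"].map(filters.route)
    qc = {
        "records": len(df),
        "unknown_contig": int(route.isna().sum()),
        "target_fragments": int((route == "target").sum()),
        "spikein_fragments": int((route == "spikein").sum()),
    }
    prov = {"source": str(path), "filters": _filters_dict(filters)}
    target = FragmentSet(df[route == "target"], "target", prov)
    spike = FragmentSet(df[route == "spikein"], "spikein", prov)
    return target, spike, qc


def _filters_dict(filters: FilterConfig) -> dict:
    return {
        "require_proper_pair": filters.require_proper_pair,
        "min_mapq": filters.min_mapq,
        "exclude_tags": list(filters.exclude_tags),
        "spikein_prefix": filters.spikein_prefix,
        "drop_duplicates": filters.drop_duplicates,
    }


def fractionate(fs: FragmentSet, scheme: SizeClassScheme | None = None):
    """Split a fragment set into footprint size classes.

    Returns ``(classes: dict label -> FragmentSet, n_dropped_short: int)``.
    Each fragment with length >= the first boundary lands in exactly one
    left-closed/right-open class; shorter fragments are dropped and counted.
    """
    scheme = scheme or SizeClassScheme()
    b = np.asarray(scheme.boundaries)
    lengths = fs.df["length"].to_numpy()
    idx = np.searchsorted(b, lengths, side="right") - 1  # -1 => below first boundary
    classes = {}
    for i, label in enumerate(scheme.labels):
        classes[label] = fs.subset(idx == i)
    n_dropped = int((idx < 0).sum())
    return classes, n_dropped


def spikein_scale(spike: FragmentSet | int, reference_count: int = 10000) -> float:
    """Spike-in normalization factor: reference_count / spike-in fragment count.

    Coverage multiplied by this factor is expressed "per ``reference_count``
    spike-in fragments", making assays with different recovery comparable.
    """
    n = spike if isinstance(spike, (int, np.integer)) else len(spike)
    if n <= 0:
        raise ValueError(
            "no spike-in fragments: cannot normalize; re-run with spike-in "
            "material or use unnormalized mode (scale=1)"
        )
    return reference_count / n


def write_fragments_tsv(fs: FragmentSet, path, header_comment: str | None = None) -> None:
    """Write a 4-column fragment TSV (chrom, start, end, length)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        fs.df.to_csv(fh, sep="\t", header=False, index=False)


def read_fragments_tsv(path) -> pd.DataFrame:
    """Read a 4-column fragment TSV, tolerating leading '#' comment lines."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chrom": str, "start": np.int64,
                            "end": np.int64, "length": np.int64})
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fragment TSV missing columns {missing}")
    return df


def write_qc_json(qc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
        fh.write("\n")
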