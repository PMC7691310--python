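"""Gene annotation: loading, singleton extraction, TSS anchors.

Metagene analyses around promoters are confounded when two promoters sit in
the same window, so the analysis restricts itself to "singleton" genes —
genes whose interval is separated from every other gene's interval on the
same contig by strictly more than a gap (default 2 kb).  The distance
between two intervals is the number of bases strictly between them
(overlapping or adjacent intervals have distance 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Gene",
    "Anchor",
    "load_genes",
    "select_singletons",
    "tss_anchor",
    "write_bed6",
]


@dataclass(frozen=True)
class Gene:
    """A gene interval, 0-based half-open, with strand and name."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: gene interval must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.name}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Anchor:
    """A strand-aware single-base anchor (here: the TSS)."""

    chrom: str
    position: int
    strand: str
    name: str = ""


def load_genes(path) -> list[Gene]:
    """Load gene records from BED6 (0-based) or GTF (1-based, converted).

    For GTF only ``gene`` features are used.  Duplicate names are
    disambiguated with a numeric suffix so downstream tables stay keyed by
    unique gene id.
    """
    path = str(path)
    if path.endswith((".gtf", ".gtf.gz")):
        genes = _load_gtf(path)
    else:
        genes = _load_bed6(path)
    return _dedupe_names(genes)


def _load_bed6(path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: missing or invalid strand {strand!r}")
            genes.append(Gene(chrom, int(start), int(end), strand, name))
    return genes


def _load_gtf(path) -> list[Gene]:
    try:
        import pyranges
    except ImportError:  # fall back to a minimal gene-feature reader
        return _load_gtf_minimal(path)
    gr = pyranges.read_gtf(path)
    df = gr.df
    df = df[df["Feature"] == "gene"]
    name_col = next((c for c in ("gene_name", "gene_id") if c in df.columns), None)
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = getattr(row, name_col) if name_col else f"gene{i + 1}"
        genes.append(Gene(str(row.Chromosome), int(row.Start), int(row.End),
                          str(row.Strand), str(name)))
    return genes


def _load_gtf_minimal(path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{ln}: malformed GTF line")
            if parts[2] != "gene":
                continue
            chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: missing strand")
            attrs = parts[8] if len(parts) > 8 else ""
            name = None
            for key in ("gene_name", "gene_id"):
                tag = f'{key} "'
                if tag in attrs:
                    name = attrs.split(tag, 1)[1].split('"', 1)[0]
                    break
            genes.append(Gene(chrom, start - 1, end, strand, name or f"gene{ln}"))
    return genes


def _dedupe_names(genes: list[Gene]) -> list[Gene]:
    seen: dict[str, int] = {}
    out = []
    for g in genes:
        n = seen.get(g.name, 0)
        seen[g.name] = n + 1
        out.append(Gene(g.chrom, g.start, g.end, g.strand,
                        g.name if n == 0 else f"{g.name}_{n + 1}"))
    return out


def select_singletons(genes: list[Gene], min_gap: int = 2000) -> list[Gene]:
    """Keep genes separated from every other gene by strictly more than min_gap.

    Gap = bases strictly between the two intervals; overlap or adjacency
    means gap 0.  The check is symmetric, and raising ``min_gap`` can only
    shrink the selection.
    """
    by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        by_contig.setdefault(g.chrom, []).append(g)
    kept = set()
    for contig_genes in by_contig.values():
        order = sorted(range(len(contig_genes)),
                       key=lambda i: (contig_genes[i].start, contig_genes[i].end))
        n = len(order)
        ok = [True] * n
        # a violating neighbour is within min_gap in sorted order; scan both ways
        for a in range(n):
            ga = contig_genes[order[a]]
            for b in range(a + 1, n):
                gb = contig_genes[order[b]]
                gap = gb.start - ga.end  # may be negative on overlap
                if gap > min_gap:
                    # later genes start even further right only in start; but a
                    # long ga could still reach them — gap uses ga.end so safe
                    break
                ok[a] = ok[b] = False
        for a in range(n):
            if ok[a]:
                kept.add(id(contig_genes[order[a]]))
    return [g for g in genes if id(g) in kept]


def tss_anchor(g: Gene) -> Anchor:
    """Strand-aware TSS: interval start for '+', last base (end-1) for '-'."""
    pos = g.start if g.strand == "+" else g.end - 1
    return Anchor(g.chrom, pos, g.strand, g.name)


def write_bed6(genes: list[Gene], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


def genes_to_frame(genes: list[Gene]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.chrom, g.start, g.end, g.name, g.strand) for g in genes],
        columns=["chrom", "start", "end", "name", "strand"],
    )
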