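"""Synthetic CUT&RUN datasets with known per-gene ground truth.

The generator reproduces the footprint geometry the analysis assumes:

* short fragments (poised-polymerase footprint): centres normally jittered
  around the TSS, lengths ~ Normal(80, 15) clipped to [40, 119] bp;
* long fragments (paused-polymerase footprint): centres at the TSS shifted
  ~150 bp downstream (gene orientation) with probability ``pi_down``, else
  upstream, jittered; lengths drawn from a two-component mixture so that
  both quantified size classes carry the paused signal — with probability
  ``mid_fraction`` Normal(200, 30) clipped to [120, 269] bp, otherwise
  Normal(320, 40) clipped to [270, 440] bp;
* uniform background cleavage over the target contig;
* spike-in fragments on a separate contig (for normalization);
* strand-specific nascent tracks whose sense/antisense balance follows the
  same ``pi_down``;
* a multiplicative attenuation factor in (0, 1] scaling every per-gene
  fragment count before half-up rounding (models fixation; background and
  spike-in are left untouched, matching the observation that fixation
  depresses the targeted signal, not the background).

The per-gene truth — ``pi_down``, its log10-odds ``true_skewness`` and the
label it implies under the +-1 thresholds — is written alongside, so
recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as _coverage

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "true_skewness",
           "simulate_assay_heights"]


@dataclass
class SimConfig:
    """Generative parameters; per-gene fields accept a scalar or an array."""

    n_genes: int = 200
    chrom: str = "chr1"
    chrom_length: int | None = None       # auto-sized from spacing if None
    spike_chrom: str = "sacCer3_chrI"
    spike_chrom_length: int = 200_000
    # per gene (scalar broadcast or length-n_genes sequence)
    strand: object = None                 # default: alternate +/-
    n_short: object = 300
    n_long: object = 2000
    pi_down: object = 0.85
    short_len_mean: float = 80.0
    short_len_sd: float = 15.0
    mid_len_mean: float = 200.0
    mid_len_sd: float = 30.0
    long_len_mean: float = 320.0
    long_len_sd: float = 40.0
    mid_fraction: float = 0.5   # share of paused fragments in [120,270) bp
    pause_offset: int = 150
    center_jitter_sd: float = 10.0
    gene_length: int = 1000
    gene_spacing: int = 6000              # >= 2x matrix half-window + 2 kb gap
    margin: int = 4000
    # globals
    background_rate: float = 2e-5         # fragments per bp
    n_spike: int = 10_000
    attenuation: float = 1.0
    nascent_halfwidth: int = 750
    nascent_scale: float = 10.0
    seed: int = 0

    def genes_frame(self) -> pd.DataFrame:
        n = self.n_genes
        if n < 1:
            raise ValueError("n_genes must be >= 1")
        strands = self.strand
        if strands is None:
            strands = ["+" if i % 2 == 0 else "-" for i in range(n)]
        strands = list(np.broadcast_to(np.asarray(strands, dtype=object), n))
        pi = np.broadcast_to(np.asarray(self.pi_down, dtype=float), n).copy()
        n_short = np.broadcast_to(np.asarray(self.n_short), n).astype(int)
        n_long = np.broadcast_to(np.asarray(self.n_long), n).astype(int)
        if np.any((pi < 0) | (pi > 1)):
            raise ValueError("pi_down must lie in [0, 1]")
        if np.any(n_short < 0) or np.any(n_long < 0):
            raise ValueError("fragment counts must be >= 0")
        if any(s not in ("+", "-") for s in strands):
            raise ValueError("strand must be '+' or '-'")
        tss = self.margin + np.arange(n) * self.gene_spacing
        start = np.where([s == "+" for s in strands], tss,
                         tss - self.gene_length + 1)
        end = start + self.gene_length
        return pd.DataFrame({
            "name": [f"gene{i + 1}" for i in range(n)],
            "chrom": self.chrom, "start": start, "end": end,
            "strand": strands, "tss": tss,
            "pi_down": pi, "n_short": n_short, "n_long": n_long,
        })

    def required_length(self) -> int:
        return 2 * self.margin + (self.n_genes - 1) * self.gene_spacing

    def validate(self) -> None:
        if not (0 < self.attenuation <= 1):
            raise ValueError("attenuation must be in (0, 1]")
        if self.background_rate < 0 or self.n_spike < 0:
            raise ValueError("background_rate and n_spike must be >= 0")
        if self.gene_spacing < self.gene_length + 2001:
            raise ValueError("gene_spacing too small for singleton genes (> 2 kb gap)")
        length = self.chrom_length or self.required_length()
        if length < self.required_length():
            raise ValueError(
                f"chrom_length {length} too small: need >= {self.required_length()} "
                f"for {self.n_genes} genes at spacing {self.gene_spacing}")
        self.genes_frame()  # validates per-gene fields

    def resolved_length(self) -> int:
        return self.chrom_length or self.required_length()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON-serializable: {type(v)}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    genes: pd.DataFrame  # name, tss, strand, pi_down, true_skewness, expected_label
    attenuation: float
    n_spike: int
    seed: int


def true_skewness(pi_down: float) -> float:
    """log10 odds of downstream placement, the noise-free skew analogue."""
    if not (0 < pi_down < 1):
        raise ValueError("true skewness is undefined for pi_down in {0, 1}")
    return math.log10(pi_down / (1 - pi_down))


def _expected_label(pi: float, threshold: float = 1.0) -> str:
    if pi <= 0 or pi >= 1:
        return "positive" if pi >= 1 else "negative"
    # compare in pi space: skew >= t  <=>  pi >= 10^t / (1 + 10^t); this is
    # exact at boundary values like pi = 10/11 where log10 round-trips badly
    odds = 10.0 ** threshold
    if pi >= odds / (1 + odds):
        return "positive"
    if pi <= 1 / (1 + odds):
        return "negative"
    return "unclassified"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def simulate_dataset(config: SimConfig, seed: int | None = None,
                     outdir=None, write_sam: bool = False):
    """Generate fragments, annotation, nascent tracks and the truth table.

    Returns ``(fragments: FragmentSet-like DataFrame holder, truth: SimTruth,
    files: dict | None)``.  With ``outdir`` set, writes: fragments.tsv
    (target + spike-in rows in one 4-column table), genes.bed,
    nascent_plus.bedGraph / nascent_minus.bedGraph, truth.tsv,
    sim_config.json, and optionally fragments.sam.  Identical config + seed
    produce byte-identical files.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.genes_frame()
    chrom_len = config.resolved_length()
    att = config.attenuation

    frag_chrom: list[str] = []
    starts: list[np.ndarray] = []
    lengths: list[np.ndarray] = []

    def emit(chrom, s, ln):
        s = np.asarray(s, dtype=np.int64)
        ln = np.asarray(ln, dtype=np.int64)
        s = np.clip(s, 0, None)
        over = s + ln > chrom_len if chrom == config.chrom else None
        if over is not None and over.any():
            s = np.where(over, chrom_len - ln, s)
        frag_chrom.extend([chrom] * len(s))
        starts.append(s)
        lengths.append(ln)

    for g in genes.itertuples(index=False):
        ns = _round_half_up(att * g.n_short)
        nl = _round_half_up(att * g.n_long)
        if ns > 0:
            centers = rng.normal(g.tss, config.center_jitter_sd, ns)
            ln = np.clip(np.rint(rng.normal(config.short_len_mean,
                                            config.short_len_sd, ns)),
                         40, 119).astype(np.int64)
            s = np.rint(centers - ln / 2).astype(np.int64)
            emit(config.chrom, s, ln)
        if nl > 0:
            down = rng.random(nl) < g.pi_down
            sign = 1 if g.strand == "+" else -1
            base = np.where(down, g.tss + sign * config.pause_offset,
                            g.tss - sign * config.pause_offset)
            centers = base + rng.normal(0, config.center_jitter_sd, nl)
            is_mid = rng.random(nl) < config.mid_fraction
            ln_mid = np.clip(np.rint(rng.normal(config.mid_len_mean,
                                                config.mid_len_sd, nl)),
                             120, 269)
            ln_large = np.clip(np.rint(rng.normal(config.long_len_mean,
                                                  config.long_len_sd, nl)),
                               270, 440)
            ln = np.where(is_mid, ln_mid, ln_large).astype(np.int64)
            s = np.rint(centers - ln / 2).astype(np.int64)
            emit(config.chrom, s, ln)

    n_bg = _round_half_up(config.background_rate * chrom_len)
    if n_bg > 0:
        ln = rng.integers(40, 441, n_bg).astype(np.int64)
        s = (rng.random(n_bg) * (chrom_len - ln)).astype(np.int64)
        emit(config.chrom, s, ln)
    if config.n_spike > 0:
        ln = np.clip(np.rint(rng.normal(150, 20, config.n_spike)),
                     100, 200).astype(np.int64)
        s = (rng.random(config.n_spike) * (config.spike_chrom_length - ln)
             ).astype(np.int64)
        emit(config.spike_chrom, s, ln)

    start_arr = (np.concatenate(starts) if starts
                 else np.zeros(0, dtype=np.int64))
    len_arr = (np.concatenate(lengths) if lengths
               else np.zeros(0, dtype=np.int64))
    frags = pd.DataFrame({
        "chrom": frag_chrom,
        "start": start_arr,
        "end": start_arr + len_arr,
        "length": len_arr,
    }).sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    truth_genes = genes[["name", "chrom", "tss", "strand", "pi_down"]].copy()
    with np.errstate(divide="ignore"):
        pi = truth_genes["pi_down"].to_numpy()
        truth_genes["true_skewness"] = np.where(
            (pi > 0) & (pi < 1), np.log10(pi / np.where(pi < 1, 1 - pi, np.nan)),
            np.where(pi >= 1, np.inf, -np.inf))
    truth_genes["expected_label"] = [
        _expected_label(p) for p in truth_genes["pi_down"]]
    truth = SimTruth(truth_genes, att, config.n_spike, config.seed)

    nascent_plus, nascent_minus = _nascent_tracks(config, genes)

    files = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = _write_outputs(config, genes, frags, truth_genes,
                               nascent_plus, nascent_minus, outdir, write_sam)
    return frags, truth, {"nascent_plus": nascent_plus,
                          "nascent_minus": nascent_minus,
                          "genes": genes, "files": files}


def simulate_assay_heights(n_genes: int = 500, attenuation: float = 0.2,
                           noise_sd: float = 0.15,
                           n_unfixed: int = 2, n_fixed: int = 2,
                           seed: int = 0):
    """Per-gene peak heights for unfixed/fixed assay groups.

    Each gene has a latent log10 height ~ Normal(1.5, 0.3); every assay
    observes it with multiplicative lognormal noise (sd ``noise_sd`` of the
    natural log), and fixed assays are additionally attenuated by
    ``attenuation``.  Returns a list of :class:`polfoot.fixation.AssayHeights`
    (unfixed first), alternating antibody labels ab1/ab2 within each group.
    """
    from .fixation import AssayHeights

    if not (0 < attenuation <= 1):
        raise ValueError("attenuation must be in (0, 1]")
    rng = np.random.default_rng(seed)
    base = 10 ** rng.normal(1.5, 0.3, n_genes)
    genes = [f"gene{i + 1}" for i in range(n_genes)]
    assays = []
    for cond, count, factor in (("unfixed", n_unfixed, 1.0),
                                ("fixed", n_fixed, attenuation)):
        for k in range(count):
            noise = np.exp(rng.normal(0.0, noise_sd, n_genes))
            heights = pd.Series(base * factor * noise, index=genes)
            assays.append(AssayHeights(f"{cond}{k + 1}", cond, heights,
                                       antibody=f"ab{k % 2 + 1}"))
    return assays


def _nascent_tracks(config: SimConfig, genes: pd.DataFrame):
    """Constant-level sense/antisense windows around each TSS.

    Sense signal (gene strand) covers the downstream ``nascent_halfwidth``
    with amplitude scale*pi_down; antisense covers the upstream window on
    the opposite strand with amplitude scale*(1 - pi_down).
    """
    hw = config.nascent_halfwidth
    c = config.nascent_scale
    plus: list[tuple[int, int, float]] = []
    minus: list[tuple[int, int, float]] = []
    for g in genes.itertuples(index=False):
        sense_val = c * g.pi_down
        anti_val = c * (1 - g.pi_down)
        down = (g.tss, g.tss + hw)       # genomic right of the TSS
        up = (g.tss - hw, g.tss)
        if g.strand == "+":
            if sense_val > 0:
                plus.append((*down, sense_val))
            if anti_val > 0:
                minus.append((*up, anti_val))
        else:
            if sense_val > 0:
                minus.append((*up, sense_val))   # downstream of a - gene
            if anti_val > 0:
                plus.append((*down, anti_val))
    mk = lambda ivals: _coverage.track_from_intervals(
        {config.chrom: ivals}) if ivals else _coverage.CoverageTrack({})
    return mk(plus), mk(minus)


def _write_outputs(config, genes, frags, truth_genes, plus, minus, outdir,
                   write_sam):
    files = {
        "fragments": outdir / "fragments.tsv",
        "genes": outdir / "genes.bed",
        "nascent_plus": outdir / "nascent_plus.bedGraph",
        "nascent_minus": outdir / "nascent_minus.bedGraph",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.json",
    }
    with open(files["fragments"], "w") as fh:
        fh.write("chrom\tstart\tend\tlength\n")
        frags.to_csv(fh, sep="\t", header=False, index=False)
    with open(files["genes"], "w") as fh:
        for g in genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
    _coverage.write_bedgraph(plus, files["nascent_plus"])
    _coverage.write_bedgraph(minus, files["nascent_minus"])
    truth_genes.to_csv(files["truth"], sep="\t", index=False)
    with open(files["config"], "w") as fh:
        fh.write(config.to_json())
        fh.write("\n")
    if write_sam:
        files["sam"] = outdir / "fragments.sam"
        _write_sam(config, frags, files["sam"])
    return {k: str(v) for k, v in files.items()}


def _write_sam(config: SimConfig, frags: pd.DataFrame, path) -> None:
    """Emit each fragment as a proper read pair (MAPQ 60, TLEN set)."""
    import pysam

    contigs = [(config.chrom, config.resolved_length()),
               (config.spike_chrom, config.spike_chrom_length)]
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contigs],
    })
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, row in enumerate(frags.itertuples(index=False)):
            rlen = min(50, int(row.length))
            for mate in (0, 1):
                a = pysam.AlignedSegment(header)
                a.query_name = f"frag{i + 1}"
                a.reference_name = row.chrom
                a.mapping_quality = 60
                a.cigarstring = f"{rlen}M"
                a.query_sequence = "N" * rlen
                a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
                if mate == 0:
                    a.flag = 99   # paired, proper, mate reverse, first in pair
                    a.reference_start = int(row.start)
                    a.next_reference_start = int(row.end) - rlen
                    a.template_length = int(row.length)
                else:
                    a.flag = 147  # paired, proper, reverse, second in pair
                    a.reference_start = int(row.end) - rlen
                    a.next_reference_start = int(row.start)
                    a.template_length = -int(row.length)
                a.next_reference_name = row.chrom
                out.write(a)
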