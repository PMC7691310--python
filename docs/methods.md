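# Methods

## The measurement model

CUT&RUN tethers micrococcal nuclease to an antibody-bound protein and cuts
the chromatin flanking the target; the released fragment spans the DNA the
protein complex protects, so the paired-end insert size is an in-situ ruler
of complex size. For RNA polymerase II near transcription start sites this
produces two separable footprints:

* a **short footprint** (< 120 bp): a single narrow peak at the TSS,
  attributed to polymerase in the pre-initiation (poised) state on
  nucleosome-depleted DNA;
* a **long footprint** (> 120 bp): a bimodal signal with modes ~150 bp
  upstream and downstream of the TSS, attributed to promoter-proximally
  paused polymerase bound by larger complexes that widen the protected
  region.

The analysis quantifies, per gene, (i) where the short-fragment peak sits,
(ii) how the long-fragment signal is split between the peak's two 500-bp
flanks, and (iii) whether that split agrees with the direction of nascent
transcription measured independently (e.g. mNET-seq).

## Pipeline stages and parameters

| Parameter | Default | Meaning |
|---|---|---|
| size boundaries | 40, 120, 270, 440 bp | footprint classes, left-closed/right-open; < 40 bp dropped |
| MAPQ cut | > 20 (strict) | alignment filter, with proper-pair flag and XA/SA exclusion |
| spike-in reference | 10,000 | coverage is "per 10,000 spike-in fragments" |
| singleton gap | > 2 kb (strict) | bases strictly between gene intervals; overlap ⇒ 0 |
| matrix window / bin | ±1500 bp / 10 bp | TSS-anchored, oriented (minus-strand rows reversed) |
| LOESS span / degree | 0.05 / 2 | fraction of bins per local fit; tricube weights |
| background threshold | 5 (strict >) | on the LOESS-fitted peak height, normalized units |
| TSS distance filter | ≤ 500 bp (inclusive) | peak-to-annotated-TSS distance |
| flank width | 500 bp | S−/S+ windows `[p−500, p)` and `[p, p+500)` |
| skew threshold | ±1 | log10(S+/S−), required in *both* large classes |
| directionality window | ±750 bp | sense/antisense nascent sums around the peak |
| fixation window | ±1500 bp | per-gene max height around the TSS |

Coordinate conventions: all intervals are 0-based half-open. The TSS is the
interval start for `+` genes and `end − 1` for `−` genes. In an oriented
matrix the centre of bin *j* sits at offset `−1500 + 10j + 5` bp, identical
for both strands, so bin indices map to genomic positions without
strand-specific bookkeeping. The peak base itself belongs to the downstream
flank (half-open partition, no gap or overlap).

### LOESS smoothing

For each bin, the `q = ceil(span·n)` nearest bins are fit with a weighted
polynomial (tricube weights `w(u) = (1−|u|³)³`, `u` = distance / largest
neighbourhood distance) and the fit is evaluated at the bin. On an even
grid all interior bins share one neighbourhood shape, so the interior
reduces to a precomputed linear filter (a convolution); edge bins are fit
individually. The two paths solve the same weighted normal equations, and
the unit tests compare the production path against a literal point-by-point
implementation and against statsmodels' lowess. Constant and linear
profiles are reproduced to machine precision. Fitted heights are floored at
0; ties at the smoothed maximum break to the smallest |TSS offset|, then
upstream — a deterministic rule exercised by constructed mirrored profiles.

### Statistics

* **Skew** is undefined (gene excluded, counted) when either flank sum is
  0; a pseudocount mode exists but is off by default because zero flanks
  mostly indicate insufficient coverage, and a pseudocount would
  manufacture signed skews. Flanks follow gene orientation by default
  (downstream = S+); a genomic-coordinate mode is available.
* **Directionality** is the bounded contrast `(sense − antisense)/(sense +
  antisense)`; absolute values are summed because some strand-resolved
  formats store minus-strand coverage negated. Classes are compared with a
  tie-corrected, continuity-corrected normal rank-sum z; when the pooled
  size is small enough the exact tail `P(W′ ≥ W)` is enumerated over all
  label assignments.
* **Fixation attenuation** uses three complementary estimates: OLS of
  fixed on unfixed heights (genes filtered on the *reference* assay so
  selection never acts on the attenuated signal), the mean per-gene log10
  ratio, and Hodges–Lehmann shifts (median of all between-sample
  differences of log10 heights — the location estimate associated with the
  rank-sum test) for every assay pair, with cross-condition pairs flagged
  and summarised both over all pairs and over antibody-matched pairs.

## The simulator

`polfoot.simulate` generates the geometry the analysis assumes, with known
truth per gene:

* short fragments: centres ~ Normal(TSS, 10 bp), lengths ~ Normal(80, 15)
  clipped to [40, 119] bp; 300 per gene by default;
* paused-footprint fragments (2000 per gene by default): centres at
  TSS ± 150 bp — downstream (gene orientation) with probability `pi_down`
  (π) — with 10 bp jitter. Lengths are drawn from a 50/50 mixture of
  Normal(200, 30) clipped to [120, 269] and Normal(320, 40) clipped to
  [270, 440] bp, so that *both* quantified size classes carry the paused
  signal with the same π, which the both-classes classification rule
  requires. The length means are free parameters read off typical
  size distributions, not measured constants;
* uniform background cleavage (2×10⁻⁵ fragments/bp, lengths uniform in
  [40, 440] bp) and spike-in fragments on a separate contig (10,000 by
  default, lengths ~ Normal(150, 20));
* nascent tracks: constant sense signal of amplitude `10·π` over the
  750 bp downstream of the TSS on the gene's strand, antisense
  `10·(1−π)` over the 750 bp upstream on the opposite strand;
* attenuation φ ∈ (0, 1] multiplies the per-gene short and long counts
  (rounded half-up) before sampling. Background and spike-in are left
  unattenuated: fixation suppresses the targeted signal, not background
  cutting, and attenuation is defined relative to the spike-in.

Genes are placed on a regular grid (spacing 6 kb) so all are singletons by
construction; out-of-range lengths are clipped rather than resampled
(distribution tails do not affect class assignment). Identical config and
seed give byte-identical output files.

A separate height-level generator (`simulate_assay_heights`) models the
fixation comparison directly: latent log10 heights ~ Normal(1.5, 0.3),
observed with multiplicative lognormal noise (sd 0.15 of the natural log)
and a condition-dependent attenuation factor.

**What the simulator does not emulate:** sequence content and mappability,
nucleosome positioning, PCR duplicates, alternative TSSs, overlapping
promoters, copy-number variation, or any dependence of fragment recovery
on chromatin state. Passing recovery tests therefore demonstrates the
correctness of the computation under the assumed footprint geometry, not
the biological validity of the geometry itself on real data.

## A measurement property worth knowing

Flank sums are coverage integrals, so a downstream paused fragment of
length ~320 bp centred at +150 bp leaks its first ~10–15 bp into the
upstream flank. This compresses measured skew toward 0: in the [270,440)
class the measured skew saturates near log10(306/14) ≈ 1.34 as π → 1, and
a gene whose true log10 odds sit just above the +1 threshold measures just
*below* it. Genes near the threshold are therefore intrinsically ambiguous
under this statistic — a property of the measurement, not a bug. Recovery
checks consequently place the skewed groups well inside their classes
(π = 0.99 / 0.5 / 0.01, true skew ±2 / 0); with 2000 paused fragments per
gene this yields essentially perfect label recovery, while the two size
classes' skews stay rank-correlated above 0.99 when π varies continuously
across genes.

## Problem sizes

Recovery suites use 200 genes × (300 short + 2000 long) fragments,
spike-in 10,000, and 500 genes for the fixation comparison — sizes at
which the binomial noise of the statistics is a few percent and each suite
completes in seconds, while remaining far below genome scale. The full
genome-scale analysis runs through exactly the same code paths (the
coverage container is run-length, so cost scales with fragments, not
genome length).

## Known limitations

* BigWig input is not parsed natively; convert external tracks to bedGraph
  first (the package reads/writes bedGraph exactly).
* Peak search is confined to the ±1.5 kb matrix window, so "peak" is
  window-relative by construction; genes whose true maximum lies outside
  the window are reported at the window's interior maximum and usually
  removed by the distance filter.
* Whether duplicate-flagged reads should be dropped is data-dependent;
  the flag is honoured by default (`drop_duplicates=True`) and exposed.
* Isoform structure is ignored: annotations must be gene-granular, with
  one TSS per record.
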