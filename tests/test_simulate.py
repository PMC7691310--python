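import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from polfoot.coverage import fragment_coverage
from polfoot.fragments import FragmentSet
from polfoot.peaks import PeakCall
from polfoot.simulate import SimConfig, simulate_dataset, true_skewness
from polfoot.skew import flank_signals, skewness


def file_hashes(d):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(d).iterdir()) if p.is_file()}


class TestTrueSkewness:
    @pytest.mark.parametrize("pi,expected", [
        (0.5, 0.0), (10 / 11, 1.0), (1 / 11, -1.0),
    ])
    def test_worked_values(self, pi, expected):
        assert true_skewness(pi) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("pi", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_pi_rejected(self, pi):
        with pytest.raises(ValueError):
            true_skewness(pi)


class TestConfigValidation:
    def test_attenuation_bounds(self):
        with pytest.raises(ValueError, match="attenuation"):
            SimConfig(attenuation=0.0).validate()
        with pytest.raises(ValueError, match="attenuation"):
            SimConfig(attenuation=1.5).validate()

    def test_pi_bounds(self):
        with pytest.raises(ValueError, match="pi_down"):
            SimConfig(pi_down=1.2).validate()

    def test_chrom_too_small(self):
        with pytest.raises(ValueError, match="chrom_length"):
            SimConfig(n_genes=100, chrom_length=1000).validate()

    def test_spacing_keeps_genes_singleton(self):
        with pytest.raises(ValueError, match="spacing"):
            SimConfig(gene_spacing=2500).validate()


class TestDeterminismAndConservation:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_genes=10, seed=42)
        simulate_dataset(cfg, outdir=tmp_path / "a", write_sam=True)
        simulate_dataset(cfg, outdir=tmp_path / "b", write_sam=True)
        assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        simulate_dataset(SimConfig(n_genes=5, seed=1), outdir=tmp_path / "a")
        simulate_dataset(SimConfig(n_genes=5, seed=2), outdir=tmp_path / "b")
        h1, h2 = file_hashes(tmp_path / "a"), file_hashes(tmp_path / "b")
        assert h1["fragments.tsv"] != h2["fragments.tsv"]

    @pytest.mark.parametrize("attenuation", [1.0, 0.5, 0.2])
    def test_fragment_count_conservation(self, attenuation):
        cfg = SimConfig(n_genes=1, n_short=300, n_long=2000,
                        background_rate=0.0, n_spike=0,
                        attenuation=attenuation, seed=3)
        frags, _, _ = simulate_dataset(cfg)
        assert len(frags) == round(attenuation * (300 + 2000))

    def test_downstream_count_within_binomial_noise(self):
        pi, n_long = 0.95, 2000
        cfg = SimConfig(n_genes=1, n_short=0, n_long=n_long, pi_down=pi,
                        background_rate=0.0, n_spike=0, seed=4)
        frags, truth, _ = simulate_dataset(cfg)
        tss = truth.genes["tss"].iloc[0]
        centers = (frags["start"] + frags["end"]) / 2
        n_down = int((centers > tss).sum())
        sd = math.sqrt(n_long * pi * (1 - pi))
        assert abs(n_down - pi * n_long) <= 3 * sd

    def test_spikein_fragments_on_spike_contig(self):
        cfg = SimConfig(n_genes=2, n_spike=500, seed=5)
        frags, _, _ = simulate_dataset(cfg)
        assert (frags["chrom"] == cfg.spike_chrom).sum() == 500


class TestTruthTable:
    def test_expected_labels_follow_thresholds(self):
        pi = np.array([0.99, 0.5, 0.01, 10 / 11, 1 / 11])
        cfg = SimConfig(n_genes=5, pi_down=pi, seed=6)
        _, truth, _ = simulate_dataset(cfg)
        assert list(truth.genes["expected_label"]) == [
            "positive", "unclassified", "negative", "positive", "negative"]

    def test_true_skewness_finite_iff_pi_interior(self):
        pi = np.array([0.0, 0.5, 1.0])
        _, truth, _ = simulate_dataset(SimConfig(n_genes=3, pi_down=pi, seed=7))
        finite = np.isfinite(truth.genes["true_skewness"])
        assert list(finite) == [False, True, False]


def measured_skews(cfg):
    """Flank skews of the large classes measured at the true TSS."""
    frags, truth, _ = simulate_dataset(cfg)
    long = FragmentSet(frags[(frags["length"] >= 120) & (frags["length"] < 440)
                             & (frags["chrom"] == cfg.chrom)])
    track = fragment_coverage(long)
    out = []
    for g in truth.genes.itertuples(index=False):
        pk = PeakCall(g.name, g.chrom, int(g.tss), 0, 10, 10, True, True,
                      g.strand)
        sm, sp = flank_signals(track, pk)
        out.append(skewness(sp, sm))
    return np.array(out, dtype=float)


def test_mirror_symmetry_of_generated_skew():
    """pi -> 1-pi with flipped strands negates the measured skew
    distribution (within sampling error)."""
    base = dict(n_genes=30, n_short=0, n_long=2000, background_rate=0.0,
                n_spike=0, seed=8)
    a = measured_skews(SimConfig(pi_down=0.9, strand="+", **base))
    b = measured_skews(SimConfig(pi_down=0.1, strand="-", **base))
    assert a.mean() == pytest.approx(-b.mean(), abs=0.05)
    assert a.mean() > 0.5  # sanity: genuinely skewed


def test_emitted_sam_round_trips_through_the_alignment_reader(tmp_path):
    """Fragments written as proper read pairs come back identically through
    the SAM filter chain (flag 3, MAPQ > 20, contig routing)."""
    from polfoot.fragments import read_fragments

    cfg = SimConfig(n_genes=3, n_short=50, n_long=100, n_spike=200, seed=10)
    frags, _, extra = simulate_dataset(cfg, outdir=tmp_path, write_sam=True)
    target, spike, qc = read_fragments(extra["files"]["sam"])
    combined = (pd.concat([target.df, spike.df])
                .sort_values(["chrom", "start", "end"], kind="mergesort")
                .reset_index(drop=True))
    pd.testing.assert_frame_equal(combined, frags)
    assert qc["rightmost_mate"] == len(frags)  # one mate per pair discarded


def test_nascent_tracks_follow_pi(tmp_path):
    from polfoot.coverage import read_bedgraph

    cfg = SimConfig(n_genes=2, pi_down=np.array([0.9, 0.9]),
                    strand=["+", "-"], seed=9)
    _, truth, extra = simulate_dataset(cfg, outdir=tmp_path)
    plus = read_bedgraph(extra["files"]["nascent_plus"])
    minus = read_bedgraph(extra["files"]["nascent_minus"])
    g_plus, g_minus = truth.genes.iloc[0], truth.genes.iloc[1]
    # + gene: sense (plus strand) downstream of the TSS, stronger than antisense
    s = plus.sum(cfg.chrom, g_plus.tss, g_plus.tss + 750)
    a = minus.sum(cfg.chrom, g_plus.tss - 750, g_plus.tss)
    assert s == pytest.approx(9 * a)
    # - gene mirrored
    s2 = minus.sum(cfg.chrom, g_minus.tss - 750, g_minus.tss)
    a2 = plus.sum(cfg.chrom, g_minus.tss, g_minus.tss + 750)
    assert s2 == pytest.approx(9 * a2)
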