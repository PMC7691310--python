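import numpy as np
import pandas as pd
import pytest

from polfoot.fragments import FragmentSet
from polfoot.simulate import SimConfig, simulate_dataset


def make_fragment_set(intervals, chrom="chr1", genome="target"):
    """FragmentSet from [(start, end), ...] on one contig."""
    starts = [s for s, _ in intervals]
    ends = [e for _, e in intervals]
    return FragmentSet.from_arrays([chrom] * len(intervals), starts, ends,
                                   genome=genome)


def brute_force_coverage(intervals, length, scale=1.0):
    """Per-base pile-up oracle: count containing intervals at every base."""
    arr = np.zeros(length)
    for s, e in intervals:
        arr[max(s, 0):min(e, length)] += 1
    return arr * scale


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 30-gene simulated dataset with strong downstream skew, on disk."""
    outdir = tmp_path_factory.mktemp("small_sim")
    cfg = SimConfig(n_genes=30, pi_down=0.99, n_short=300, n_long=2000, seed=7)
    frags, truth, extra = simulate_dataset(cfg, outdir=outdir)
    return {"config": cfg, "frags": frags, "truth": truth, "outdir": outdir,
            **extra}


@pytest.fixture(scope="session")
def mixed_pi_run(tmp_path_factory):
    """Full pipeline run on 90 genes with pi spanning the three classes."""
    from polfoot.pipeline import RunConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("mixed_run")
    n = 200
    pi = np.r_[np.full(70, 0.99), np.full(65, 0.01), np.full(65, 0.5)]
    sim_cfg = SimConfig(n_genes=n, pi_down=pi, n_short=300, n_long=2000, seed=19)
    _, truth, extra = simulate_dataset(sim_cfg, outdir=outdir / "sim")
    files = extra["files"]
    cfg = RunConfig(fragments=files["fragments"], genes=files["genes"],
                    nascent_plus=files["nascent_plus"],
                    nascent_minus=files["nascent_minus"],
                    seed=19, outdir=str(outdir / "out"))
    manifest = run_pipeline(cfg)
    return {"truth": truth, "cfg": cfg, "manifest": manifest,
            "outdir": outdir / "out",
            "peaks": pd.read_csv(outdir / "out" / "peaks.tsv", sep="\t",
                                 comment="#"),
            "skew": pd.read_csv(outdir / "out" / "skewness.tsv", sep="\t",
                                comment="#"),
            "direction": pd.read_csv(outdir / "out" / "directionality.tsv",
                                     sep="\t", comment="#")}
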