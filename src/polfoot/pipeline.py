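"""End-to-end workflow: fragments -> coverage -> peaks -> skew -> direction.

Every run echoes its configuration (and a short hash of it) into the output
directory; stage outputs carry the hash so artifacts from different
configurations cannot be mixed silently.  All randomness flows from the
single seed in the configuration, so a rerun with the same config produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation as _ann
from . import coverage as _cov
from . import direction as _dir
from . import fragments as _frag
from . import matrix as _mat
from . import peaks as _pk
from . import simulate as _sim
from . import skew as _skew

__all__ = ["RunConfig", "run_pipeline", "config_hash"]

SHORT_CLASS = "40-120"


@dataclass
class RunConfig:
    """Aggregated defaults for the whole workflow (one value per knob)."""

    # inputs (fragments may be .tsv or .sam/.bam); simulate=True generates them
    fragments: str | None = None
    genes: str | None = None
    nascent_plus: str | None = None
    nascent_minus: str | None = None
    simulate: bool = False
    n_genes: int = 200
    pi_down: float = 0.85
    attenuation: float = 1.0
    # analysis constants
    size_boundaries: tuple[int, ...] = (40, 120, 270, 440)
    spike_reference: int = 10000
    spikein_prefix: str = "sacCer"
    min_gap: int = 2000
    half_window: int = 1500
    bin_size: int = 10
    span: float = 0.05
    degree: int = 2
    background_threshold: float = 5.0
    max_tss_distance: int = 500
    flank_width: int = 500
    skew_threshold: float = 1.0
    directionality_halfwidth: int = 750
    fixation_halfwidth: int = 1500
    drop_duplicates: bool = True
    seed: int = 0
    outdir: str = "polfoot_run"

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for ln, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{ln}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{ln}: unknown key {key!r}")
                kwargs[key] = _coerce(val, getattr(cls(), key))
        return cls(**kwargs)


def _coerce(text: str, default):
    if isinstance(default, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(default, int) and not isinstance(default, bool):
        return int(text)
    if isinstance(default, float):
        return float(text)
    if isinstance(default, tuple):
        return tuple(int(x) for x in text.split(","))
    if text.lower() in ("none", ""):
        return None
    return text


#: location fields excluded from the config hash: the hash identifies the
#: analysis parameters, not where files happen to live
_PATH_FIELDS = ("fragments", "genes", "nascent_plus", "nascent_minus", "outdir")


def config_hash(cfg: RunConfig) -> str:
    lines = [ln for ln in cfg.to_text().splitlines()
             if ln.split(" =")[0] not in _PATH_FIELDS]
    return hashlib.sha256("\n".join(lines).encode()).hexdigest()[:12]


def _log(msg: str) -> None:
    print(f"[polfoot] {msg}", file=sys.stderr)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage, writing TSV/JSON artifacts into ``cfg.outdir``.

    Returns a manifest dict (also written as ``manifest.json``).  Raises on
    the first stage failure (e.g. zero spike-in fragments at normalization).
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(cfg)
    (out / "run_config.txt").write_text(cfg.to_text())
    manifest = {"config_hash": h, "stages": {}}

    if cfg.simulate:
        sim_cfg = _sim.SimConfig(n_genes=cfg.n_genes, pi_down=cfg.pi_down,
                                 attenuation=cfg.attenuation, seed=cfg.seed)
        _, _, extra = _sim.simulate_dataset(sim_cfg, outdir=out / "sim")
        files = extra["files"]
        cfg = dataclasses.replace(cfg, fragments=files["fragments"],
                                  genes=files["genes"],
                                  nascent_plus=files["nascent_plus"],
                                  nascent_minus=files["nascent_minus"])
        manifest["stages"]["simulate"] = {
            k: str(Path(v).relative_to(out)) for k, v in files.items()}
        _log(f"simulate: {cfg.n_genes} genes -> {files['fragments']}")
    if not cfg.fragments or not cfg.genes:
        raise FileNotFoundError("stage 'input': fragments and genes files required")
    for name in ("fragments", "genes"):
        if not Path(getattr(cfg, name)).exists():
            raise FileNotFoundError(f"stage 'input': missing {name} file "
                                    f"{getattr(cfg, name)!r}")

    filters = _frag.FilterConfig(spikein_prefix=cfg.spikein_prefix,
                                 drop_duplicates=cfg.drop_duplicates)
    target, spike, qc = _frag.read_fragments(cfg.fragments, filters)
    _frag.write_qc_json({**qc, "config_hash": h}, out / "fragments_qc.json")
    _log(f"fragments: {len(target)} target, {len(spike)} spike-in")

    scale = _frag.spikein_scale(spike, cfg.spike_reference)
    manifest["stages"]["normalization"] = {"scale": scale,
                                           "n_spikein": len(spike)}
    _log(f"normalization: scale={scale:.4g}")

    scheme = _frag.SizeClassScheme(tuple(cfg.size_boundaries))
    classes, n_dropped = _frag.fractionate(target, scheme)
    tracks = {}
    for label, fs in classes.items():
        tracks[label] = _cov.fragment_coverage(fs, scale,
                                               {"size_class": label})
        _cov.write_bedgraph(tracks[label], out / f"coverage_{label}.bedGraph")
    manifest["stages"]["fractionate"] = {
        **{k: len(v) for k, v in classes.items()},
        "dropped_below_min": n_dropped}
    _log("fractionate: " + ", ".join(f"{k}:{len(v)}" for k, v in classes.items()))

    genes = _ann.load_genes(cfg.genes)
    singletons = _ann.select_singletons(genes, cfg.min_gap)
    _ann.write_bed6(singletons, out / "singletons.bed")
    anchors = [_ann.tss_anchor(g) for g in singletons]
    manifest["stages"]["annotation"] = {"genes": len(genes),
                                        "singletons": len(singletons)}
    _log(f"annotation: {len(genes)} genes, {len(singletons)} singletons")

    spec = _mat.MatrixSpec(cfg.half_window, cfg.bin_size, orient=True)
    short_label = scheme.labels[0]
    short_matrix = _mat.build_matrix(tracks[short_label], anchors, spec)
    short_matrix.write_tsv(out / "matrix_short.tsv", f"config={h}")
    _mat.metaplot(short_matrix).to_csv(out / "metaplot_short.tsv", sep="\t",
                                       index=False)

    pk_cfg = _pk.PeakConfig(cfg.span, cfg.degree, cfg.background_threshold,
                            cfg.max_tss_distance)
    calls = _pk.call_peaks(short_matrix, pk_cfg)
    retained, counts = _pk.filter_peaks(calls, pk_cfg)
    df = _pk.calls_to_frame(calls)
    with open(out / "peaks.tsv", "w") as fh:
        fh.write(f"# config={h}\n")
        df.to_csv(fh, sep="\t", index=False)
    manifest["stages"]["peaks"] = counts
    _log(f"peaks: {counts}")

    mid_label, large_label = scheme.labels[1], scheme.labels[2]
    records = _skew.skew_table(tracks[mid_label], tracks[large_label],
                               retained, cfg.flank_width, cfg.skew_threshold)
    with open(out / "skewness.tsv", "w") as fh:
        fh.write(f"# config={h}\n")
        _skew.records_to_frame(records).to_csv(fh, sep="\t", index=False)
    counts = _skew.class_counts(records)
    manifest["stages"]["skewness"] = counts
    _log(f"skewness: {counts}")

    if cfg.nascent_plus and cfg.nascent_minus:
        plus = _cov.read_bedgraph(cfg.nascent_plus, absolute=True)
        minus = _cov.read_bedgraph(cfg.nascent_minus, absolute=True)
        dir_records = _dir.directionality_table(plus, minus, retained,
                                                cfg.directionality_halfwidth)
        with open(out / "directionality.tsv", "w") as fh:
            fh.write(f"# config={h}\n")
            _dir.records_to_frame(dir_records).to_csv(fh, sep="\t", index=False)
        labels = {r.gene: r.label for r in records}
        summary = _dir.concordance(labels, dir_records)
        manifest["stages"]["directionality"] = summary
        with open(out / "concordance.json", "w") as fh:
            json.dump({"config_hash": h, **summary}, fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
        _log("directionality: "
             + ", ".join(f"{k}:n={v['n']}" for k, v in
                         summary["per_class"].items()))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def check_config_hash(path, expected: str) -> None:
    """Refuse to consume a stage output produced under a different config."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config=") and first.strip() != f"# config={expected}":
        raise ValueError(f"{path}: config hash mismatch "
                         f"({first.strip()!r} != 'config={expected}')")
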