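"""End-to-end orchestration: scan -> candidates -> duplexes -> report.

The genome is scanned fragment by fragment (10,000 nt, 500-nt overlap);
each fragment's cleavage signals are checkpointed as a JSON file so an
interrupted run resumes without recomputation and produces a byte-identical
report.  Fragment scanning can run on several workers; results are merged
by genomic key, so the report is independent of worker count and
scheduling order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import multiprocessing
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import duplex as dx
from . import hairpin as hp
from .io import (GenomeFragment, Library, MirbaseSet, fragment_chromosome,
                 load_mirbase, read_collapsed, read_genome)
from .report import annotate_known, calls_to_records, write_report
from .scan import CleavageSignal, dedupe_signals, scan_fragment


@dataclass
class RunConfig:
    """All pipeline inputs and parameters (defaults are the published
    operating point: 5x flank ratio, top-12 rank, 70% stem complementarity,
    1 RPM AGO floor at 3x enrichment, 10,000/500 fragmenting)."""

    genome: str = ""
    degradome: list[str] = field(default_factory=list)
    srna: list[str] = field(default_factory=list)
    ago: str | None = None
    control: str | None = None
    mirbase_hairpin: str | None = None
    mirbase_mature: str | None = None
    species_prefix: str = ""
    outdir: str = "digger_out"
    L: int | None = None  # override; default = longest registered hairpin
    flank_w: int = 50
    ratio: float = 5.0
    rank_k: int = 12
    agg: str = "mean"
    stem_threshold: float = 0.70
    len_min: int = 18
    len_max: int = 25
    ago_min_rpm: float = 1.0
    ago_fold: float = 3.0
    max_unpaired: float = 0.5
    fold_backend: str = "auto"
    workers: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


# module-level worker state for multiprocessing (fork-safe, read-only)
_WORKER: dict = {}


def _scan_worker_init(libs: list[Library], params: dict) -> None:
    _WORKER["libs"] = libs
    _WORKER["params"] = params


def _scan_one(frag: GenomeFragment) -> tuple[str, int, list[dict]]:
    p = _WORKER["params"]
    signals = scan_fragment(frag, _WORKER["libs"], p["flank_w"], p["ratio"],
                            p["rank_k"], p["agg"])
    return frag.chrom, frag.start, [dataclasses.asdict(s) for s in signals]


def _fragment_marker(outdir: Path, chrom: str, start: int) -> Path:
    return outdir / "checkpoints" / f"{chrom}_{start}.json"


def scan_genome(
    config: RunConfig,
    genome: dict[str, str],
    degradome_libs: list[Library],
    outdir: Path,
) -> list[CleavageSignal]:
    """Scan all fragments for cleavage signals, honouring per-fragment
    checkpoints; returns the deduplicated genome-wide signal set."""
    (outdir / "checkpoints").mkdir(parents=True, exist_ok=True)
    fragments = [f for chrom, seq in sorted(genome.items())
                 for f in fragment_chromosome(chrom, seq)]
    pending = []
    for frag in fragments:
        marker = _fragment_marker(outdir, frag.chrom, frag.start)
        if marker.exists():
            try:
                data = json.loads(marker.read_text())
                if data.get("complete"):
                    continue
            except (json.JSONDecodeError, OSError):
                pass  # corrupted marker: reprocess with a fresh scan
        pending.append(frag)

    params = {"flank_w": config.flank_w, "ratio": config.ratio,
              "rank_k": config.rank_k, "agg": config.agg}
    if config.workers > 1 and len(pending) > 1:
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(config.workers, _scan_worker_init,
                      (degradome_libs, params)) as pool:
            results = pool.map(_scan_one, pending)
    else:
        _scan_worker_init(degradome_libs, params)
        results = [_scan_one(f) for f in pending]
    for chrom, start, sigs in results:
        marker = _fragment_marker(outdir, chrom, start)
        marker.write_text(json.dumps(
            {"complete": True, "chrom": chrom, "start": start,
             "signals": sigs}, sort_keys=True))

    signals: list[CleavageSignal] = []
    for frag in fragments:
        marker = _fragment_marker(outdir, frag.chrom, frag.start)
        data = json.loads(marker.read_text())
        signals.extend(CleavageSignal(**s) for s in data["signals"])
    return dedupe_signals(signals)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every stage and write the report; returns the report table."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config)
    genome = read_genome(config.genome)
    degradome_libs = [read_collapsed(p, "degradome") for p in config.degradome]
    if not degradome_libs:
        raise ValueError("at least one degradome library is required")
    srna_libs = [read_collapsed(p, "srna") for p in config.srna]
    if not srna_libs:
        raise ValueError("at least one sRNA library is required")
    ago_lib = read_collapsed(config.ago, "ago") if config.ago else None
    control_lib = (read_collapsed(config.control, "control")
                   if config.control else None)
    mirbase: MirbaseSet | None = None
    if config.mirbase_hairpin and config.mirbase_mature:
        mirbase = load_mirbase(config.mirbase_hairpin, config.mirbase_mature,
                               config.species_prefix)
    L = config.L if config.L is not None else (
        mirbase.longest_hairpin_len if mirbase else None)
    if L is None:
        raise ValueError("parameter L: supply miRBase files or an explicit L")
    L = max(L, hp.MIN_CANDIDATE_LEN)

    signals = scan_genome(config, genome, degradome_libs, outdir)

    candidates: list[hp.PrecursorCandidate] = []
    for sig in signals:
        candidates.extend(hp.candidate_windows(sig, L, genome[sig.chrom]))
    scored = [
        hp.score_candidate(hp.fold_candidate(c, config.fold_backend),
                           config.stem_threshold)
        for c in candidates
    ]
    retained = hp.filter_candidates(scored, config.stem_threshold)

    calls: list[dx.DuplexCall] = []
    for lib in srna_libs:
        for cand in retained:
            placements = dx.map_srna(cand, lib, config.len_min, config.len_max)
            clusters = dx.cluster_reads(placements)
            call = dx.call_duplex(cand, clusters, config.max_unpaired)
            if call is None:
                continue
            call = dx.ago_filter(call, ago_lib, control_lib,
                                 config.ago_min_rpm, config.ago_fold)
            call = dataclasses.replace(call, library=lib.name)
            if mirbase is not None:
                call = annotate_known(call, mirbase)
            calls.append(call)
    calls = _dedupe_calls(calls)

    records = calls_to_records(calls)
    write_report(records, outdir)
    manifest = {
        "config": config.to_dict(),
        "L": L,
        "n_signals": len(signals),
        "n_candidates": len(candidates),
        "n_retained": len(retained),
        "n_calls": len(calls),
        "inputs": {p: _checksum(p) for p in
                   [config.genome, *config.degradome, *config.srna]
                   + [x for x in (config.ago, config.control) if x]},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                    sort_keys=True))
    return records


def _dedupe_calls(calls: list[dx.DuplexCall]) -> list[dx.DuplexCall]:
    """One call per (library, trimmed precursor locus), keeping the call
    with the most abundant mature (a duplex found from both of its scar
    anchors would otherwise be reported twice, once mirrored)."""
    best: dict[tuple, dx.DuplexCall] = {}
    for c in calls:
        key = (c.library, c.candidate.chrom, c.candidate.strand,
               c.precursor_span)
        prev = best.get(key)
        if prev is None or (c.mature.rpm, c.mature.sequence) > (
                prev.mature.rpm, prev.mature.sequence):
            best[key] = c
    return [best[k] for k in sorted(best)]


def resume(outdir: str | Path) -> pd.DataFrame:
    """Resume an interrupted run from its manifest-recorded configuration;
    only fragments without completion markers are rescanned."""
    outdir = Path(outdir)
    manifest = outdir / "manifest.json"
    config_path = outdir / "run_config.yaml"
    if manifest.exists():
        cfg = RunConfig(**json.loads(manifest.read_text())["config"])
    elif config_path.exists():
        cfg = RunConfig.from_yaml(config_path)
    else:
        raise FileNotFoundError(f"no manifest or run_config.yaml in {outdir}")
    return run_pipeline(cfg)


def save_config(config: RunConfig) -> None:
    """Persist the configuration into the output directory so an
    interrupted run can be resumed before the manifest exists."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
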