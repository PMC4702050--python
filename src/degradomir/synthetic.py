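"""Seeded synthetic fixtures: genomes with planted hairpins, degradome
libraries with Dicer scars, isomiR-scattered sRNA libraries and AGO/control
pairs.

The generator emulates the data a degradome-guided miRNA screen consumes:

* a random background genome with ``n_hairpins`` planted inverted-repeat
  precursors (perfect stems) hosting a mature/star pair in canonical 2-nt
  3' overhang geometry, on either strand;
* a degradome library whose tag 5' ends mark the four Dicer cut positions
  of each planted duplex, over a Poisson background of single-count tags.
  The duplex 5' ends carry ``scar_rpm_fold`` times the background count and
  the 3' ends a minor 2x count, mirroring the empirical dominance of
  5'-end signatures (equal counts at all four ends would mutually suppress
  under the 5x flank criterion, since the scars sit well within one flank
  window of each other);
* sRNA libraries where the planted mature dominates its locus and isomiRs
  decay geometrically (ratio 0.5) with 5'-end shifts up to
  ``isomir_spread``; star reads sit at the exact overhang coordinates at
  lower abundance;
* an AGO-IP/control pair in which planted mature/star reads are >= 3x
  enriched over a uniform control.

Every output is a plain (sequence, count) record list or FASTA/TSV file in
the dialects the IO layer reads, plus a truth table sufficient to score
recall/precision without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .util import revcomp

BASES = np.array(list("ACGT"))

MATURE_OFFSET = 5  # mature 5' end sits 5 nt into the lower stem arm
SCAR_TAG_LEN = 20
MINOR_SCAR_COUNT = 2


@dataclass
class PlantSpec:
    """Parameters of one synthetic dataset."""

    n_hairpins: int = 20
    genome_len: int = 500_000
    chrom: str = "chr1"
    mature_len: int = 21
    stem_len: int = 42
    loop_len: int = 12
    scar_rpm_fold: float = 10.0
    isomir_spread: int = 2
    background_tag_rate: float = 2.0  # tags per kb (both strands combined)
    mature_count: int = 100
    star_count: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hairpins", "genome_len", "mature_len", "stem_len",
                     "loop_len", "isomir_spread", "mature_count", "star_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mature_len + MATURE_OFFSET > self.stem_len:
            raise ValueError("stem too short to host the mature miRNA")
        if self.hairpin_len >= self.genome_len:
            raise ValueError("hairpin longer than genome")

    @property
    def hairpin_len(self) -> int:
        return 2 * self.stem_len + self.loop_len


@dataclass
class PlantedHairpin:
    """Ground truth for one planted precursor (all coords 0-based)."""

    hairpin_id: str
    chrom: str
    strand: str
    start: int  # genomic half-open span of the hairpin
    end: int
    hairpin_seq: str  # transcript orientation
    mature_seq: str
    star_seq: str
    mature_local: tuple[int, int]  # hairpin coords, half-open
    star_local: tuple[int, int]
    cut_positions: tuple[int, ...]  # 5' ends of the four intermediates (local)

    def to_genomic(self, t: int) -> int:
        """Transcript coordinate -> genomic coordinate."""
        return self.start + t if self.strand == "+" else self.end - 1 - t


@dataclass
class Truth:
    spec: PlantSpec
    genome: dict[str, str]
    hairpins: list[PlantedHairpin] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = [{
            "hairpin_id": h.hairpin_id, "chrom": h.chrom, "strand": h.strand,
            "start": h.start, "end": h.end, "mature_seq": h.mature_seq,
            "star_seq": h.star_seq,
        } for h in self.hairpins]
        return pd.DataFrame(
            rows, columns=["hairpin_id", "chrom", "strand", "start", "end",
                           "mature_seq", "star_seq"])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _build_hairpin(rng: np.random.Generator, spec: PlantSpec) -> dict:
    """One perfect inverted-repeat hairpin with canonical duplex geometry."""
    lower = _random_seq(rng, spec.stem_len)
    loop = _random_seq(rng, spec.loop_len)
    hairpin = lower + loop + revcomp(lower)
    n = len(hairpin)
    m5 = MATURE_OFFSET
    m3 = m5 + spec.mature_len - 1  # inclusive
    # perfect stem: position i pairs with n-1-i
    s5 = n - 1 - (m3 - 2)
    s3 = (n - 1 - m5) + 2
    return {
        "seq": hairpin,
        "mature": (m5, m3 + 1),
        "star": (s5, s3 + 1),
        "cuts": (m5, m3 + 1, s5, s3 + 1),
    }


def make_genome(spec: PlantSpec) -> Truth:
    """Random genome with disjoint planted hairpins and its truth table."""
    rng = np.random.default_rng(spec.seed)
    genome = list(_random_seq(rng, spec.genome_len))
    truth = Truth(spec=spec, genome={})
    n = spec.hairpin_len
    margin = 200  # keep planted loci apart and off chromosome ends
    slots: list[tuple[int, int]] = []
    attempts = 0
    while len(slots) < spec.n_hairpins:
        attempts += 1
        if attempts > 10_000 * max(1, spec.n_hairpins):
            raise ValueError("cannot place hairpins: genome too small")
        g = int(rng.integers(margin, spec.genome_len - n - margin))
        if all(g + n + margin <= s or e + margin <= g for s, e in slots):
            slots.append((g, g + n))
    slots.sort()
    for i, (g, _) in enumerate(slots):
        h = _build_hairpin(rng, spec)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = h["seq"] if strand == "+" else revcomp(h["seq"])
        genome[g:g + n] = list(planted)
        truth.hairpins.append(PlantedHairpin(
            hairpin_id=f"syn-MIR{i + 1:04d}",
            chrom=spec.chrom, strand=strand, start=g, end=g + n,
            hairpin_seq=h["seq"],
            mature_seq=h["seq"][h["mature"][0]:h["mature"][1]],
            star_seq=h["seq"][h["star"][0]:h["star"][1]],
            mature_local=h["mature"], star_local=h["star"],
            cut_positions=h["cuts"],
        ))
    truth.genome = {spec.chrom: "".join(genome)}
    return truth


def _tag_at(genome: str, pos: int, strand: str, length: int = SCAR_TAG_LEN) -> str | None:
    """Genome tag whose 5' end sits at ``pos`` on ``strand``."""
    if strand == "+":
        s, e = pos, pos + length
    else:
        s, e = pos - length + 1, pos + 1
    if s < 0 or e > len(genome):
        return None
    seq = genome[s:e]
    return seq if strand == "+" else revcomp(seq)


def make_degradome(spec: PlantSpec, truth: Truth) -> list[tuple[str, int]]:
    """Collapsed degradome records: scar tags at the four duplex ends of
    each planted hairpin plus Poisson background tags of count 1."""
    rng = np.random.default_rng(spec.seed + 1)
    genome = truth.genome[spec.chrom]
    counts: dict[str, int] = {}

    def add(seq: str | None, c: int) -> None:
        if seq and "N" not in seq:
            counts[seq] = counts.get(seq, 0) + c

    major = max(1, int(round(spec.scar_rpm_fold)))
    for h in truth.hairpins:
        local5 = (h.cut_positions[0], h.cut_positions[2])  # duplex 5' ends
        local3 = (h.cut_positions[1], h.cut_positions[3])
        for t in local5:
            add(_tag_at(genome, h.to_genomic(t), h.strand), major)
        for t in local3:
            add(_tag_at(genome, h.to_genomic(t), h.strand), MINOR_SCAR_COUNT)
    n_bg = rng.poisson(spec.background_tag_rate * spec.genome_len / 1000)
    for _ in range(int(n_bg)):
        pos = int(rng.integers(0, spec.genome_len))
        strand = "+" if rng.random() < 0.5 else "-"
        add(_tag_at(genome, pos, strand), 1)
    return sorted(counts.items())


def make_srna(
    spec: PlantSpec, truth: Truth, background_reads: int | None = None
) -> tuple[list[tuple[str, int]], list[tuple[str, int]], list[tuple[str, int]]]:
    """(srna, ago, control) collapsed-read record lists.

    The main library carries the mature (dominant), its isomiRs with 5'
    shifts up to ``isomir_spread`` at geometrically decaying counts (ratio
    0.5), the star at the exact overhang coordinates, star isomiRs, and
    random background reads.  The AGO library is mature/star-enriched; the
    control is uniform low-count.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genome = truth.genome[spec.chrom]
    if background_reads is None:
        background_reads = spec.genome_len // 2000

    srna: dict[str, int] = {}
    ago: dict[str, int] = {}
    control: dict[str, int] = {}

    def add(d: dict[str, int], seq: str | None, c: int) -> None:
        if seq and c > 0 and "N" not in seq:
            d[seq] = d.get(seq, 0) + c

    for h in truth.hairpins:
        hp = h.hairpin_seq
        for (lo, hi), base in ((h.mature_local, spec.mature_count),
                               (h.star_local, spec.star_count)):
            for d in range(-spec.isomir_spread, spec.isomir_spread + 1):
                s, e = lo + d, hi + d
                if s < 0 or e > len(hp):
                    continue
                count = int(round(base * 0.5 ** abs(d)))
                add(srna, hp[s:e], count)
        add(ago, h.mature_seq, spec.mature_count // 2)
        add(ago, h.star_seq, max(1, spec.star_count // 2))
        add(control, h.mature_seq, 1)
        add(control, h.star_seq, 1)
    # the control is dominated by a diffuse background so that the planted
    # reads' control RPM stays well below a third of their AGO RPM
    for _ in range(background_reads):
        length = int(rng.integers(18, 26))
        pos = int(rng.integers(0, spec.genome_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[pos:pos + length]
        if strand == "-":
            seq = revcomp(seq)
        add(srna, seq, 1)
        if rng.random() < 0.25:
            add(ago, seq, 1)
        add(control, seq, 4)
    return sorted(srna.items()), sorted(ago.items()), sorted(control.items())


def write_collapsed_tsv(path: str | Path, records: list[tuple[str, int]]) -> None:
    with open(path, "w") as fh:
        for seq, count in records:
            fh.write(f"{seq}\t{count}\n")


def write_fixture_set(spec: PlantSpec, outdir: str | Path) -> dict[str, Path]:
    """Materialise a complete fixture set (genome, libraries, miRBase-style
    files, truth table) in the dialects the IO layer reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_genome(spec)
    paths = {
        "genome": outdir / "genome.fa",
        "degradome": outdir / "degradome.tsv",
        "srna": outdir / "srna.tsv",
        "ago": outdir / "ago.tsv",
        "control": outdir / "control.tsv",
        "hairpin_fa": outdir / "hairpin.fa",
        "mature_fa": outdir / "mature.fa",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["genome"], "w") as fh:
        for chrom, seq in truth.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_collapsed_tsv(paths["degradome"], make_degradome(spec, truth))
    srna, ago, control = make_srna(spec, truth)
    write_collapsed_tsv(paths["srna"], srna)
    write_collapsed_tsv(paths["ago"], ago)
    write_collapsed_tsv(paths["control"], control)
    with open(paths["hairpin_fa"], "w") as fh:
        for h in truth.hairpins:
            fh.write(f">{h.hairpin_id}\n{h.hairpin_seq}\n")
    with open(paths["mature_fa"], "w") as fh:
        for h in truth.hairpins:
            mid = h.hairpin_id.replace("MIR", "miR")
            fh.write(f">{mid}\n{h.mature_seq}\n")
            fh.write(f">{mid}*\n{h.star_seq}\n")
    truth.table().to_csv(paths["truth"], sep="\t", index=False)
    return paths
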