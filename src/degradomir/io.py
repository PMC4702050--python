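"""Input formats, HTS pre-treatment and genome fragmentation.

Degradome (PARE) and small-RNA libraries arrive as *collapsed reads*: one
record per distinct sequence with its raw read count.  Two dialects are
accepted:

* FASTA with the count encoded in the header, ``>id_count`` or ``>id-count``
  (the convention used by GEO sRNA deposits);
* two-column TSV, ``sequence<TAB>count``.

Pre-treatment discards reads containing N and reads with a zero count, maps
U to T, uppercases, merges duplicate sequences, and normalises to reads per
million (RPM) over the *retained* raw total, so that every library's RPMs
sum to 1e6.

Genomes are scanned in 10,000-nt fragments with 500-nt overlaps so that no
precursor-sized locus is split between fragments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .util import to_dna

FRAGMENT_SIZE = 10_000
FRAGMENT_OVERLAP = 500
FRAGMENT_STEP = FRAGMENT_SIZE - FRAGMENT_OVERLAP

LIBRARY_KINDS = ("degradome", "srna", "ago", "control")


class FormatError(ValueError):
    """Raised for malformed input files."""


class EmptyLibraryError(ValueError):
    """Raised when pre-treatment leaves a library with no reads."""


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct sequence with its raw count and RPM."""

    sequence: str
    raw_count: int
    rpm: float


@dataclass
class Library:
    """A pre-treated collapsed-read library.

    ``total_raw`` is the sum of raw counts of the retained reads; it is the
    RPM denominator, so sum(rpm) == 1e6 for every library.
    """

    name: str
    kind: str
    reads: list[CollapsedRead] = field(default_factory=list)
    total_raw: int = 0

    def rpm_of(self, sequence: str) -> float:
        """RPM of an exact sequence, 0.0 if absent."""
        return self._index().get(sequence, 0.0)

    def _index(self) -> dict[str, float]:
        idx = getattr(self, "_rpm_index", None)
        if idx is None:
            idx = {r.sequence: r.rpm for r in self.reads}
            object.__setattr__(self, "_rpm_index", idx)
        return idx


@dataclass(frozen=True)
class GenomeFragment:
    chrom: str
    start: int  # 0-based inclusive genomic offset
    sequence: str
    is_last: bool

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class MirbaseSet:
    """Hairpin and mature sequences for one species.

    ``longest_hairpin_len`` is the species parameter L: the candidate
    windows extracted around each cleavage signal are (30+L) nt long.
    """

    hairpins: dict[str, str]
    matures: dict[str, str]
    longest_hairpin_len: int


def pretreat_library(
    records: Iterable[tuple[str, int]], kind: str, name: str = "library"
) -> Library:
    """Pre-treat raw (sequence, count) records into a normalised Library.

    Reads containing N (after U->T/uppercase) and reads with count 0 are
    discarded; duplicate sequences are merged by summing counts; RPM is
    computed over the retained raw total.
    """
    if kind not in LIBRARY_KINDS:
        raise ValueError(f"unknown library kind {kind!r}")
    counts: dict[str, int] = {}
    for seq, count in records:
        seq = to_dna(str(seq))
        count = int(count)
        if count < 0:
            raise FormatError(f"{name}: negative read count for {seq}")
        if count == 0 or not seq or not set(seq) <= set("ACGT"):
            continue
        counts[seq] = counts.get(seq, 0) + count
    if not counts:
        raise EmptyLibraryError(f"no reads left after pre-treatment of {name!r}")
    total = sum(counts.values())
    reads = [
        CollapsedRead(seq, c, c / total * 1e6)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return Library(name=name, kind=kind, reads=reads, total_raw=total)


_HEADER_COUNT = re.compile(r"^(?P<id>.*?)[_-](?P<count>\d+)$")


def read_collapsed(path: str | Path, kind: str, name: str | None = None) -> Library:
    """Read a collapsed-read file (FASTA with header counts, or TSV) and
    pre-treat it."""
    path = Path(path)
    name = name or path.stem
    text = path.read_text()
    records: list[tuple[str, int]] = []
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _HEADER_COUNT.match(rec.id)
            if not m:
                raise FormatError(
                    f"{path}: FASTA header {rec.id!r} carries no _count/-count suffix"
                )
            records.append((str(rec.seq), int(m.group("count"))))
    else:
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'sequence<TAB>count'")
            try:
                records.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad count {parts[1]!r}") from exc
    return pretreat_library(records, kind, name=name)


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a multi-record genome FASTA into {chrom: DNA sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate sequence ID {rec.id!r}")
        genome[rec.id] = to_dna(str(rec.seq))
    if not genome:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def fragment_chromosome(chrom: str, sequence: str) -> Iterator[GenomeFragment]:
    """Split one chromosome into 10,000-nt fragments with 500-nt overlaps.

    Fragment starts are 0, 9500, 19000, ...; the last fragment may be
    shorter and is flagged ``is_last``.
    """
    n = len(sequence)
    start = 0
    while True:
        end = min(start + FRAGMENT_SIZE, n)
        is_last = end == n
        yield GenomeFragment(chrom, start, sequence[start:end], is_last)
        if is_last:
            return
        start += FRAGMENT_STEP


def fragment_genome(path: str | Path) -> Iterator[GenomeFragment]:
    """Stream fragments for every chromosome of a genome FASTA."""
    for chrom, seq in read_genome(path).items():
        yield from fragment_chromosome(chrom, seq)


def load_mirbase(
    hairpin_fasta: str | Path, mature_fasta: str | Path, species_prefix: str
) -> MirbaseSet:
    """Load miRBase-dialect hairpin and mature FASTAs for one species.

    Records are filtered by ID prefix (e.g. ``ath``); U is mapped to T; the
    length parameter L is the longest retained hairpin.
    """

    def _load(path: str | Path) -> dict[str, str]:
        return {
            rec.id: to_dna(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
            if rec.id.startswith(species_prefix)
        }

    hairpins = _load(hairpin_fasta)
    matures = _load(mature_fasta)
    if not hairpins:
        raise FormatError(
            f"{hairpin_fasta}: no hairpin records with prefix {species_prefix!r}"
        )
    return MirbaseSet(
        hairpins=hairpins,
        matures=matures,
        longest_hairpin_len=max(len(s) for s in hairpins.values()),
    )


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
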