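"""Degradome tag mapping and cleavage-signal calling.

A degradome (PARE) tag's 5' end marks an uncapped RNA 5' terminus — for our
purposes, a candidate Dicer/DCL1 cleavage position.  Tags are mapped exactly
(no mismatches) onto both strands of each 10,000-nt genome fragment, and a
genomic position becomes a *cleavage signal* when it passes two abundance
criteria within its library:

1. the mean RPM of the distinct tags whose 5' ends map to the position is at
   least ``ratio`` (default 5) times the mean over tag-bearing positions in
   the surrounding ``flank_w`` nt (default 50 per side); a position with no
   tag-bearing flank positions passes vacuously;
2. the most abundant tag at the position ranks in the top ``rank_k``
   (default 12) distinct tags mapped to the fragment on that strand
   (competition ranking, ties share a rank).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GenomeFragment, Library
from .util import revcomp


@dataclass(frozen=True)
class MappedTag:
    """An exact placement of a collapsed read on the genome."""

    sequence: str
    rpm: float
    chrom: str
    strand: str  # '+' or '-'
    start: int  # 0-based half-open genomic span
    end: int

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the tag's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class CleavageSignal:
    chrom: str
    strand: str
    pos: int  # genomic coordinate of the dominant 5' ends
    mean_rpm: float
    peak_rank: int
    library: str


def _occurrences(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i >= 0:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_tags(fragment: GenomeFragment, lib: Library) -> list[MappedTag]:
    """Map every read of a pre-treated library exactly onto both strands of
    a fragment; multi-mapping reads keep all placements."""
    out: list[MappedTag] = []
    seq = fragment.sequence
    for read in lib.reads:
        tag = read.sequence
        for off in _occurrences(seq, tag):
            out.append(MappedTag(tag, read.rpm, fragment.chrom, "+",
                                 fragment.start + off, fragment.start + off + len(tag)))
        for off in _occurrences(seq, revcomp(tag)):
            out.append(MappedTag(tag, read.rpm, fragment.chrom, "-",
                                 fragment.start + off, fragment.start + off + len(tag)))
    return out


def call_signals(
    tags: list[MappedTag],
    flank_w: int = 50,
    ratio: float = 5.0,
    rank_k: int = 12,
    agg: str = "mean",
    library: str = "",
) -> list[CleavageSignal]:
    """Call cleavage signals from the tags of one (fragment, strand, library).

    ``agg`` selects how per-position tag abundance is summarised ("mean" of
    distinct-tag RPMs, the default literal reading, or "sum").
    """
    if flank_w <= 0:
        raise ValueError("flank_w must be positive")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if agg not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {agg!r}")
    if not tags:
        return []
    chrom = tags[0].chrom
    strand = tags[0].strand

    # per-position distinct tags (a tag may hit one position repeatedly only
    # via distinct placements of the same sequence; collapse by sequence)
    by_pos: dict[int, dict[str, float]] = {}
    frag_tags: dict[str, float] = {}
    for t in tags:
        by_pos.setdefault(t.five_prime_pos, {})[t.sequence] = t.rpm
        frag_tags[t.sequence] = t.rpm

    def abundance(pos: int) -> float:
        vals = by_pos[pos].values()
        return sum(vals) / len(vals) if agg == "mean" else sum(vals)

    # competition ranks over distinct tag sequences on this strand
    ordered = sorted(frag_tags.values(), reverse=True)
    rank_of: dict[float, int] = {}
    for i, v in enumerate(ordered):
        rank_of.setdefault(v, i + 1)

    positions = sorted(by_pos)
    signals: list[CleavageSignal] = []
    for p in positions:
        flank = [abundance(q) for q in positions if q != p and abs(q - p) <= flank_w]
        if flank:
            baseline = sum(flank) / len(flank)
            # 'ratio times or more': a tiny relative slack keeps an exact
            # 5x ratio from failing on the last ulp of the RPM division
            if abundance(p) < ratio * baseline * (1.0 - 1e-9):
                continue
        peak = max(by_pos[p].values())
        rank = rank_of[peak]
        if rank > rank_k:
            continue
        signals.append(CleavageSignal(chrom, strand, p, abundance(p), rank, library))
    return signals


def scan_fragment(
    fragment: GenomeFragment,
    libs: list[Library],
    flank_w: int = 50,
    ratio: float = 5.0,
    rank_k: int = 12,
    agg: str = "mean",
) -> list[CleavageSignal]:
    """Map each degradome library onto a fragment and call signals per
    (strand, library)."""
    signals: list[CleavageSignal] = []
    for lib in libs:
        mapped = map_tags(fragment, lib)
        for strand in "+-":
            sub = [t for t in mapped if t.strand == strand]
            signals.extend(
                call_signals(sub, flank_w, ratio, rank_k, agg, library=lib.name)
            )
    return signals


def dedupe_signals(signals: list[CleavageSignal]) -> list[CleavageSignal]:
    """Union signals by (chrom, strand, pos), keeping per-library evidence as
    separate records but dropping duplicates from overlapping fragments."""
    seen: set[tuple] = set()
    out: list[CleavageSignal] = []
    key_order = lambda s: (s.chrom, s.pos, s.strand, s.library, s.peak_rank, -s.mean_rpm)
    for s in sorted(signals, key=key_order):
        key = (s.chrom, s.strand, s.pos, s.library)
        if key in seen:
            continue
        seen.add(key)
        out.append(s)
    return out
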