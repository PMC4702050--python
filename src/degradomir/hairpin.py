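"""Precursor-candidate extraction and the 30-nt stem-complementarity filter.

Each cleavage signal is interpreted as a possible Dicer scar at a duplex
end.  Because the scar may sit at either end of a 5'-arm or a 3'-arm
miRNA(*), two (30+L)-nt windows are cut around it (L = length of the
species' longest registered hairpin): one extending L nt downstream of the
scar plus 30 nt upstream, and the mirrored one.  Each window is folded; the
candidate is retained when at least one of the two 30-nt regions abutting
the scar is base-paired into the opposite arm at more than the
complementarity threshold (default 0.70, strict), with all partners falling
on one side of the region (locally duplex-like geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .fold import FoldResult, fold
from .scan import CleavageSignal
from .util import revcomp

MIN_CANDIDATE_LEN = 60
STEM_REGION_LEN = 30


@dataclass(frozen=True)
class PrecursorCandidate:
    """A genomic window anchored on a cleavage signal.

    ``anchor`` is the candidate-local (transcript-orientation) index of the
    signal position; ``start``/``end`` are the 0-based half-open genomic
    span; ``sequence`` is strand-adjusted (the transcript-sense sequence).
    """

    chrom: str
    strand: str
    start: int
    end: int
    sequence: str
    arm_hypothesis: str  # 'three_prime_arm' (window A) | 'five_prime_arm' (B)
    anchor: int
    anchor_signal: CleavageSignal
    fold: FoldResult | None = None
    stem_scores: tuple[float, float] | None = None
    passed: bool = False


def candidate_windows(
    sig: CleavageSignal, L: int, chrom_seq: str
) -> list[PrecursorCandidate]:
    """Cut up to two (30+L)-nt candidate windows around a signal.

    Windows truncated at chromosome ends are kept if still >= 60 nt;
    windows containing N are dropped.
    """
    if L < MIN_CANDIDATE_LEN:
        raise ValueError(f"L must be >= {MIN_CANDIDATE_LEN}, got {L}")
    p = sig.pos
    n = len(chrom_seq)
    if sig.strand == "+":
        # transcript orientation == genomic orientation
        spans = [(p - STEM_REGION_LEN, p + L, "three_prime_arm"),
                 (p - L, p + STEM_REGION_LEN, "five_prime_arm")]
    else:
        spans = [(p - L + 1, p + STEM_REGION_LEN + 1, "three_prime_arm"),
                 (p - STEM_REGION_LEN + 1, p + L + 1, "five_prime_arm")]
    out: list[PrecursorCandidate] = []
    for s, e, arm in spans:
        s, e = max(0, s), min(n, e)
        if e - s < MIN_CANDIDATE_LEN:
            continue
        seq = chrom_seq[s:e]
        if "N" in seq:
            continue
        anchor = p - s if sig.strand == "+" else e - 1 - p
        if not 0 <= anchor < e - s:
            continue
        out.append(
            PrecursorCandidate(
                chrom=sig.chrom, strand=sig.strand, start=s, end=e,
                sequence=seq if sig.strand == "+" else revcomp(seq),
                arm_hypothesis=arm, anchor=anchor, anchor_signal=sig,
            )
        )
    return out


def fold_candidate(c: PrecursorCandidate, backend: str = "auto") -> PrecursorCandidate:
    return replace(c, fold=fold(c.sequence, backend=backend))


def stem_complementarity(c: PrecursorCandidate) -> tuple[float, float]:
    """Score the two 30-nt regions abutting the anchor.

    Region U ends at the anchor ([anchor-30, anchor)), region D starts at it
    ([anchor, anchor+30)); both are clipped to the candidate and scored over
    their actual length.  The score is the fraction of region positions
    whose fold partner lies outside the region (i.e. paired into the
    opposite arm).
    """
    if c.fold is None:
        raise ValueError("candidate must be folded first")
    if not 0 <= c.anchor < len(c.sequence):
        raise ValueError("anchor lies outside the candidate")
    pairs = c.fold.pairs

    def score(lo: int, hi: int) -> float:
        lo, hi = max(0, lo), min(len(c.sequence), hi)
        if hi <= lo:
            return 0.0
        n = sum(1 for i in range(lo, hi) if pairs[i] >= 0 and not lo <= pairs[i] < hi)
        return n / (hi - lo)

    return (
        score(c.anchor - STEM_REGION_LEN, c.anchor),
        score(c.anchor, c.anchor + STEM_REGION_LEN),
    )


def _one_sided(c: PrecursorCandidate, lo: int, hi: int) -> bool:
    """True when every outside partner of [lo, hi) falls on one side of the
    region — the local geometry of a clean duplex rather than scattered
    pairing."""
    pairs = c.fold.pairs
    lo, hi = max(0, lo), min(len(c.sequence), hi)
    partners = [pairs[i] for i in range(lo, hi)
                if pairs[i] >= 0 and not lo <= pairs[i] < hi]
    if not partners:
        return False
    return all(p < lo for p in partners) or all(p >= hi for p in partners)


def score_candidate(c: PrecursorCandidate, threshold: float = 0.70) -> PrecursorCandidate:
    """Attach stem scores and the pass/fail flag (strict > threshold plus
    one-sidedness of the passing region)."""
    up, down = stem_complementarity(c)
    a = c.anchor
    regions = [(up, a - STEM_REGION_LEN, a), (down, a, a + STEM_REGION_LEN)]
    passed = any(s > threshold and _one_sided(c, lo, hi) for s, lo, hi in regions)
    return replace(c, stem_scores=(up, down), passed=passed)


def filter_candidates(
    cands: list[PrecursorCandidate], threshold: float = 0.70
) -> list[PrecursorCandidate]:
    """Keep candidates passing the stem filter; deduplicate identical
    (chrom, strand, genomic span)."""
    seen: set[tuple] = set()
    out: list[PrecursorCandidate] = []
    for c in cands:
        if c.stem_scores is None:
            c = score_candidate(c, threshold)
        if not c.passed:
            continue
        key = (c.chrom, c.strand, c.start, c.end)
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out
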