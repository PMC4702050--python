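"""miRNA/miRNA* duplex calling on retained precursor candidates.

Small-RNA reads (18-25 nt by default) are placed exactly on the candidate's
transcript-sense sequence.  Placements are grouped into isomiR clusters
(single linkage: 5' ends within 3 nt and overlapping spans).  The most
abundant cluster anchored at the cleavage signal yields the mature miRNA;
the star coordinates follow from the fold's pair table and the 2-nt 3'
overhang geometry Dicer leaves on the duplex:

    star_5' = partner(mature_3' - 2)        star_3' = partner(mature_5') + 2

An sRNA read at exactly those coordinates is the canonical star
(``overhang`` mode); failing that, the top read of an isomiR* cluster
overlapping the expected star span is accepted (``isomir_fallback`` —
passenger strands degrade fast and are often caught only as variants).
The called precursor is trimmed to the duplex plus 5 nt on each side and
refolded; the call survives only if the duplex geometry holds on the refold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .fold import FoldResult, fold
from .hairpin import PrecursorCandidate
from .io import Library

ANCHOR_TOL = 3  # max nt between a cluster end and the anchor signal
CLUSTER_5P_TOL = 3  # isomiR 5'-end linkage distance
PRECURSOR_FLANK = 5  # nt retained on each side of the duplex
DEFAULT_MAX_UNPAIRED = 0.5


@dataclass(frozen=True)
class SrnaPlacement:
    """An exact placement of a small-RNA read on a candidate (candidate
    coordinates, transcript orientation; 0-based half-open)."""

    sequence: str
    rpm: float
    start: int
    end: int


@dataclass
class IsomirCluster:
    reads: list[SrnaPlacement]  # ordered by descending rpm
    span: tuple[int, int]
    total_rpm: float

    @property
    def top_read(self) -> SrnaPlacement:
        return self.reads[0]


@dataclass(frozen=True)
class DuplexCall:
    candidate: PrecursorCandidate
    mature: SrnaPlacement
    star: SrnaPlacement
    star_mode: str  # 'overhang' | 'isomir_fallback'
    precursor_span: tuple[int, int]  # genomic, 0-based half-open, post-trim
    precursor_seq: str
    fold: FoldResult
    mature_local: tuple[int, int]  # duplex coords within trimmed precursor
    star_local: tuple[int, int]
    ago_status: str = "not_tested"  # 'not_tested' | 'enriched' | 'rejected'
    known_ids: tuple[str, ...] = ()
    library: str = ""


def map_srna(
    candidate: PrecursorCandidate,
    lib: Library,
    len_min: int = 18,
    len_max: int = 25,
) -> list[SrnaPlacement]:
    """Exact, full-length, sense-strand placements of length-bounded reads."""
    seq = candidate.sequence
    out: list[SrnaPlacement] = []
    for read in lib.reads:
        s = read.sequence
        if not len_min <= len(s) <= len_max:
            continue
        i = seq.find(s)
        while i >= 0:
            out.append(SrnaPlacement(s, read.rpm, i, i + len(s)))
            i = seq.find(s, i + 1)
    return out


def cluster_reads(placements: list[SrnaPlacement]) -> list[IsomirCluster]:
    """Single-linkage isomiR clustering: link placements whose 5' ends are
    within 3 nt and whose spans overlap; clusters sorted by total RPM."""
    if not placements:
        return []
    order = sorted(placements, key=lambda p: (p.start, p.end, p.sequence))
    clusters: list[list[SrnaPlacement]] = []
    cur = [order[0]]
    for p in order[1:]:
        last_5p = max(q.start for q in cur)
        last_end = max(q.end for q in cur)
        if p.start - last_5p <= CLUSTER_5P_TOL and p.start < last_end:
            cur.append(p)
        else:
            clusters.append(cur)
            cur = [p]
    clusters.append(cur)
    out = []
    for members in clusters:
        members = sorted(members, key=lambda p: (-p.rpm, p.start, p.sequence))
        out.append(
            IsomirCluster(
                reads=members,
                span=(min(p.start for p in members), max(p.end for p in members)),
                total_rpm=sum(p.rpm for p in members),
            )
        )
    out.sort(key=lambda c: (-c.total_rpm, c.span))
    return out


def expected_star_span(
    mature: tuple[int, int], pairs: tuple[int, ...]
) -> tuple[int, int] | None:
    """Star span implied by the 2-nt 3' overhang rule, or None when the
    required mature positions are unpaired.  Spans half-open."""
    m5, m3 = mature[0], mature[1] - 1  # inclusive ends
    i, j = m3 - 2, m5
    if not (0 <= i < len(pairs) and 0 <= j < len(pairs)):
        return None
    if pairs[i] < 0 or pairs[j] < 0:
        return None
    s5 = pairs[i]
    s3 = pairs[j] + 2
    if s3 >= len(pairs) or s5 >= s3:
        return None
    return (s5, s3 + 1)  # half-open


def call_duplex(
    candidate: PrecursorCandidate,
    clusters: list[IsomirCluster],
    max_unpaired: float = DEFAULT_MAX_UNPAIRED,
) -> DuplexCall | None:
    """Call the mature/star pair for one candidate, or return None.

    The mature is the top read of the most abundant cluster with a 5' or 3'
    end within +/-3 nt of the anchor signal; the star is found at the
    overhang-implied coordinates, with the isomiR* fallback.
    """
    if candidate.fold is None:
        raise ValueError("candidate must be folded")
    anchor = candidate.anchor
    mature = None
    for cl in clusters:
        top = cl.top_read
        if min(abs(top.start - anchor), abs(top.end - 1 - anchor)) <= ANCHOR_TOL:
            mature = top
            break
    if mature is None:
        return None
    pairs = candidate.fold.pairs
    exp = expected_star_span((mature.start, mature.end), pairs)
    if exp is None:
        return None
    if candidate.fold.unpaired_fraction(mature.start, mature.end) > max_unpaired:
        return None
    if candidate.fold.unpaired_fraction(*exp) > max_unpaired:
        return None
    if not (exp[0] >= mature.end or exp[1] <= mature.start):
        return None  # arms must be disjoint
    star = None
    mode = None
    for cl in clusters:
        for p in cl.reads:
            if (p.start, p.end) == exp:
                star, mode = p, "overhang"
                break
        if star:
            break
    if star is None:
        for cl in clusters:
            top = cl.top_read
            if top.start < exp[1] and exp[0] < top.end and (
                top.end <= mature.start or top.start >= mature.end
            ):
                star, mode = top, "isomir_fallback"
                break
    if star is None:
        return None
    call = DuplexCall(
        candidate=candidate, mature=mature, star=star, star_mode=mode,
        precursor_span=(candidate.start, candidate.end),
        precursor_seq=candidate.sequence, fold=candidate.fold,
        mature_local=(mature.start, mature.end),
        star_local=(star.start, star.end),
    )
    return trim_precursor(call)


def trim_precursor(call: DuplexCall, backend: str = "auto") -> DuplexCall | None:
    """Trim the precursor to the duplex plus 5 nt flanks, refold, and keep
    the call only if the duplex geometry survives the refold."""
    c = call.candidate
    lo = max(0, min(call.mature.start, call.star.start) - PRECURSOR_FLANK)
    hi = min(len(c.sequence), max(call.mature.end, call.star.end) + PRECURSOR_FLANK)
    seq = c.sequence[lo:hi]
    refold = fold(seq, backend=backend)
    m = (call.mature.start - lo, call.mature.end - lo)
    s = (call.star.start - lo, call.star.end - lo)
    exp = expected_star_span(m, refold.pairs)
    if exp is None:
        return None
    if call.star_mode == "overhang":
        if exp != s:
            return None
    else:
        if not (s[0] < exp[1] and exp[0] < s[1]):
            return None
    max_unpaired = DEFAULT_MAX_UNPAIRED
    if refold.unpaired_fraction(*m) > max_unpaired:
        return None
    if refold.unpaired_fraction(*s) > max_unpaired:
        return None
    # genomic span of the trimmed precursor (candidate seq is transcript-sense)
    if c.strand == "+":
        gspan = (c.start + lo, c.start + hi)
    else:
        gspan = (c.end - hi, c.end - lo)
    return replace(
        call,
        precursor_span=gspan,
        precursor_seq=seq,
        fold=refold,
        mature_local=m,
        star_local=s,
    )


def ago_filter(
    call: DuplexCall,
    ago_lib: Library | None,
    control_lib: Library | None,
    min_rpm: float = 1.0,
    fold_change: float = 3.0,
) -> DuplexCall:
    """AGO-enrichment status: enriched iff the mature or the star is above
    ``min_rpm`` in the AGO library and at least ``fold_change`` times its
    control abundance (a sequence absent from the control passes on the RPM
    floor alone)."""
    if ago_lib is None:
        return replace(call, ago_status="not_tested")

    def enriched(seq: str) -> bool:
        a = ago_lib.rpm_of(seq)
        c = control_lib.rpm_of(seq) if control_lib is not None else 0.0
        return a > min_rpm and a >= fold_change * c

    ok = enriched(call.mature.sequence) or enriched(call.star.sequence)
    return replace(call, ago_status="enriched" if ok else "rejected")
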