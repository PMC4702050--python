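from __future__ import annotations

import numpy as np
import pytest

from degradomir.duplex import (ago_filter, call_duplex, cluster_reads,
                               expected_star_span, map_srna, SrnaPlacement)
from degradomir.hairpin import PrecursorCandidate, fold_candidate
from degradomir.scan import CleavageSignal
from degradomir.synthetic import PlantSpec, make_genome
from degradomir.util import revcomp

from conftest import make_library


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture()
def planted(rng):
    """A folded candidate holding one perfect planted hairpin, plus its
    ground-truth duplex coordinates (candidate coords, half-open)."""
    spec = PlantSpec(n_hairpins=1, genome_len=2_000, seed=21)
    truth = make_genome(spec)
    h = truth.hairpins[0]
    pad = 20
    chrom = truth.genome[spec.chrom]
    if h.strand == "+":
        seq = chrom[h.start - pad:h.end + pad]
    else:
        seq = revcomp(chrom[h.start - pad:h.end + pad])
    m = (pad + h.mature_local[0], pad + h.mature_local[1])
    s = (pad + h.star_local[0], pad + h.star_local[1])
    anchor = m[0]  # scar at the mature 5' end
    cand = PrecursorCandidate("chr1", h.strand, h.start - pad, h.end + pad,
                              seq, "three_prime_arm", anchor,
                              CleavageSignal("chr1", h.strand, 0, 10.0, 1, "d"))
    return fold_candidate(cand), m, s, h


def placements_for(cand, m, s, h, spread=2, star_shift=0):
    """IsomiR cloud around the planted mature plus star reads."""
    seq = cand.sequence
    rpm = {}
    for d in range(-spread, spread + 1):
        rpm[seq[m[0] + d:m[1] + d]] = 100.0 * 0.5 ** abs(d)
    rpm[seq[s[0] + star_shift:s[1] + star_shift]] = 20.0
    for d in (star_shift - 1, star_shift + 1):
        # star isomiRs, so the fallback has something to find; never plant
        # the exact overhang coordinates unless star_shift is 0
        if d != 0:
            rpm.setdefault(seq[s[0] + d:s[1] + d], 8.0)
    return make_library(rpm, kind="srna")


class TestMapSrna:
    def test_planted_mature_found_at_offset(self, planted):
        cand, m, s, h = planted
        lib = make_library({h.mature_seq: 50.0}, kind="srna")
        hits = map_srna(cand, lib)
        assert [(p.start, p.end) for p in hits] == [m]

    def test_length_bounds(self, planted):
        cand, m, *_ = planted
        too_long = cand.sequence[m[0]:m[0] + 31]
        lib = make_library({too_long: 50.0}, kind="srna")
        assert map_srna(cand, lib) == []

    def test_isomir_cloud_all_placed(self, planted):
        cand, m, s, h = planted
        lib = placements_for(cand, m, s, h)
        hits = map_srna(cand, lib)
        starts = {p.start for p in hits}
        assert {m[0] - 2, m[0] - 1, m[0], m[0] + 1, m[0] + 2} <= starts


class TestClustering:
    def test_identical_five_prime_ends_one_cluster(self):
        ps = [SrnaPlacement("A" * 21, 10.0, 100, 121),
              SrnaPlacement("C" * 22, 5.0, 100, 122)]
        assert len(cluster_reads(ps)) == 1

    def test_linkage_oracle_on_offsets(self):
        ps = [SrnaPlacement("A" * 21, 10.0, o, o + 21)
              for o in (100, 101, 103, 160)]
        clusters = cluster_reads(ps)
        assert sorted(tuple(sorted(p.start for p in c.reads))
                      for c in clusters) == [(100, 101, 103), (160,)]

    def test_empty(self):
        assert cluster_reads([]) == []

    def test_sorted_by_total_rpm(self):
        ps = [SrnaPlacement("A" * 21, 1.0, 100, 121),
              SrnaPlacement("C" * 21, 50.0, 200, 221)]
        clusters = cluster_reads(ps)
        assert clusters[0].span[0] == 200


class TestCallDuplex:
    def test_overhang_mode_on_planted_hairpin(self, planted):
        cand, m, s, h = planted
        lib = placements_for(cand, m, s, h)
        call = call_duplex(cand, cluster_reads(map_srna(cand, lib)))
        assert call is not None
        assert call.star_mode == "overhang"
        assert call.mature.sequence == h.mature_seq
        assert call.star.sequence == h.star_seq

    def test_shifted_star_falls_back_to_isomir(self, planted):
        cand, m, s, h = planted
        lib = placements_for(cand, m, s, h, star_shift=1)
        call = call_duplex(cand, cluster_reads(map_srna(cand, lib)))
        assert call is not None
        assert call.star_mode == "isomir_fallback"
        assert call.mature.sequence == h.mature_seq

    def test_fallback_never_changes_the_mature(self, planted):
        cand, m, s, h = planted
        with_star = placements_for(cand, m, s, h)
        without = make_library(
            {r.sequence: r.rpm for r in with_star.reads
             if r.sequence != h.star_seq}, kind="srna")
        a = call_duplex(cand, cluster_reads(map_srna(cand, with_star)))
        b = call_duplex(cand, cluster_reads(map_srna(cand, without)))
        assert a.star_mode == "overhang"
        assert b is not None and b.star_mode == "isomir_fallback"
        assert a.mature.sequence == b.mature.sequence == h.mature_seq

    def test_loop_reads_only_no_call(self, planted):
        cand, m, s, h = planted
        loop_lo = m[1] + 18
        loop_read = cand.sequence[loop_lo:loop_lo + 20]
        lib = make_library({loop_read: 80.0}, kind="srna")
        call = call_duplex(cand, cluster_reads(map_srna(cand, lib)))
        assert call is None

    def test_overhang_invariant_on_reported_fold(self, planted):
        cand, m, s, h = planted
        lib = placements_for(cand, m, s, h)
        call = call_duplex(cand, cluster_reads(map_srna(cand, lib)))
        exp = expected_star_span(call.mature_local, call.fold.pairs)
        assert exp == call.star_local
        # arms disjoint and inside the trimmed precursor
        ml, sl = call.mature_local, call.star_local
        assert ml[1] <= sl[0] or sl[1] <= ml[0]
        n = len(call.precursor_seq)
        assert 0 <= ml[0] < ml[1] <= n and 0 <= sl[0] < sl[1] <= n

    def test_trim_arithmetic(self, planted):
        cand, m, s, h = planted
        lib = placements_for(cand, m, s, h)
        call = call_duplex(cand, cluster_reads(map_srna(cand, lib)))
        lo = min(m[0], s[0]) - 5
        hi = max(m[1], s[1]) + 5
        assert len(call.precursor_seq) == hi - lo
        if cand.strand == "+":
            assert call.precursor_span == (cand.start + lo, cand.start + hi)
        else:
            assert call.precursor_span == (cand.end - hi, cand.end - lo)


class TestExpectedStar:
    def test_perfect_stem_geometry(self):
        # 40-bp perfect stem, 8-nt loop; mature on the 5' arm
        from degradomir.fold import pairs_from_dotbracket
        n = 88
        pairs = pairs_from_dotbracket("(" * 40 + "." * 8 + ")" * 40)
        m = (5, 26)
        exp = expected_star_span(m, pairs)
        # star_5' = partner(mature_3'-2); star_3' = partner(mature_5') + 2
        assert exp == (n - 1 - 23, n - 1 - 5 + 2 + 1)

    def test_unpaired_mature_end_gives_none(self):
        from degradomir.fold import pairs_from_dotbracket
        pairs = pairs_from_dotbracket("." * 80)
        assert expected_star_span((5, 26), pairs) is None


class TestAgoFilter:
    def _call(self, planted):
        cand, m, s, h = planted
        lib = placements_for(cand, m, s, h)
        return call_duplex(cand, cluster_reads(map_srna(cand, lib))), h

    def test_nine_vs_three_rpm_enriched(self, planted):
        call, h = self._call(planted)
        ago = make_library({h.mature_seq: 9.0}, kind="ago")
        ctrl = make_library({h.mature_seq: 3.0}, kind="control")
        assert ago_filter(call, ago, ctrl).ago_status == "enriched"

    def test_below_floor_rejected(self, planted):
        call, h = self._call(planted)
        ago = make_library({h.mature_seq: 0.5}, kind="ago")
        ctrl = make_library({"ACGTACGTACGTACGTACGTA": 1.0}, kind="control")
        assert ago_filter(call, ago, ctrl).ago_status == "rejected"

    def test_absent_from_control_passes_on_floor(self, planted):
        call, h = self._call(planted)
        ago = make_library({h.mature_seq: 2.0}, kind="ago")
        ctrl = make_library({"ACGTACGTACGTACGTACGTA": 99.0}, kind="control")
        assert ago_filter(call, ago, ctrl).ago_status == "enriched"

    def test_no_ago_library_not_tested(self, planted):
        call, _ = self._call(planted)
        assert ago_filter(call, None, None).ago_status == "not_tested"
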