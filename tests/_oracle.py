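"""Independent brute-force re-implementations used as test oracles.

Deliberately naive: plain loops, no shared code with the package internals
beyond the public data types.
"""

from __future__ import annotations

from degradomir.scan import MappedTag


def brute_force_signals(
    tags: list[MappedTag], flank_w: int, ratio: float, rank_k: int
) -> list[tuple[int, float, int]]:
    """Return (pos, mean_rpm, peak_rank) for every position passing both
    criteria, recomputed from first principles for each position."""
    positions = sorted({t.five_prime_pos for t in tags})
    results = []
    # distinct tag sequences on this strand with their rpm
    seq_rpm: dict[str, float] = {}
    for t in tags:
        seq_rpm[t.sequence] = t.rpm
    for p in positions:
        here = {t.sequence: t.rpm for t in tags if t.five_prime_pos == p}
        mean_here = sum(here.values()) / len(here)
        flank_means = []
        for q in positions:
            if q == p or abs(q - p) > flank_w:
                continue
            there = {t.sequence: t.rpm for t in tags if t.five_prime_pos == q}
            flank_means.append(sum(there.values()) / len(there))
        if flank_means:
            baseline = sum(flank_means) / len(flank_means)
            # same 'at least ratio-fold' semantics as the caller under test:
            # an exact ratio passes despite floating-point rounding
            if mean_here < ratio * baseline * (1.0 - 1e-9):
                continue
        peak = max(here.values())
        rank = 1 + sum(1 for v in seq_rpm.values() if v > peak)
        if rank > rank_k:
            continue
        results.append((p, mean_here, rank))
    return results
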