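"""Annotation, report writing, and the degradome end-support profiler.

The profiler quantifies how well known miRNA/miRNA* duplex ends are
supported by degradome signatures: for each registered hairpin whose mature
can be located by exact substring match, degradome tags are mapped onto the
hairpin, cleavage signals are called with the same two abundance criteria
used for the genome scan, and every signal is classified by its nearest
duplex end — (1) mature 5', (2) mature 3', (3) star 5', (4) star 3' — and
signed offset in -3..+3.  Signals equidistant from two or more ends are
split equally between them; signals farther than 3 nt from every end are
tallied in an ``other`` bucket so both denominator conventions stay
computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .duplex import DuplexCall, expected_star_span
from .fold import fold
from .io import GenomeFragment, Library, MirbaseSet
from .scan import call_signals, map_tags
from .util import to_rna

END_LABELS = ("mature_5p", "mature_3p", "star_5p", "star_3p")
OFFSETS = tuple(range(-3, 4))

REPORT_COLUMNS = [
    "chrom", "start", "end", "strand", "precursor_id",
    "mature_seq", "mature_rpm", "mature_start", "mature_end",
    "star_seq", "star_rpm", "star_start", "star_end",
    "star_mode", "ago_status", "signature_pos", "library",
    "mfe", "structure", "precursor_seq", "known_ids", "novel",
]


def annotate_known(call: DuplexCall, mirbase: MirbaseSet) -> DuplexCall:
    """Attach the names of registered matures whose sequence equals the
    called mature or star exactly (U/T-insensitive)."""
    hits = [
        name
        for name, seq in sorted(mirbase.matures.items())
        if seq in (call.mature.sequence, call.star.sequence)
    ]
    return replace(call, known_ids=tuple(hits))


@dataclass
class EndSupportProfile:
    precursor_id: str
    counts: dict[tuple[str, int], float] = field(default_factory=dict)
    other: float = 0.0
    n_signals: int = 0

    def add(self, end: str, offset: int, weight: float) -> None:
        key = (end, offset)
        self.counts[key] = self.counts.get(key, 0.0) + weight

    @property
    def total_weight(self) -> float:
        return sum(self.counts.values()) + self.other


def _locate_duplex(
    hairpin: str, matures: dict[str, str]
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Locate mature (and star) spans on a hairpin.

    Registered matures found as substrings give the mature arm and, when a
    second record sits on the opposite arm, the star; otherwise the star is
    derived from the MFE fold by the 2-nt 3' overhang rule.
    """
    found: list[tuple[int, int]] = []
    for seq in matures.values():
        i = hairpin.find(seq)
        if i >= 0:
            span = (i, i + len(seq))
            if span not in found:
                found.append(span)
    if not found:
        return None
    found.sort()
    mature = found[0]
    for other in found[1:]:
        if other[0] >= mature[1] or other[1] <= mature[0]:
            return mature, other
    exp = expected_star_span(mature, fold(hairpin).pairs)
    if exp is None or not (exp[0] >= mature[1] or exp[1] <= mature[0]):
        return None
    return mature, exp


def end_support_profile(
    mirbase: MirbaseSet,
    degradome_libs: list[Library],
    flank_w: int = 50,
    ratio: float = 5.0,
    rank_k: int = 12,
    max_offset: int = 3,
) -> list[EndSupportProfile]:
    """Profile degradome support at the four duplex ends of each registered
    hairpin (the hairpin stands in for the genome fragment)."""
    profiles: list[EndSupportProfile] = []
    for hid, hseq in sorted(mirbase.hairpins.items()):
        duplex = _locate_duplex(hseq, mirbase.matures)
        if duplex is None:
            continue
        (m5, m_end), (s5, s_end) = duplex
        ends = {
            "mature_5p": m5,
            "mature_3p": m_end - 1,
            "star_5p": s5,
            "star_3p": s_end - 1,
        }
        prof = EndSupportProfile(precursor_id=hid)
        frag = GenomeFragment(hid, 0, hseq, True)
        for lib in degradome_libs:
            tags = [t for t in map_tags(frag, lib) if t.strand == "+"]
            for sig in call_signals(tags, flank_w, ratio, rank_k, library=lib.name):
                offsets = {
                    label: sig.pos - pos
                    for label, pos in ends.items()
                    if abs(sig.pos - pos) <= max_offset
                }
                prof.n_signals += 1
                if not offsets:
                    prof.other += 1.0
                    continue
                best = min(abs(o) for o in offsets.values())
                nearest = {k: o for k, o in offsets.items() if abs(o) == best}
                w = 1.0 / len(nearest)
                for label, off in nearest.items():
                    prof.add(label, off, w)
        profiles.append(prof)
    return profiles


def profile_frequency_table(profiles: list[EndSupportProfile]) -> pd.DataFrame:
    """Aggregate end/offset weights over all profiles (the four-end,
    offset -3..+3 frequency table)."""
    rows = []
    for end in END_LABELS:
        for off in OFFSETS:
            w = sum(p.counts.get((end, off), 0.0) for p in profiles)
            rows.append({"end": end, "offset": off, "weight": w})
    rows.append({"end": "other", "offset": 0,
                 "weight": sum(p.other for p in profiles)})
    return pd.DataFrame(rows)


def calls_to_records(calls: list[DuplexCall]) -> pd.DataFrame:
    """Flatten duplex calls into the master report table.

    Genomic spans are 1-based inclusive in the report; sequences are in RNA
    alphabet; duplex coordinates are 1-based within the trimmed precursor.
    """
    rows = []
    for c in calls:
        sig = c.candidate.anchor_signal
        rows.append({
            "chrom": c.candidate.chrom,
            "start": c.precursor_span[0] + 1,
            "end": c.precursor_span[1],
            "strand": c.candidate.strand,
            "precursor_id": f"{c.candidate.chrom}:{c.precursor_span[0] + 1}"
                            f"-{c.precursor_span[1]}({c.candidate.strand})",
            "mature_seq": to_rna(c.mature.sequence),
            "mature_rpm": round(c.mature.rpm, 4),
            "mature_start": c.mature_local[0] + 1,
            "mature_end": c.mature_local[1],
            "star_seq": to_rna(c.star.sequence),
            "star_rpm": round(c.star.rpm, 4),
            "star_start": c.star_local[0] + 1,
            "star_end": c.star_local[1],
            "star_mode": c.star_mode,
            "ago_status": c.ago_status,
            "signature_pos": sig.pos + 1,
            "library": c.library,
            "mfe": round(c.fold.mfe, 2),
            "structure": c.fold.structure,
            "precursor_seq": to_rna(c.precursor_seq),
            "known_ids": ";".join(c.known_ids),
            "novel": "yes" if not c.known_ids else "no",
        })
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df.sort_values(
        ["chrom", "start", "strand", "mature_seq", "library"]
    ).reset_index(drop=True)


def write_report(records: pd.DataFrame, outdir: str | Path) -> tuple[Path, Path]:
    """Write the master TSV and the precursor structure blocks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / "duplex_report.tsv"
    records.to_csv(tsv, sep="\t", index=False)
    blocks = outdir / "precursor_structures.txt"
    with open(blocks, "w") as fh:
        for _, row in records.iterrows():
            fh.write(f">{row['precursor_id']} mfe={row['mfe']} "
                     f"novel={row['novel']}\n")
            fh.write(f"{row['precursor_seq']}\n{row['structure']}\n\n")
    return tsv, blocks


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"known_ids": str})
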