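# degradomir

Genome-wide discovery of miRNA/miRNA* duplexes guided by degradome-supported
Dicer cleavage signatures.

## The problem

Dicer (DCL1 in plants) excises the miRNA/miRNA* duplex from its hairpin
precursor, cutting at the duplex ends and leaving 2-nt 3′ overhangs.  Each
cut releases an intermediate whose uncapped 5′ end is captured by degradome
(PARE) sequencing.  Degradome tag 5′ ends therefore pile up at miRNA and
miRNA* boundaries on real precursors — and those pile-ups can serve as
*guideposts* for finding precursors nobody has annotated yet.  `degradomir`
turns that observation into a discovery pipeline for anyone with a genome,
one or more degradome libraries, and small-RNA HTS libraries (plant or
animal):

1. **Pre-treatment** — collapsed reads with `N`s or zero counts are
   discarded; counts are normalised to reads per million (RPM) over the
   retained total.
2. **Cleavage-signal scan** — the genome is cut into 10,000-nt fragments
   with 500-nt overlaps; degradome tags are exact-matched on both strands.
   A position *p* is a cleavage signal when
   (i) mean RPM of tags with 5′ ends at *p* ≥ 5 × the mean over tag-bearing
   positions within ±50 nt, and (ii) its top tag ranks in the fragment's
   top 12 tags.
3. **Precursor candidates** — around each signal, two windows of (30+L) nt
   are cut (L = longest registered hairpin of the species, e.g. from
   miRBase files).  Each is folded (ViennaRNA MFE); a candidate is kept
   when one of the two 30-nt regions abutting the signal is base-paired
   into the opposite arm at > 70% (strict), i.e. the scar sits on a stem.
4. **Duplex calling** — sRNA reads (18–25 nt) are placed exactly on each
   retained candidate and grouped into isomiR clusters (5′ ends within
   3 nt).  The top read of the most abundant cluster anchored at the signal
   is the mature; the star follows from the pair table via
   `star5′ = partner(mature3′ − 2)`, `star3′ = partner(mature5′) + 2`.
   An exact read at those coordinates gives an `overhang` call, otherwise
   the top overlapping isomiR* is accepted (`isomir_fallback`).  The
   precursor is trimmed to the duplex ± 5 nt and must refold cleanly.
5. **Optional AGO filter** — a duplex is `enriched` when the mature or star
   exceeds 1 RPM in an AGO-IP library and ≥ 3 × its control abundance.
6. **Report** — TSV of loci, sequences (RNA alphabet), per-library RPMs,
   duplex coordinates, structures and MFEs; matches to registered matures
   are named, everything else flagged novel.

A separate **end-support profiler** runs the same signal criteria over
*known* precursors and tallies signatures by nearest duplex end
(mature 5′/3′, star 5′/3′) and offset −3..+3, with equidistant signals
split equally — the classic evidence plot that motivates the method.

## Worked example

```sh
python examples/01_discover_from_synthetic.py
```

builds a 60-kb genome with 5 planted precursors and matching libraries,
runs the pipeline at defaults and prints (abridged):

```
  chrom  start    end strand             mature_seq star_mode ago_status                 known_ids
0  chr1  12756  12853      -  UGGGACGCAUACUAGCACCAA  overhang   enriched  syn-miR0001;syn-miR0001*
1  chr1  12758  12855      +  UGGGACGCAUACUAGCACCAA  overhang   enriched  syn-miR0001;syn-miR0001*
2  chr1  13894  13991      -  AGGCCUUGGAAUCUGGGCAGG  overhang   enriched  syn-miR0002;syn-miR0002*
...
recovered 5/5 planted matures
```

Each row is one called duplex: its trimmed precursor locus, the mature and
star sequences, how the star was found, AGO status, and any registered
matures with identical sequence.  A perfect inverted repeat is
strand-ambiguous, so each planted locus appears once per strand.
`examples/02_cleavage_signal_scan.py` and
`examples/03_end_support_profile.py` demonstrate the scan stage and the
profiler in isolation; the `degradomir` CLI (`scan`, `dig`, `profile`,
`fixtures`, `resume`) exposes the same stages from the shell, with
per-fragment checkpointing so an interrupted `dig` resumes where it
stopped.

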