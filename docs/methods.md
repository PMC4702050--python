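# Methods

## Model and rationale

Dicer/DCL1 processing of a miRNA precursor cuts the stem at the two ends of
the miRNA/miRNA* duplex, leaving 2-nt 3′ overhangs and releasing
intermediates whose uncapped 5′ ends are sequenced by degradome/PARE
protocols.  The pipeline inverts this: degradome tag 5′-end pile-ups are
treated as candidate Dicer scars, the surrounding sequence is tested for
hairpin geometry, and small-RNA reads are asked to reproduce the duplex the
scar implies.  Requiring independent degradome evidence of processing is
what distinguishes the approach from purely sRNA-profile-based miRNA
finders; it also means sensitivity is bounded by degradome library depth.

Assumptions: cleavage positions are read from exact 5′ ends of exactly
matching tags (no mismatch or isoform-aware mapping); one duplex per
precursor; sRNA reads are mapped sense-only onto candidates, since
antisense reads fall outside the biogenesis model.

## Coordinates and alphabets

Internally everything is DNA alphabet (U→T on input) and 0-based half-open;
report output is RNA alphabet and 1-based inclusive.  On the − strand, a
tag's 5′ end is the highest genomic coordinate of its span; candidate
sequences are stored transcript-sense.

## Stage parameters

| parameter | default | meaning |
|---|---|---|
| fragment size / overlap | 10,000 / 500 nt | scan unit; overlap ≥ any precursor so no locus is split |
| `flank_w` | 50 nt/side | neighbourhood of the 5×-over-flank abundance test |
| `ratio` | 5 | signal-over-flank mean-RPM ratio ("five times or more") |
| `rank_k` | 12 | top-k rank the signal's best tag must reach per fragment/strand |
| `L` | longest registered hairpin | candidate window length is 30+L |
| `stem_threshold` | 0.70 (strict >) | fraction of a 30-nt scar-adjacent region paired into the opposite arm |
| `len_min..len_max` | 18–25 nt | sRNA lengths considered for duplex calling |
| `max_unpaired` | 0.5 | max unpaired fraction tolerated over mature/star (plant duplexes bulge) |
| `ago_min_rpm`, `ago_fold` | 1 RPM, 3× | AGO-IP floor and enrichment over control |

RPM uses the retained-read total as denominator, so every library's RPMs
sum to 10⁶ — the invariant the tests exploit.  The flank baseline is the
mean over tag-bearing flank positions only; a position with empty flanks
passes the ratio test vacuously (a deliberate recall-preserving choice —
isolated single tags survive to the structural filters, which is where they
die).  Tag ranking uses competition ranking over distinct sequences per
fragment and strand; multi-mapping tags contribute full RPM at every
placement, as no apportioning rule is defensible without a mapping model.

## Numerical choices

* The ratio test is `mean ≥ ratio × baseline` with a 1e-9 relative slack:
  an exactly 5× signal must pass, and the RPM divisions otherwise lose the
  tie in the last ulp.  The brute-force oracle applies the same semantics.
* Stem complementarity is the fraction of region positions whose MFE-fold
  partner lies outside the region — G:U wobbles count as paired because the
  fold engine pairs them.  The passing region's outside partners must also
  all fall on one side (a clean duplex, not scattered pairing).
  Regions truncated by candidate edges are scored over their actual length.
* Threshold comparison is strict (>0.70); a score of exactly 0.70 fails.
* Folding uses ViennaRNA's MFE (`RNA.fold`); the bundled weighted-Nussinov
  engine (GC=3, AU=2, GU=1, min loop 3) is a pluggable dependency-free
  alternative used in backend-parametrised tests.
* The mature cluster must have its top read's 5′ or 3′ end within ±3 nt of
  the anchor signal — matching the observed up-to-3-nt migration of scars
  around duplex ends; which end matched is recoverable from coordinates.
* Trimming keeps duplex ± 5 nt and refolds; an `overhang` call must
  reproduce the exact star coordinates on the refold, a fallback call must
  still overlap them.
* Profiler end positions are the terminal nucleotides themselves; offset =
  signal − end in transcript orientation, so a cut at a 3′ end registers
  at +1.  Equidistant ends split a signal's weight equally; signals > 3 nt
  from every end are tallied in an `other` bucket so both denominator
  conventions (classified-only vs all signals) stay computable.
* Calls are deduplicated per (library, precursor locus), keeping the more
  abundant mature: a duplex discovered from both of its scars would
  otherwise appear twice, once with mature and star swapped.
* Report ordering is (chrom, start, strand, mature, library); RPMs are
  written at 4 decimals and MFE at 2, which is what makes interrupted-and-
  resumed and multi-worker runs byte-identical.

## Synthetic data

The generator plants perfect inverted-repeat hairpins (default stem 42 nt,
loop 12 nt, mature 21 nt starting 5 nt into the stem) in a uniform random
genome, on either strand, ≥200 nt apart.  Star coordinates follow the 2-nt
3′ overhang rule exactly.  The degradome library puts tag 5′ ends at the
four duplex-end cut positions — the two duplex 5′ ends at
`scar_rpm_fold` (default 10) × the unit background count, the two 3′ ends
at 2× — over Poisson background tags (default 2/kb, count 1).  The
asymmetry mirrors the empirical dominance of 5′-end signatures and is also
structurally necessary here: the four scars lie 21–46 nt apart, inside one
another's flank windows, so four equal-abundance scars would mutually
suppress under the 5× criterion.  sRNA libraries carry the mature at count
100 with geometrically decaying isomiRs (ratio 0.5, 5′ shifts ≤ 2 nt), the
star at 20, and background reads of count 1; the AGO library is
mature/star-enriched while the control is dominated by a diffuse 4×-count
background, keeping planted AGO/control RPM ratios comfortably above 3.

What the fixtures do **not** emulate: imperfect stems and bulged duplexes,
multi-mapping repeat-derived tags, realistic PARE abundance distributions,
RNA degradation noise at non-Dicer positions, and strand-unambiguous loci —
a perfect inverted repeat is identical to its reverse complement up to the
loop, so every planted locus is legitimately called on both strands.
Passing tests therefore demonstrate correctness of the machinery at its
operating point, not performance on real tissue libraries, where depth,
stem imperfection and background structure dominate sensitivity.

Test and acceptance problem sizes — 60-kb/5-hairpin fixtures for unit and
determinism tests, one 500-kb/20-hairpin condition (plus its matched
background-only genome) for end-to-end recovery, 200 random ≤2-kb
fragments for oracle equivalence — were chosen as the smallest scales at
which every stage (fragmenting, multi-fragment overlap dedup, rank
criterion, clustering, fallback) is genuinely exercised.

## Known limitations

* Exact-match tag mapping only; SNPs or sequencing errors at a scar hide it.
* One duplex per precursor; polycistronic or dual-duplex hairpins yield at
  most the dominant call.
* The end-support profiler needs the mature to occur verbatim in its
  hairpin record and maps tags sense-only.
* EST/transcriptome-only input (no genome) is unsupported, as is target
  prediction/validation — both out of scope here.
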