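# Methods

This note records the model, the numerical and design choices, and what
the synthetic benchmarks do and do not demonstrate.

## Evidence model

Junction evidence is the set of `N` (reference-skip) operations in
retained alignment records. A record is retained unless unmapped,
duplicate-flagged, QC-failed, secondary (unless requested), or below the
MAPQ floor. Deduplication is assumed done upstream (UMI consensus or
positional); duplicate flags are honoured defensively. Each `N` in a
retained record is one observation — overlapping mates observing the same
gap therefore count twice by default, since mate consensus is likewise an
upstream concern; `count_fragments=True` collapses them per fragment.

*Anchors.* A gap is counted only if the contiguous aligned segment
(M/=/X bases) on each side reaches `min_anchor` (default 5 bp). Aligners
apply their own overhang filters before emitting alignments, but the rule
must be defined locally so that synthetic alignments behave like real
ones. `min_mapq` defaults to 0 because unique-mapper MAPQ conventions
differ between aligners.

*Strand.* For stranded libraries the template strand is derived from the
flag bits (FR: read 1 carries the transcript strand; RF: read 2), and a
junction takes the majority orientation of its observations, `'.'` on
ties. Unstranded or tied junctions are rescued from the intron motif
(GT..AG ⇒ `+`, CT..AC ⇒ `-`) when the genome is available, and finally
adopt the annotation strand when both their sites are annotated on a
single strand. Lookups with strand `'.'` match any annotated strand:
unstranded evidence cannot exclude a strand. Genes overlapping on
opposite strands therefore share no sites (the index is per-strand), but
an unstranded junction at such a position would match either — an
ambiguity inherited from the data, not resolvable by the caller.

*No-splice depth.* The no-splice alternative at a site is the number of
retained reads covering the probe base — the `k`-th base inside the
putative intron, `k = nosplice_offset` (default 3, i.e. the 3rd intronic
base: `pos + 2` for a left site, `pos − 2` for a right site) — with a
reference-consuming match state. Reads spliced (N) or deleted (D) over
the probe base do not count: they are not evidence of retention. Depth is
measured at every annotated site and every site discovered from gaps;
no-splice rows for sites with zero depth and no junction are suppressed
as zero-information.

## Realignment

Gap placement is ambiguous exactly when the intron's flanking sequence
repeats across its boundary: placement `(s+k, e+k)` is equivalent to
`(s, e)` iff `genome[s..s+k−1] == genome[e+1..e+k]` (and symmetrically
left). The range is found by direct base comparison outward from `k = 0`,
stopping at the first mismatch, the chromosome edge, or 100 bp (a guard
against pathological repeats; biological boundary repeats are far
shorter). Equivalence is defined on the reference sequence alone — as in
indel left-alignment — so all reads of a junction shift together.

Among equivalent placements the winner maximizes, in order: number of its
two sites present in the annotation; membership of the whole junction in
the annotated-junction catalog; canonical splice motif on the junction's
strand (both GT–AG and CT–AC count when the strand is unknown); smallest
absolute shift; leftmost. The last two tie-breaks are committed choices —
when neither annotation nor motif distinguishes two placements there is
no biological signal left, and determinism is what matters. Junctions
already matching two annotated sites are left untouched, and placements
that collide after shifting merge their evidence.

## Classification and PSI

The six classes partition all records: four junction classes by the
annotation status of the two sites (`Annotated`, `Plausible`, `Anchored`,
`Unknown`) and two no-splice classes by the status of the single site
(`NoSplice` at an annotated site, `Trivial` at a de novo one).

PSI is deliberately local: one alternative in the context of one site,
`count / site total`, with the no-splice alternative an ordinary member
of the denominator. No attempt is made to integrate multiple evidence
sources into composite event models; the two per-junction PSI values
(donor-side and acceptor-side) are reported side by side and may
legitimately differ when the two sites see different alternative loads.
PSI is undefined (written `.`) when a site total is zero. Denominators
are per sample and per site; sites are never pooled across strands. The
strand-less no-splice depth of a position attaches to every strand group
at that position/side — distinct strands at one position do not co-occur
in practice, and splitting the depth would invent information.
Orientation counts are reported alongside but never weight PSI.

Read-vs-fragment counting for PSI numerators follows the evidence
setting (`count_fragments`), defaulting to reads.

## Fusion candidates

Junction evidence: two sites with disjoint non-empty gene sets (gene sets
come from the annotated-site → gene map, falling back to gene-span
overlap for novel sites). Chimeric evidence: rows of a STAR-style
chimeric table aggregate per locus pair and qualify when chromosomes
differ, strands are incompatible on one chromosome, or the distance
exceeds 1 Mb (configurable; intronic distances above that are
implausible for one gene). Without a chimeric table only same-chromosome,
gap-evidenced fusions are callable — a documented limitation, since
inter-chromosomal reads never appear as `N` gaps.

## Filter tiers

`none` (report everything), `sensitive` (≥ 5 reads, PSI ≥ 0.01),
`intermediate` (≥ 10, 0.05), `stringent` (≥ 20, 0.10). The filtering
tiers report the novel classes `{Plausible, Anchored, Unknown, NoSplice}`;
`Annotated` and `Trivial` rows appear only in the unfiltered table. The
threshold ladder is non-decreasing by construction, which makes survivor
sets nested. These defaults are this package's own calibration for
panel-depth data — deep targeted panels make a 5-read floor conservative —
and are overridable per tier via the YAML config. A record passes the PSI
floor on the larger of its two PSI values: a junction dominant at either
site is interesting even if diluted at the other.

## The synthetic fixtures

`make_reference` lays out genes (default 4 exons × 120 bp, 90 bp introns,
300 bp spacers) left to right on one or more chromosomes of random
sequence, strands random, with canonical GT..AG (or CT..AC) written at
every annotated intron boundary. `plant_events` draws at most one event
per gene — exon skip, multi-exon skip, intron retention, alternative
5′/3′ site at 12.5% each, no event at 37.5% — with true PSI uniform on
(0.2, 0.8) and alternative-site offsets uniform on 4–25 bp (never 0, and
capped so probe bases stay intronic). No canonical motif is written at
the novel alt-site boundary: detection is motif-agnostic, and realignment
cannot cancel the event because shifting moves both intron ends jointly
off the annotated partner site. `simulate_alignments` draws per-gene
fragment counts from uniform 60× coverage (optional log-normal
expression factor), picks the aberrant isoform with probability equal to
the true PSI, and emits proper paired records with exact CIGARs —
`N` over introns, `M` through retained ones. Fragment lengths are
normal(250, 40) clipped to the isoform, so junction coverage varies as it
does in real libraries. Sequencing error is off by default (the caller's
arithmetic is error-agnostic); a uniform substitution rate is available
for robustness checks.

Planted *support* is bookkept during simulation, independently of the
caller, as the number of reads spanning the event's gap with ≥ 5 aligned
bases on each side (for retention: covering a probe base unspliced) — the
reads a caller could possibly use.

What the fixtures do **not** emulate: alignment errors and soft-clipping,
mismapping in repeats, non-uniform coverage within a transcript,
incomplete annotations, multi-isoform genes beyond the two per event, or
UMI artefacts. Passing benchmarks therefore demonstrate the correctness
of the coordinate arithmetic, classification, quantification and
filtering logic — not robustness to aligner pathology.

## Scoring

A junction-type truth matches a call exactly when both intron ends agree,
nearly when both ends are within 10 bp (reported separately). Retention
truth matches a `NoSplice` call at either flanking site — the reporting
granularity for retention is per-site, so either side suffices. Two
signal classes are *attributed* to their event rather than counted as
recall or spurious: the second flanking site of a matched retained
intron, and the no-splice signal at the displaced boundary of an
alternative-site event (exon elongation necessarily covers the old
boundary's probe base). Precision is matched calls over matched plus
spurious; support cutoffs apply only when reading recall, never during
matching, so low-support truth still claims its calls.

## Benchmark sizes

The end-to-end benchmark uses 50 genes at 60× with the standard event
mix (~30 planted events, ~20 k reads), the realignment sweep 1 000 random
genome/junction pairs, and PSI recovery 2 000 informative reads at a true
PSI of 0.3 — sizes chosen so the full suite runs in seconds while every
event class appears many times. At these sizes all planted events with
≥ 10 supporting reads are recovered exactly; recall on real data is
bounded by the upstream aligner and is not claimed here.

## Known limitations

- GTF only (GFF3 `ID/Parent` graphs are out of scope); exon features and
  their `gene_id`/`transcript_id` attributes are the entire contract.
- No soft-clip realignment or split-read rescue: a junction the aligner
  did not gap is invisible.
- No cohort-level outlier statistics: the caller quantifies one sample
  at a time by design.
- Fusion candidates are loci pairs with evidence counts, not assembled
  breakpoints or reading frames.
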