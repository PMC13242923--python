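# sjcaller

Splice-junction detection, classification, PSI quantification and tiered
filtering for targeted short-read RNA-seq — aimed at clinical panel data,
where splicing aberrations must be found in *individual* samples without a
large cohort of controls, and where events diverging from the transcript
annotation (exon skips, intron retentions, alternative 5′/3′ sites, gene
fusions) are exactly the ones of interest.

`sjcaller` consumes coordinate-level evidence that upstream tools already
produce — deduplicated spliced alignments (SAM/BAM), a reference genome
(FASTA), a transcript annotation (GTF), and optionally a STAR-style
chimeric-junction table — and turns it into annotated, quantified,
filterable event tables. A built-in synthetic-fixture generator plants
known events in a toy genome so the whole stack is testable end to end
without any external data.

## The model

**Junctions.** Every `N` operation in a retained alignment is one
observation of a splice junction, recorded as the intron interval
(first intronic base, last intronic base, 1-based inclusive — the
`SJ.out.tab` convention). Gaps whose aligned flank is shorter than a
minimum anchor (default 5 bp) are ignored; strand is inferred from read
pair orientation when the library is stranded and rescued from the GT–AG
motif otherwise.

**Realignment.** A gapped alignment determines its intron only up to the
repeat content of the boundaries: if the bases at the intron start equal
the bases just after its end, the whole gap can slide without changing the
aligned sequence (the same ambiguity as indel left-alignment). All
sequence-equivalent placements are enumerated and the one most consistent
with the annotation is kept — ranked by number of annotated sites hit,
then annotated-junction membership, canonical GT–AG motif, smallest shift,
leftmost.

**Classification.** Each junction is classified by the annotation status
of its two splice sites: `Annotated` (both sites annotated and some
transcript holds the junction), `Plausible` (both annotated, never
paired), `Anchored` (one annotated), `Unknown` (none). The *absence* of
splicing at a site — reads running unspliced into the intron, the
signature of intron retention or exon elongation — is measured as the
aligned depth at the 3rd intronic base and treated as one more
alternative: `NoSplice` at an annotated site, `Trivial` at a de novo one.

**PSI.** For a site *s* and an alternative *j* (a junction using *s*, or
the no-splice alternative at *s*):

```
PSI(s, j) = reads_j / Σ_k reads_k   over all alternatives k at site s
```

Every junction gets two PSI values, one per site; PSI values at a site sum
to 1 whenever the site has any evidence.

**Fusions.** A junction whose two sites carry disjoint, non-empty gene
sets is a same-chromosome fusion candidate; chimeric-table rows joining
two chromosomes, incompatible strands, or loci > 1 Mb apart add
inter-locus candidates.

**Filters.** Four stringency tiers — `none`, `sensitive` (≥ 5 reads,
PSI ≥ 0.01), `intermediate` (≥ 10, 0.05), `stringent` (≥ 20, 0.10) — with
nested survivor sets; the filtering tiers report novel classes only,
leaving `Annotated`/`Trivial` rows to the unfiltered table.

## Worked example

```python
import sjcaller as sj
from sjcaller import fixtures as fx

ref   = fx.make_reference(seed=1, n_genes=8)          # toy genome + GTF models
truth = fx.plant_events(ref.models, seed=2)           # one event per ~62.5% of genes
sam   = fx.simulate_alignments(ref, truth, "demo.sam", depth=60, seed=3)

result = sj.run_sample(sam, models=ref.models, genome=ref.genome,
                       tier="sensitive", sample_id="demo")
for r in result.filtered:
    print(r.klass.value, r.chrom, r.start, r.end, r.split_reads,
          r.psi_left, r.psi_right)
```

prints (abridged):

```
Plausible chr1  421  720  43  0.524  0.422    # exon skip in G0001 (true PSI 0.38)
Anchored  chr1 1891 1959  36  0.655  1.0      # alt 3' site in G0002 (true PSI 0.56)
NoSplice  chr1 5671 5671  22  0.449  .        # retained intron, G0006 (true PSI 0.60)
NoSplice  chr1 5760 5760  39  .      0.591    #   ...its other flanking site
```

Each row is one alternative at its site(s): the exon skip joins two
annotated sites no transcript pairs (`Plausible`), carries 43 split reads,
and accounts for ~52% of the splicing observed at its donor; the retained
intron shows up as unspliced depth at both flanking sites of the intron.
Scoring against the planted truth:

```python
score = fx.score_calls(result.records, truth)
score.recall(min_support=10)   # 1.0  — all well-supported events recovered
score.precision()              # 1.0  — nothing called that was not planted
```

The same pipeline runs from the shell:

```sh
sjcaller call --bam sample.sam --gtf anno.gtf --fasta ref.fa \
    --filter sensitive --out results/run1
```

writing `results/run1.<sample>.filtered.tsv`, `...unfiltered.tsv` and, when
candidates exist, `...fusions.tsv`.

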