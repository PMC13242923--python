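"""End-to-end orchestration: alignments + annotation + genome -> event tables.

One sample at a time: extract gaps, realign ambiguous placements toward
the annotation, measure no-splice depth at every annotated and discovered
site, classify, compute PSI, call fusions, filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation import (
    GeneIntervals,
    JunctionCatalog,
    SpliceSiteIndex,
    build_gene_intervals,
    build_site_index,
    load_annotation,
)
from .events import (
    EventRecord,
    FusionCandidate,
    assemble_records,
    call_fusions,
    read_chimeric_table,
)
from .evidence import EvidenceConfig, Junction, extract_gaps, measure_depths
from .filters import apply_filter, get_tier
from .refine import realign_all

log = logging.getLogger(__name__)

__all__ = ["SampleResult", "run_sample"]


@dataclass
class SampleResult:
    sample_id: str
    junctions: dict[tuple[str, int, int], Junction]
    records: list[EventRecord]  # all records, unfiltered
    filtered: list[EventRecord]
    fusions: list[FusionCandidate] = field(default_factory=list)


def _load_genome(genome, fasta):
    if genome is not None:
        return genome
    if fasta is not None:
        import pyfaidx

        return pyfaidx.Fasta(fasta)
    return None


def run_sample(
    alignments,
    models=None,
    gtf=None,
    genome=None,
    fasta=None,
    chimeric=None,
    config: EvidenceConfig | None = None,
    tier: str = "none",
    tier_overrides=None,
    sample_id: str = "sample",
    max_shift: int = 100,
    fusion_distance: int = 1_000_000,
) -> SampleResult:
    """Run the full caller on one sample.

    ``alignments`` is a SAM/BAM path (or a re-iterable record collection);
    it is traversed twice: once for gaps, once for no-splice depth.
    Either ``models`` or ``gtf`` must be given; ``genome`` (dict or
    pyfaidx.Fasta) or ``fasta`` enables realignment and motif strand
    rescue.
    """
    if models is None:
        if gtf is None:
            raise ValueError("need models or gtf")
        models = load_annotation(gtf)
    genome = _load_genome(genome, fasta)
    config = config or EvidenceConfig()

    index, catalog = build_site_index(models)
    gene_intervals = build_gene_intervals(models)

    junctions = extract_gaps(alignments, config, genome=genome)
    n_raw = len(junctions)
    if genome is not None:
        junctions = realign_all(junctions, genome, index, catalog, max_shift)
    for junction in junctions.values():
        if junction.strand == ".":
            strands = index.strands_at(*junction.left_site) | index.strands_at(
                *junction.right_site
            )
            if len(strands) == 1:
                junction.strand = next(iter(strands))

    sites = set(index.sites())
    for junction in junctions.values():
        sites.add(junction.left_site)
        sites.add(junction.right_site)
    depths = measure_depths(alignments, sites, config)

    records = assemble_records(
        junctions, depths, index, catalog, gene_intervals, sample_id
    )
    chimeric_rows = read_chimeric_table(chimeric) if chimeric is not None else None
    fusions = call_fusions(records, chimeric_rows, fusion_distance)
    filtered = apply_filter(records, get_tier(tier, tier_overrides))
    log.info(
        "%s: %d raw junctions, %d after realignment, %d records, "
        "%d pass tier %s, %d fusion candidates",
        sample_id, n_raw, len(junctions), len(records), len(filtered), tier,
        len(fusions),
    )
    return SampleResult(
        sample_id=sample_id,
        junctions=junctions,
        records=records,
        filtered=filtered,
        fusions=fusions,
    )
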