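"""Shared fixtures: a hand-written toy annotation and read-construction helpers."""

from __future__ import annotations

import io

import pysam
import pytest

from sjcaller.annotation import build_site_index, load_annotation
from sjcaller import fixtures as fx

# Two genes on chr1: GENE1 with two transcripts sharing a donor (exons
# 101-200, 301-400, 501-600; the second transcript skips nothing but uses
# an alternative acceptor at 451), GENE2 with a single 2-exon transcript.
TOY_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GENE1"; transcript_id "T1"; gene_name "Alpha";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "GENE1"; transcript_id "T1"; gene_name "Alpha";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "GENE1"; transcript_id "T1"; gene_name "Alpha";
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GENE1"; transcript_id "T2"; gene_name "Alpha";
chr1\ttest\texon\t451\t600\t.\t+\t.\tgene_id "GENE1"; transcript_id "T2"; gene_name "Alpha";
chr1\ttest\texon\t1001\t1100\t.\t+\t.\tgene_id "GENE2"; transcript_id "T3";
chr1\ttest\texon\t1301\t1400\t.\t+\t.\tgene_id "GENE2"; transcript_id "T3";
"""


@pytest.fixture(scope="session")
def toy_models():
    return load_annotation(io.StringIO(TOY_GTF))


@pytest.fixture(scope="session")
def toy_index_catalog(toy_models):
    return build_site_index(toy_models)


@pytest.fixture(scope="session")
def sam_header():
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": "chr1", "LN": 100_000}, {"SN": "chr2", "LN": 100_000}],
        }
    )


@pytest.fixture
def make_read(sam_header):
    """Build a minimal aligned record: pos is 1-based, cigar a string."""

    def _make(
        pos: int,
        cigar: str,
        chrom: str = "chr1",
        flag: int = 0,
        mapq: int = 60,
        name: str = "read",
    ) -> pysam.AlignedSegment:
        seg = pysam.AlignedSegment(sam_header)
        seg.query_name = name
        seg.flag = flag
        seg.reference_name = chrom
        seg.reference_start = pos - 1
        seg.mapping_quality = mapq
        seg.cigarstring = cigar
        qlen = seg.infer_query_length()
        if qlen:
            seg.query_sequence = "A" * qlen
        return seg

    return _make


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """The desk-scale end-to-end benchmark: 50 genes, 60x, default event mix."""
    import sjcaller as sj

    out = tmp_path_factory.mktemp("e2e")
    ref = fx.make_reference(seed=11, n_genes=50, exons_per_gene=4)
    truth = fx.plant_events(ref.models, seed=12)
    sam = fx.simulate_alignments(ref, truth, str(out / "reads.sam"), depth=60, seed=13)
    result = sj.run_sample(sam, models=ref.models, genome=ref.genome, tier="none")
    return ref, truth, sam, result
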