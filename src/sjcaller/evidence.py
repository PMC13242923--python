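"""Split-read junction evidence and no-splice depth from aligned reads.

Junction evidence is the N (reference-skip) operations of retained CIGAR
strings; the no-splice alternative is measured as the aligned depth at a
probe base a fixed number of bases *inside* the putative intron (default:
the 3rd intronic base).  Reads are assumed UMI-deduplicated upstream;
duplicate-flagged records are skipped defensively.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pysam

log = logging.getLogger(__name__)

__all__ = [
    "Junction",
    "NoSpliceCount",
    "EvidenceConfig",
    "extract_gaps",
    "infer_orientation",
    "measure_depths",
    "measure_depth_inside",
]

# CIGAR operation codes (pysam numeric encoding)
_MATCH_OPS = frozenset({0, 7, 8})  # M, =, X
_REF_OPS = frozenset({0, 2, 3, 7, 8})  # consume reference
_QUERY_OPS = frozenset({0, 1, 4, 7, 8})  # consume query


@dataclass
class Junction:
    """A genomic gap (intron) with its split-read evidence.

    Coordinates are 1-based inclusive over the intron: ``intron_start`` is
    the first and ``intron_end`` the last intronic base.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "."
    split_reads: int = 0
    orientation_counts: Counter = field(default_factory=Counter)
    shift_applied: int = 0

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)

    @property
    def left_site(self) -> tuple[str, int, str]:
        return (self.chrom, self.intron_start, "left")

    @property
    def right_site(self) -> tuple[str, int, str]:
        return (self.chrom, self.intron_end, "right")

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron start > end: {self.chrom}:{self.intron_start}-{self.intron_end}"
            )


@dataclass(frozen=True)
class NoSpliceCount:
    """Unspliced read depth at the probe base of one splice site."""

    site: tuple[str, int, str]  # (chrom, pos, side)
    depth: int


@dataclass(frozen=True)
class EvidenceConfig:
    """Read-filtering and counting policy for evidence collection.

    strandedness
        'unstranded', 'forward' (FR: read 1 carries the transcript strand)
        or 'reverse' (RF: read 2 carries it).
    min_anchor
        Minimum aligned bases (M/=/X) flanking a gap on both sides for the
        gap to be counted.
    nosplice_offset
        The probe base is the offset-th intronic base (3 = "3 bases inside").
    count_fragments
        When True, overlapping mates observing the same gap (or probe base)
        count once per fragment instead of once per read.
    """

    strandedness: str = "unstranded"
    min_mapq: int = 0
    min_anchor: int = 5
    count_secondary: bool = False
    nosplice_offset: int = 3
    count_fragments: bool = False

    def __post_init__(self) -> None:
        if self.strandedness not in ("unstranded", "forward", "reverse"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")
        if self.min_anchor < 1:
            raise ValueError("min_anchor must be >= 1")
        if self.nosplice_offset < 1:
            raise ValueError("nosplice_offset must be >= 1")


def _open_alignments(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
) -> tuple[Iterable[pysam.AlignedSegment], bool]:
    """Return (record iterable, needs_close)."""
    if isinstance(alignments, str):
        handle = pysam.AlignmentFile(alignments, check_sq=False)
        return handle, True
    return alignments, False


def _retained(read: pysam.AlignedSegment, config: EvidenceConfig) -> bool:
    if read.is_unmapped or read.is_duplicate or read.is_qcfail:
        return False
    if read.is_secondary and not config.count_secondary:
        return False
    if read.mapping_quality < config.min_mapq:
        return False
    return True


def infer_orientation(flag: int, config: EvidenceConfig) -> str:
    """Infer template orientation from SAM flags under the library protocol.

    Returns 'sense' when the originating transcript lies on the forward
    genomic strand, 'antisense' for the reverse strand, 'unknown' for
    unstranded libraries.  Unpaired reads are treated as first-in-pair.
    """
    if config.strandedness == "unstranded":
        return "unknown"
    reverse = bool(flag & 0x10)
    second = bool(flag & 0x1) and bool(flag & 0x80)
    # forward (FR) protocol: read 1 maps on the transcript strand
    transcript_forward = reverse if second else not reverse
    if config.strandedness == "reverse":
        transcript_forward = not transcript_forward
    return "sense" if transcript_forward else "antisense"


def _iter_read_gaps(
    read: pysam.AlignedSegment, min_anchor: int
) -> Iterator[tuple[int, int]]:
    """Yield 1-based inclusive intron intervals for anchored N operations.

    The anchor of a gap is the number of aligned query bases (M/=/X) in the
    contiguous reference segment adjacent to it; both flanks must reach
    ``min_anchor``.
    """
    cigar = read.cigartuples
    if not cigar:
        return
    # split into reference segments separated by N, tracking aligned length
    segments: list[int] = []  # aligned (M/=/X) bases per segment
    gaps: list[tuple[int, int]] = []  # (start, end) 1-based per N op
    ref = read.reference_start  # 0-based
    aligned = 0
    for op, length in cigar:
        if op == 3:  # N
            gaps.append((ref + 1, ref + length))
            segments.append(aligned)
            aligned = 0
            ref += length
        elif op in _REF_OPS:
            if op in _MATCH_OPS:
                aligned += length
            ref += length
    segments.append(aligned)
    for i, gap in enumerate(gaps):
        if segments[i] >= min_anchor and segments[i + 1] >= min_anchor:
            yield gap


def extract_gaps(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    config: EvidenceConfig | None = None,
    genome=None,
) -> dict[tuple[str, int, int], Junction]:
    """Collect junction evidence from every N operation of retained records.

    Each retained record contributes one observation per anchored gap to the
    :class:`Junction` keyed by (chrom, intron interval); orientation counts
    are tallied per record.  Junction strand is the majority orientation
    ('.' when unstranded or tied); when a genome is supplied, strands left
    at '.' are rescued from the GT-AG / CT-AC intron motif.

    Input order is irrelevant: the result depends only on the record set.
    """
    config = config or EvidenceConfig()
    records, needs_close = _open_alignments(alignments)
    junctions: dict[tuple[str, int, int], Junction] = {}
    seen_fragments: set[tuple[str, str, int, int]] = set()
    skipped_no_ref = 0
    try:
        for read in records:
            if not _retained(read, config):
                continue
            chrom = read.reference_name
            if chrom is None:
                raise ValueError(f"record {read.query_name} has no reference name")
            if read.cigartuples and not any(
                op in _REF_OPS for op, _ in read.cigartuples
            ):
                skipped_no_ref += 1
                continue
            orientation = infer_orientation(read.flag, config)
            for start, end in _iter_read_gaps(read, config.min_anchor):
                if config.count_fragments:
                    frag_key = (read.query_name or "", chrom, start, end)
                    if frag_key in seen_fragments:
                        continue
                    seen_fragments.add(frag_key)
                key = (chrom, start, end)
                junction = junctions.get(key)
                if junction is None:
                    junction = Junction(chrom, start, end)
                    junctions[key] = junction
                junction.split_reads += 1
                junction.orientation_counts[orientation] += 1
    finally:
        if needs_close:
            records.close()  # type: ignore[union-attr]
    if skipped_no_ref:
        log.warning("skipped %d records whose CIGAR consumes no reference", skipped_no_ref)

    for junction in junctions.values():
        junction.strand = _majority_strand(junction.orientation_counts)
        if junction.strand == "." and genome is not None:
            junction.strand = motif_strand(genome, junction)
    return junctions


def _majority_strand(counts: Counter) -> str:
    sense = counts.get("sense", 0)
    anti = counts.get("antisense", 0)
    if sense > anti:
        return "+"
    if anti > sense:
        return "-"
    return "."


def motif_strand(genome, junction: Junction) -> str:
    """Strand implied by the canonical splice motif, or '.' if non-canonical.

    GT..AG on the forward strand reads as '+'; CT..AC (the reverse
    complement seen on the forward strand) as '-'.
    """
    from .refine import fetch_bases  # local import to avoid a cycle

    s, e = junction.intron_start, junction.intron_end
    donor = fetch_bases(genome, junction.chrom, s, s + 1)
    acceptor = fetch_bases(genome, junction.chrom, e - 1, e)
    if donor == "GT" and acceptor == "AG":
        return "+"
    if donor == "CT" and acceptor == "AC":
        return "-"
    return "."


def probe_position(site: tuple[str, int, str], offset: int = 3) -> int:
    """The probe base of a site: the offset-th base inside the intron.

    Left sites probe downstream (pos + offset - 1), right sites upstream
    (pos - offset + 1); offset 3 probes the 3rd intronic base.
    """
    chrom, pos, side = site
    if side == "left":
        return pos + offset - 1
    if side == "right":
        return pos - offset + 1
    raise ValueError(f"unknown site side {side!r}")


def measure_depths(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    sites: Iterable[tuple[str, int, str]],
    config: EvidenceConfig | None = None,
) -> dict[tuple[str, int, str], int]:
    """Unspliced depth at the probe base of each site, in one pass.

    A read contributes iff its alignment covers the probe base with a
    reference-consuming match state (M/=/X): deletions (D) and gaps (N)
    over the probe base do not count — a read spliced over the site is not
    evidence of its retention.
    """
    config = config or EvidenceConfig()
    probes: dict[tuple[str, int], list[tuple[str, int, str]]] = {}
    depths: dict[tuple[str, int, str], int] = {}
    for site in sites:
        depths.setdefault(site, 0)
        pos = probe_position(site, config.nosplice_offset)
        if pos < 1:
            log.warning("probe base for site %s falls outside the chromosome", site)
            continue
        probes.setdefault((site[0], pos), []).append(site)
    if not probes:
        return depths

    records, needs_close = _open_alignments(alignments)
    seen: set[tuple[str, str, int, str]] = set()
    try:
        for read in records:
            if not _retained(read, config):
                continue
            chrom = read.reference_name
            cigar = read.cigartuples
            if chrom is None or not cigar:
                continue
            ref = read.reference_start  # 0-based
            for op, length in cigar:
                if op in _REF_OPS:
                    if op in _MATCH_OPS:
                        for pos in range(ref + 1, ref + length + 1):
                            for site in probes.get((chrom, pos), ()):
                                if config.count_fragments:
                                    frag = (read.query_name or "", *site)
                                    if frag in seen:
                                        continue
                                    seen.add(frag)
                                depths[site] += 1
                    ref += length
    finally:
        if needs_close:
            records.close()  # type: ignore[union-attr]
    return depths


def measure_depth_inside(
    alignments: str | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    site: tuple[str, int, str],
    config: EvidenceConfig | None = None,
) -> NoSpliceCount:
    """No-splice depth at a single site (see :func:`measure_depths`)."""
    depths = measure_depths(alignments, [site], config)
    return NoSpliceCount(site=site, depth=depths[site])
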