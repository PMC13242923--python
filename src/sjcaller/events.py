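"""Junction classification, per-site alternative groups, PSI, fusions.

Each junction is classified by the annotation status of its two splice
sites:

* ``Annotated`` — both sites annotated and at least one transcript holds
  the junction;
* ``Plausible`` — both sites annotated but no transcript pairs them
  (e.g. an exon skip);
* ``Anchored`` — exactly one site annotated (e.g. an alternative 5'/3'
  site);
* ``Unknown`` — neither site annotated.

The absence of splicing at a site (reads running unspliced into the
intron, as in intron retention or exon elongation) is itself an
alternative:

* ``NoSplice`` — no-splice at an annotated site;
* ``Trivial`` — no-splice at a site only discovered from reads.

PSI of an alternative at a site is its count over the site total, the
no-splice alternative included in the denominator; every junction gets
two PSI values, one per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

from .annotation import GeneIntervals, JunctionCatalog, SpliceSiteIndex
from .evidence import Junction

log = logging.getLogger(__name__)

__all__ = [
    "JunctionClass",
    "SiteGroup",
    "EventRecord",
    "FusionCandidate",
    "classify_junction",
    "classify_nosplice",
    "build_site_groups",
    "compute_psi",
    "assemble_records",
    "read_chimeric_table",
    "call_fusions",
]


class JunctionClass(str, Enum):
    ANNOTATED = "Annotated"
    PLAUSIBLE = "Plausible"
    ANCHORED = "Anchored"
    UNKNOWN = "Unknown"
    NOSPLICE = "NoSplice"
    TRIVIAL = "Trivial"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: alternative identifiers within a site group
JunctionAlt = tuple[str, str, int, int, str]  # ("J", chrom, start, end, strand)
NoSpliceAlt = tuple[str, str, int, str]  # ("NS", chrom, pos, side)


def junction_alt_id(junction: Junction) -> JunctionAlt:
    return ("J", junction.chrom, junction.intron_start, junction.intron_end, junction.strand)


def nosplice_alt_id(site: tuple[str, int, str]) -> NoSpliceAlt:
    return ("NS", site[0], site[1], site[2])


@dataclass
class SiteGroup:
    """All competing alternatives observed at one splice site.

    Alternatives are the junctions using the site plus at most one
    no-splice alternative; PSI denominators are the group totals.
    """

    site: tuple[str, int, str, str]  # (chrom, pos, side, strand)
    alternatives: list[tuple[tuple, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(count for _, count in self.alternatives)


@dataclass
class EventRecord:
    """One classified, PSI-annotated row of the output tables.

    Junction rows span the intron; no-splice rows sit on their site
    (start == end == site position).  A PSI of ``None`` means the site
    group total was zero (undefined, written as '.').
    """

    kind: str  # "junction" | "nosplice"
    chrom: str
    start: int
    end: int
    strand: str
    klass: JunctionClass
    split_reads: int
    psi_left: float | None = None
    psi_right: float | None = None
    genes_left: frozenset[str] = frozenset()
    genes_right: frozenset[str] = frozenset()
    nosplice_depth_left: int = 0
    nosplice_depth_right: int = 0
    shift_applied: int = 0
    sample_id: str = "sample"
    site_side: str | None = None  # for no-splice rows

    @property
    def max_psi(self) -> float | None:
        defined = [p for p in (self.psi_left, self.psi_right) if p is not None]
        return max(defined) if defined else None


def classify_junction(
    junction: Junction, site_index: SpliceSiteIndex, catalog: JunctionCatalog
) -> JunctionClass:
    """Classify a (refined) junction by the status of its two sites."""
    chrom, s, e = junction.chrom, junction.intron_start, junction.intron_end
    strand = junction.strand
    n_annotated = int(site_index.has_site(chrom, s, "left", strand)) + int(
        site_index.has_site(chrom, e, "right", strand)
    )
    if n_annotated == 2:
        if catalog.contains(chrom, s, e, strand):
            return JunctionClass.ANNOTATED
        return JunctionClass.PLAUSIBLE
    if n_annotated == 1:
        return JunctionClass.ANCHORED
    return JunctionClass.UNKNOWN


def classify_nosplice(
    site: tuple[str, int, str], site_index: SpliceSiteIndex
) -> JunctionClass:
    """No-splice at an annotated site is NoSplice; at a de novo site, Trivial."""
    if site_index.has_site(site[0], site[1], site[2], "."):
        return JunctionClass.NOSPLICE
    return JunctionClass.TRIVIAL


def build_site_groups(
    junctions: Mapping[tuple[str, int, int], Junction] | Iterable[Junction],
    nosplice_counts: Mapping[tuple[str, int, str], int] | None = None,
) -> dict[tuple[str, int, str, str], SiteGroup]:
    """Group junction and no-splice counts per splice site.

    Every site used by at least one junction, or with no-splice depth
    measured, yields a group.  Groups are keyed per strand (sites are not
    pooled across strands); the strand-less no-splice depth of a
    (chrom, pos, side) attaches to every group at that position and side,
    and forms its own '.'-strand group when no junction uses the site.
    """
    if isinstance(junctions, Mapping):
        junctions = junctions.values()
    nosplice_counts = nosplice_counts or {}

    groups: dict[tuple[str, int, str, str], SiteGroup] = {}
    by_pos_side: dict[tuple[str, int, str], list[SiteGroup]] = {}

    def get_group(site3: tuple[str, int, str], strand: str) -> SiteGroup:
        key = (*site3, strand)
        group = groups.get(key)
        if group is None:
            group = SiteGroup(site=key)
            groups[key] = group
            by_pos_side.setdefault(site3, []).append(group)
        return group

    for junction in junctions:
        alt = junction_alt_id(junction)
        for site3 in (junction.left_site, junction.right_site):
            get_group(site3, junction.strand).alternatives.append(
                (alt, junction.split_reads)
            )

    for site3, depth in nosplice_counts.items():
        holders = by_pos_side.get(site3)
        if holders is None:
            if depth > 0:
                holders = [get_group(site3, ".")]
            else:
                continue  # site never touched by any read: no group
        alt = nosplice_alt_id(site3)
        for group in holders:
            group.alternatives.append((alt, depth))
    return groups


def compute_psi(group: SiteGroup) -> dict[tuple, float]:
    """PSI of each alternative: count / site total.

    Empty when the total is zero (all PSI undefined).  The no-splice
    alternative is an ordinary member of the denominator.
    """
    total = group.total
    if total <= 0:
        return {}
    return {alt: count / total for alt, count in group.alternatives}


def _site_genes(
    chrom: str,
    pos: int,
    side: str,
    site_index: SpliceSiteIndex,
    gene_intervals: GeneIntervals | None,
) -> frozenset[str]:
    genes = site_index.genes_at(chrom, pos, side)
    if not genes and gene_intervals is not None:
        genes = gene_intervals.genes_at(chrom, pos)
    return genes


def assemble_records(
    junctions: Mapping[tuple[str, int, int], Junction],
    nosplice_counts: Mapping[tuple[str, int, str], int],
    site_index: SpliceSiteIndex,
    catalog: JunctionCatalog,
    gene_intervals: GeneIntervals | None = None,
    sample_id: str = "sample",
) -> list[EventRecord]:
    """Classify and PSI-annotate every junction and informative no-splice site.

    No-splice rows at sites never touched by any read (zero depth and no
    junction) are suppressed as zero-information.
    """
    groups = build_site_groups(junctions, nosplice_counts)
    psi: dict[tuple[str, int, str, str], dict[tuple, float]] = {
        key: compute_psi(group) for key, group in groups.items()
    }

    records: list[EventRecord] = []
    for junction in junctions.values():
        alt = junction_alt_id(junction)
        lkey = (*junction.left_site, junction.strand)
        rkey = (*junction.right_site, junction.strand)
        records.append(
            EventRecord(
                kind="junction",
                chrom=junction.chrom,
                start=junction.intron_start,
                end=junction.intron_end,
                strand=junction.strand,
                klass=classify_junction(junction, site_index, catalog),
                split_reads=junction.split_reads,
                psi_left=psi[lkey].get(alt),
                psi_right=psi[rkey].get(alt),
                genes_left=_site_genes(
                    junction.chrom, junction.intron_start, "left", site_index, gene_intervals
                ),
                genes_right=_site_genes(
                    junction.chrom, junction.intron_end, "right", site_index, gene_intervals
                ),
                nosplice_depth_left=nosplice_counts.get(junction.left_site, 0),
                nosplice_depth_right=nosplice_counts.get(junction.right_site, 0),
                shift_applied=junction.shift_applied,
                sample_id=sample_id,
            )
        )

    emitted: set[tuple[str, int, str]] = set()
    for key, group in groups.items():
        chrom, pos, side, strand = key
        site3 = (chrom, pos, side)
        alt = nosplice_alt_id(site3)
        depth = nosplice_counts.get(site3)
        if depth is None or depth <= 0 or site3 in emitted:
            continue
        if not any(a == alt for a, _ in group.alternatives):
            continue
        emitted.add(site3)
        p = psi[key].get(alt)
        genes = _site_genes(chrom, pos, side, site_index, gene_intervals)
        records.append(
            EventRecord(
                kind="nosplice",
                chrom=chrom,
                start=pos,
                end=pos,
                strand=strand,
                klass=classify_nosplice(site3, site_index),
                split_reads=depth,
                psi_left=p if side == "left" else None,
                psi_right=p if side == "right" else None,
                genes_left=genes if side == "left" else frozenset(),
                genes_right=genes if side == "right" else frozenset(),
                nosplice_depth_left=depth if side == "left" else 0,
                nosplice_depth_right=depth if side == "right" else 0,
                sample_id=sample_id,
                site_side=side,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.kind))
    return records


@dataclass(frozen=True)
class FusionCandidate:
    """Two loci joined by splicing or chimeric evidence, in distinct genes."""

    site_a: tuple[str, int]  # (chrom, pos)
    site_b: tuple[str, int]
    genes_a: frozenset[str]
    genes_b: frozenset[str]
    split_reads: int
    chimeric_reads: int
    same_chrom: bool


#: columns of the STAR Chimeric.out.junction dialect we consume
_CHIMERIC_COLS = 14


def read_chimeric_table(source: str | IO[str]) -> list[dict]:
    """Parse a STAR ``Chimeric.out.junction``-style table (one row per read).

    Only the six locus columns are interpreted; malformed rows are skipped
    with a warning.
    """
    if hasattr(source, "read"):
        lines = source
    else:
        lines = open(source, "rt")
    rows: list[dict] = []
    skipped = 0
    with lines:  # type: ignore[arg-type]
        for raw in lines:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chr_donorA\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                skipped += 1
                continue
            try:
                row = {
                    "chrom_a": fields[0],
                    "pos_a": int(fields[1]),
                    "strand_a": fields[2],
                    "chrom_b": fields[3],
                    "pos_b": int(fields[4]),
                    "strand_b": fields[5],
                }
            except ValueError:
                skipped += 1
                continue
            rows.append(row)
    if skipped:
        log.warning("skipped %d malformed chimeric rows", skipped)
    return rows


def call_fusions(
    records: Sequence[EventRecord],
    chimeric_rows: Sequence[dict] | None = None,
    distance_threshold: int = 1_000_000,
) -> list[FusionCandidate]:
    """Call gene-fusion candidates from junction and chimeric evidence.

    A junction whose two sites carry disjoint, non-empty gene sets is a
    same-chromosome candidate.  A chimeric row joining two chromosomes,
    incompatible strands, or loci farther apart than ``distance_threshold``
    is an inter-locus candidate; rows aggregate per locus pair, evidence
    being the read count.
    """
    candidates: list[FusionCandidate] = []
    for rec in records:
        if rec.kind != "junction":
            continue
        if not rec.genes_left or not rec.genes_right:
            continue
        if rec.genes_left & rec.genes_right:
            continue
        candidates.append(
            FusionCandidate(
                site_a=(rec.chrom, rec.start),
                site_b=(rec.chrom, rec.end),
                genes_a=rec.genes_left,
                genes_b=rec.genes_right,
                split_reads=rec.split_reads,
                chimeric_reads=0,
                same_chrom=True,
            )
        )

    if chimeric_rows:
        tallies: dict[tuple, int] = {}
        for row in chimeric_rows:
            different_chrom = row["chrom_a"] != row["chrom_b"]
            incompatible_strand = (
                not different_chrom and row["strand_a"] != row["strand_b"]
            )
            distant = (
                not different_chrom
                and abs(row["pos_a"] - row["pos_b"]) > distance_threshold
            )
            if not (different_chrom or incompatible_strand or distant):
                continue
            key = (row["chrom_a"], row["pos_a"], row["chrom_b"], row["pos_b"])
            tallies[key] = tallies.get(key, 0) + 1
        for (chrom_a, pos_a, chrom_b, pos_b), count in sorted(tallies.items()):
            candidates.append(
                FusionCandidate(
                    site_a=(chrom_a, pos_a),
                    site_b=(chrom_b, pos_b),
                    genes_a=frozenset(),
                    genes_b=frozenset(),
                    split_reads=0,
                    chimeric_reads=count,
                    same_chrom=chrom_a == chrom_b,
                )
            )
    return candidates
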