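"""Placement ambiguity of gaps and realignment toward annotated sites.

A gapped alignment only determines an intron up to the repeat content of
its boundaries: when the bases at the intron start equal the bases just
after its end, sliding the whole gap leaves the implied aligned sequence
unchanged (the same ambiguity indel left-alignment resolves).  Aligners
pick one placement arbitrarily; here every sequence-equivalent placement
is enumerated and the one most consistent with the annotation is kept.

Equivalence is defined on the reference sequence alone, so all reads of a
junction shift together.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .annotation import JunctionCatalog, SpliceSiteIndex
from .evidence import Junction

__all__ = ["ShiftRange", "shift_range", "realign_junction", "realign_all", "fetch_bases"]

#: never scan further than this, to guard against pathological repeats
MAX_SHIFT = 100


@dataclass(frozen=True)
class ShiftRange:
    """How far a gap can slide left/right without changing the alignment."""

    max_left: int
    max_right: int


def _chrom_length(genome, chrom: str) -> int:
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} not in genome") from exc
    return len(seq)


def fetch_bases(genome, chrom: str, start: int, end: int) -> str:
    """Uppercase genome bases, 1-based inclusive; works for dict-of-str and
    pyfaidx.Fasta alike.  Out-of-bounds requests are clipped."""
    seq = genome[chrom]
    lo = max(start - 1, 0)
    hi = min(end, len(seq))
    if lo >= hi:
        return ""
    return str(seq[lo:hi]).upper()


def shift_range(genome, junction: Junction, max_shift: int = MAX_SHIFT) -> ShiftRange:
    """Maximal equivalent slide of a gap in each direction.

    For intron (s, e): sliding right by k is equivalence-preserving iff
    genome[s .. s+k-1] == genome[e+1 .. e+k] base for base; left
    symmetrically.  Scanning stops at the first mismatch, the chromosome
    edge, or ``max_shift``.
    """
    chrom = junction.chrom
    n = _chrom_length(genome, chrom)
    s, e = junction.intron_start, junction.intron_end
    if s < 1 or e > n:
        raise ValueError(
            f"junction {chrom}:{s}-{e} outside chromosome bounds (length {n})"
        )
    max_right = 0
    for k in range(1, max_shift + 1):
        if e + k > n:
            break
        if fetch_bases(genome, chrom, s + k - 1, s + k - 1) != fetch_bases(
            genome, chrom, e + k, e + k
        ):
            break
        max_right = k
    max_left = 0
    for k in range(1, max_shift + 1):
        if s - k < 1:
            break
        if fetch_bases(genome, chrom, s - k, s - k) != fetch_bases(
            genome, chrom, e - k + 1, e - k + 1
        ):
            break
        max_left = k
    return ShiftRange(max_left=max_left, max_right=max_right)


def _is_canonical(genome, chrom: str, s: int, e: int, strand: str) -> bool:
    donor = fetch_bases(genome, chrom, s, s + 1)
    acceptor = fetch_bases(genome, chrom, e - 1, e)
    forward = donor == "GT" and acceptor == "AG"
    reverse = donor == "CT" and acceptor == "AC"
    if strand == "+":
        return forward
    if strand == "-":
        return reverse
    return forward or reverse


def placement_score(
    genome,
    chrom: str,
    s: int,
    e: int,
    strand: str,
    site_index: SpliceSiteIndex,
    catalog: JunctionCatalog,
    k: int,
) -> tuple:
    """Ranking key of one candidate placement (higher is better):
    annotated-site count, catalog membership, canonical motif, smaller
    absolute shift, leftmost."""
    n_sites = int(site_index.has_site(chrom, s, "left", strand)) + int(
        site_index.has_site(chrom, e, "right", strand)
    )
    in_catalog = int(catalog.contains(chrom, s, e, strand))
    canonical = int(_is_canonical(genome, chrom, s, e, strand))
    return (n_sites, in_catalog, canonical, -abs(k), -k)


def realign_junction(
    junction: Junction,
    genome,
    site_index: SpliceSiteIndex,
    catalog: JunctionCatalog,
    max_shift: int = MAX_SHIFT,
) -> Junction:
    """Shift a junction to the most annotation-consistent equivalent placement.

    Junctions whose two sites are both annotated are returned unchanged.
    Evidence counts are carried over; ``shift_applied`` records the slide.
    """
    chrom, s, e = junction.chrom, junction.intron_start, junction.intron_end
    strand = junction.strand
    if site_index.has_site(chrom, s, "left", strand) and site_index.has_site(
        chrom, e, "right", strand
    ):
        return junction
    rng = shift_range(genome, junction, max_shift=max_shift)
    best_k = 0
    best_score = placement_score(genome, chrom, s, e, strand, site_index, catalog, 0)
    for k in range(-rng.max_left, rng.max_right + 1):
        if k == 0:
            continue
        score = placement_score(
            genome, chrom, s + k, e + k, strand, site_index, catalog, k
        )
        if score > best_score:
            best_score = score
            best_k = k
    if best_k == 0:
        return junction
    shifted = replace(
        junction,
        intron_start=s + best_k,
        intron_end=e + best_k,
        shift_applied=junction.shift_applied + best_k,
    )
    return shifted


def realign_all(
    junctions: dict[tuple[str, int, int], Junction],
    genome,
    site_index: SpliceSiteIndex,
    catalog: JunctionCatalog,
    max_shift: int = MAX_SHIFT,
) -> dict[tuple[str, int, int], Junction]:
    """Realign every junction; placements that collide merge their evidence."""
    out: dict[tuple[str, int, int], Junction] = {}
    for junction in junctions.values():
        shifted = realign_junction(junction, genome, site_index, catalog, max_shift)
        key = shifted.key
        present = out.get(key)
        if present is None:
            out[key] = shifted
        else:
            present.split_reads += shifted.split_reads
            present.orientation_counts.update(shifted.orientation_counts)
            if present.strand == ".":
                present.strand = shifted.strand
    return out
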