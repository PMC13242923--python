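"""Transcript annotation parsing and splice-site indexing.

A splice *site* is one boundary of an intron: the "left" site is the first
intronic base, the "right" site the last intronic base (1-based inclusive,
the SJ.out.tab convention).  Which one is the donor depends on the strand.
The :class:`SpliceSiteIndex` and :class:`JunctionCatalog` derived here are
what junction classification and realignment are checked against.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "Exon",
    "TranscriptModel",
    "SpliceSiteIndex",
    "JunctionCatalog",
    "GeneIntervals",
    "MalformedAnnotationError",
    "load_annotation",
    "build_site_index",
    "build_gene_intervals",
]


class MalformedAnnotationError(ValueError):
    """Raised when the annotation violates basic structural constraints."""


@dataclass(frozen=True)
class Exon:
    """One exon; coordinates are 1-based inclusive genomic positions."""

    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MalformedAnnotationError(
                f"exon end < start for transcript {self.transcript_id}: "
                f"{self.chrom}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered, non-overlapping exon chain on one strand."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (first intronic base, last intronic base)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append((a.end + 1, b.start - 1))
        return out

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


class SpliceSiteIndex:
    """Annotated splice sites, with the gene(s) each site belongs to.

    Sites are keyed by ``(chrom, pos, side)`` with the set of annotated
    strands stored alongside; lookups with strand ``'.'`` match any strand
    (unstranded evidence cannot rule a strand out).
    """

    def __init__(self) -> None:
        self._strands: dict[tuple[str, int, str], set[str]] = {}
        self._genes: dict[tuple[str, int, str], set[str]] = {}

    def add(self, chrom: str, pos: int, side: str, strand: str, gene_id: str) -> None:
        key = (chrom, pos, side)
        self._strands.setdefault(key, set()).add(strand)
        self._genes.setdefault(key, set()).add(gene_id)

    def has_site(self, chrom: str, pos: int, side: str, strand: str = ".") -> bool:
        strands = self._strands.get((chrom, pos, side))
        if not strands:
            return False
        return strand in (".", None) or strand in strands

    def genes_at(self, chrom: str, pos: int, side: str) -> frozenset[str]:
        return frozenset(self._genes.get((chrom, pos, side), ()))

    def strands_at(self, chrom: str, pos: int, side: str) -> frozenset[str]:
        return frozenset(self._strands.get((chrom, pos, side), ()))

    def sites(self) -> Iterator[tuple[str, int, str]]:
        return iter(self._strands)

    def __len__(self) -> int:
        return len(self._strands)


class JunctionCatalog:
    """The set of introns present in at least one annotated transcript."""

    def __init__(self) -> None:
        self._strands: dict[tuple[str, int, int], set[str]] = {}

    def add(self, chrom: str, start: int, end: int, strand: str) -> None:
        self._strands.setdefault((chrom, start, end), set()).add(strand)

    def contains(self, chrom: str, start: int, end: int, strand: str = ".") -> bool:
        strands = self._strands.get((chrom, start, end))
        if not strands:
            return False
        return strand in (".", None) or strand in strands

    def __len__(self) -> int:
        return len(self._strands)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self._strands)


class GeneIntervals:
    """Gene spans per chromosome, for assigning genes to arbitrary positions."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, gene_id: str) -> None:
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, gene_id)

    def genes_at(self, chrom: str, pos: int) -> frozenset[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return frozenset()
        return frozenset(iv.data for iv in tree.at(pos))


def _open_text(source: str | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    with open(source, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(source, "rt")
    return open(source, "rt")


def load_annotation(gtf: str | IO[str] | Iterable[str]) -> list[TranscriptModel]:
    """Parse GTF ``exon`` features into :class:`TranscriptModel` objects.

    Non-exon features are ignored.  Exons are grouped by ``transcript_id``
    and sorted by start, so line order in the input is irrelevant.
    ``gene_name`` falls back to ``gene_id`` when the attribute is absent.
    Gzip-compressed files are read transparently.

    Raises
    ------
    MalformedAnnotationError
        If an exon has end < start (the offending line is named), or a
        transcript's exons span more than one chromosome or strand.
    """
    if isinstance(gtf, str) or hasattr(gtf, "read"):
        lines: Iterable[str] = _open_text(gtf)  # type: ignore[arg-type]
    else:
        lines = gtf

    by_tx: dict[str, list[Exon]] = {}
    names: dict[str, tuple[str, str]] = {}  # transcript_id -> (gene_id, gene_name)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = gffutils.feature.feature_from_line(line)
        except Exception as exc:  # malformed line
            raise MalformedAnnotationError(f"line {lineno}: {exc}") from exc
        if feat.featuretype != "exon":
            continue
        attrs = feat.attributes
        try:
            tx_id = attrs["transcript_id"][0]
            gene_id = attrs["gene_id"][0]
        except KeyError as exc:
            raise MalformedAnnotationError(
                f"line {lineno}: exon lacks {exc} attribute"
            ) from exc
        gene_name = attrs["gene_name"][0] if "gene_name" in attrs else gene_id
        if feat.end < feat.start:
            raise MalformedAnnotationError(
                f"line {lineno}: exon end < start ({line})"
            )
        by_tx.setdefault(tx_id, []).append(
            Exon(feat.seqid, feat.start, feat.end, feat.strand, tx_id, gene_id)
        )
        names[tx_id] = (gene_id, gene_name)

    models = []
    for tx_id, exons in by_tx.items():
        exons.sort(key=lambda e: e.start)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1:
            raise MalformedAnnotationError(
                f"transcript {tx_id} spans chromosomes {sorted(chroms)}"
            )
        if len(strands) > 1:
            raise MalformedAnnotationError(
                f"transcript {tx_id} mixes strands {sorted(strands)}"
            )
        gene_id, gene_name = names[tx_id]
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_id,
                gene_name=gene_name,
                chrom=exons[0].chrom,
                strand=exons[0].strand,
                exons=tuple(exons),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


def build_site_index(
    models: Iterable[TranscriptModel],
) -> tuple[SpliceSiteIndex, JunctionCatalog]:
    """Derive the splice-site index and annotated-junction catalog.

    Every intron (s, e) of every transcript contributes a left site at s,
    a right site at e, and the catalog junction (chrom, s, e, strand).
    Duplicates across transcripts collapse.
    """
    index = SpliceSiteIndex()
    catalog = JunctionCatalog()
    for model in models:
        for s, e in model.introns():
            index.add(model.chrom, s, "left", model.strand, model.gene_id)
            index.add(model.chrom, e, "right", model.strand, model.gene_id)
            catalog.add(model.chrom, s, e, model.strand)
    return index, catalog


def build_gene_intervals(models: Iterable[TranscriptModel]) -> GeneIntervals:
    """Gene spans (union of transcript extents per gene) as interval trees."""
    spans: dict[tuple[str, str], tuple[int, int]] = {}
    for m in models:
        key = (m.chrom, m.gene_id)
        if key in spans:
            s, e = spans[key]
            spans[key] = (min(s, m.start), max(e, m.end))
        else:
            spans[key] = (m.start, m.end)
    out = GeneIntervals()
    for (chrom, gene_id), (s, e) in spans.items():
        out.add(chrom, s, e, gene_id)
    return out
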