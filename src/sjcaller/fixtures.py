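"""Synthetic genome/annotation/alignment fixtures with planted splicing events.

The generator emulates, at desk scale, what a splicing-event benchmark
needs: a random toy genome with embedded multi-exon genes (canonical GT-AG
motifs at every annotated intron), per-gene planted events — exon skip,
multi-exon skip, intron retention, alternative 5'/3' site (12.5% chance
each) or no event (37.5%) — at a drawn true PSI, and paired-end alignments
whose CIGAR strings carry the implied gaps (N) or retained introns (M).
A scorer compares caller output against the planted truth, counting calls
off by at most 10 bp at either end separately as near-matches.

Everything is seed-deterministic; all outputs are plain text (FASTA, GTF,
SAM, TSV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import IO, Mapping, Sequence

import numpy as np
import pysam

from .annotation import Exon, TranscriptModel
from .events import EventRecord, JunctionClass

log = logging.getLogger(__name__)

__all__ = [
    "Reference",
    "TruthEvent",
    "MatchResult",
    "ScoreResult",
    "make_reference",
    "plant_events",
    "plant_fusion",
    "simulate_alignments",
    "simulate_junction_reads",
    "write_chimeric_table",
    "score_calls",
    "DEFAULT_EVENT_PROBS",
]

#: per-gene event class probabilities used throughout the benchmarks
DEFAULT_EVENT_PROBS: dict[str, float] = {
    "exon_skip": 0.125,
    "multi_exon_skip": 0.125,
    "intron_retention": 0.125,
    "alt5": 0.125,
    "alt3": 0.125,
    "none": 0.375,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Reference:
    """A toy genome with its transcript annotation."""

    genome: dict[str, str]
    models: list[TranscriptModel]

    def write_fasta(self, path: str) -> str:
        with open(path, "wt") as out:
            for chrom in sorted(self.genome):
                out.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    out.write(seq[i : i + 60] + "\n")
        return path

    def write_gtf(self, path: str) -> str:
        with open(path, "wt") as out:
            for model in self.models:
                for exon in model.exons:
                    attrs = (
                        f'gene_id "{model.gene_id}"; '
                        f'transcript_id "{model.transcript_id}"; '
                        f'gene_name "{model.gene_name}";'
                    )
                    out.write(
                        "\t".join(
                            [
                                exon.chrom,
                                "fixture",
                                "exon",
                                str(exon.start),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )
        return path


@dataclass
class TruthEvent:
    """Ground truth for one planted event.

    ``junction`` is the aberrant intron (first, last intronic base) for
    junction-type events; ``retained_intron`` the retained interval for
    intron retention.  ``base_intron`` is the annotated intron the event
    modified (for alt sites, the one whose boundary moved), used by the
    scorer to attribute the unavoidable exon-elongation signal.
    ``support`` is filled by the simulator: reads evidencing the event
    with at least 5 aligned bases on each side of the gap (for retention,
    reads covering a probe base unspliced).
    """

    gene_id: str
    event_type: str
    chrom: str
    true_psi: float
    junction: tuple[int, int] | None = None
    retained_intron: tuple[int, int] | None = None
    base_intron: tuple[int, int] | None = None
    aberrant_blocks: tuple[tuple[int, int], ...] = ()
    support: int = 0
    partner_gene: str | None = None


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_reference(
    seed: int,
    n_genes: int = 10,
    exons_per_gene: int = 4,
    exon_len: int = 120,
    intron_len: int = 90,
    n_chroms: int = 1,
    spacer: int = 300,
    chrom_len: int | None = None,
) -> Reference:
    """Build a random toy genome with embedded genes.

    Genes are laid out left to right with ``spacer`` intergenic bases,
    round-robin across ``n_chroms`` chromosomes, on random strands.
    Canonical splice motifs (GT..AG on the gene strand) are written at
    every annotated intron boundary.  Deterministic for a given seed.

    Raises
    ------
    ValueError
        If an explicit ``chrom_len`` cannot hold the requested layout.
    """
    if min(n_genes, exons_per_gene, exon_len, intron_len) < 1:
        raise ValueError("all sizes must be positive")
    rng = np.random.default_rng(seed)
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    per_chrom = -(-n_genes // n_chroms)  # ceil
    needed = spacer + per_chrom * (gene_span + spacer)
    if chrom_len is not None and chrom_len < needed:
        raise ValueError(
            f"layout needs {needed} bp per chromosome but chrom_len={chrom_len}"
        )
    length = chrom_len or needed

    chroms = [f"chr{c + 1}" for c in range(n_chroms)]
    seqs = {c: _random_seq(rng, length) for c in chroms}
    models: list[TranscriptModel] = []
    cursors = {c: spacer for c in chroms}
    for g in range(n_genes):
        chrom = chroms[g % n_chroms]
        start = cursors[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"G{g + 1:04d}"
        tx_id = f"{gene_id}.t1"
        exons = []
        pos = start
        for _ in range(exons_per_gene):
            exons.append(
                Exon(chrom, pos + 1, pos + exon_len, strand, tx_id, gene_id)
            )
            pos += exon_len + intron_len
        model = TranscriptModel(tx_id, gene_id, gene_id, chrom, strand, tuple(exons))
        models.append(model)
        seq = seqs[chrom]
        for s, e in model.introns():  # write canonical motifs (1-based s, e)
            donor, acceptor = (b"GT", b"AG") if strand == "+" else (b"CT", b"AC")
            seq[s - 1 : s + 1] = np.frombuffer(donor, dtype="S1")
            seq[e - 2 : e] = np.frombuffer(acceptor, dtype="S1")
        cursors[chrom] = pos - intron_len + spacer
    genome = {c: seqs[c].tobytes().decode() for c in chroms}
    return Reference(genome=genome, models=models)


def _blocks(model: TranscriptModel) -> tuple[tuple[int, int], ...]:
    return tuple((e.start, e.end) for e in model.exons)


def _make_event(
    model: TranscriptModel,
    event_type: str,
    rng: np.random.Generator,
    psi_range: tuple[float, float],
    alt_offset_range: tuple[int, int],
    partner: TranscriptModel | None = None,
) -> TruthEvent | None:
    """Construct one event on a gene, or None if the gene cannot host it."""
    exons = _blocks(model)
    introns = model.introns()
    n = len(exons)
    psi = float(rng.uniform(*psi_range))
    ev = TruthEvent(model.gene_id, event_type, model.chrom, psi)

    if event_type == "exon_skip":
        if n < 3:
            return None
        k = int(rng.integers(1, n - 1))
        ev.junction = (exons[k - 1][1] + 1, exons[k + 1][0] - 1)
        ev.aberrant_blocks = exons[:k] + exons[k + 1 :]
    elif event_type == "multi_exon_skip":
        if n < 4:
            return None
        m = int(rng.integers(2, n - 1))  # number of skipped exons
        k = int(rng.integers(1, n - m))
        ev.junction = (exons[k - 1][1] + 1, exons[k + m][0] - 1)
        ev.aberrant_blocks = exons[:k] + exons[k + m :]
    elif event_type == "intron_retention":
        if n < 2:
            return None
        i = int(rng.integers(0, n - 1))
        ev.retained_intron = introns[i]
        merged = (exons[i][0], exons[i + 1][1])
        ev.aberrant_blocks = exons[:i] + (merged,) + exons[i + 2 :]
    elif event_type in ("alt5", "alt3"):
        if n < 2:
            return None
        i = int(rng.integers(0, n - 1))
        s, e = introns[i]
        lo, hi = alt_offset_range
        hi = min(hi, (e - s + 1) - 2 * 3 - 1)  # keep probe bases intronic
        if hi < lo:
            return None
        off = int(rng.integers(lo, hi + 1))
        # which genomic boundary is the transcript-5' one depends on strand
        move_left = (event_type == "alt5") == (model.strand == "+")
        if move_left:  # extend the upstream exon into the intron
            ev.junction = (s + off, e)
            left = (exons[i][0], s + off - 1)
            ev.aberrant_blocks = exons[:i] + (left,) + exons[i + 1 :]
        else:
            ev.junction = (s, e - off)
            right = (e - off + 1, exons[i + 1][1])
            ev.aberrant_blocks = exons[: i + 1] + (right,) + exons[i + 2 :]
        ev.base_intron = (s, e)
    elif event_type == "fusion":
        if partner is None or partner.chrom != model.chrom:
            return None
        a_exons, b_exons = exons, _blocks(partner)
        if a_exons[-1][1] >= b_exons[0][0] or n < 2 or len(b_exons) < 2:
            return None
        ja = n // 2  # keep exons[0..ja-1] of A
        jb = len(b_exons) // 2  # keep exons[jb..] of B
        ev.junction = (a_exons[ja - 1][1] + 1, b_exons[jb][0] - 1)
        ev.aberrant_blocks = a_exons[:ja] + b_exons[jb:]
        ev.partner_gene = partner.gene_id
    else:
        raise ValueError(f"unknown event type {event_type!r}")
    return ev


def plant_events(
    models: Sequence[TranscriptModel],
    seed: int,
    event_probs: Mapping[str, float] | None = None,
    psi_range: tuple[float, float] = (0.2, 0.8),
    alt_offset_range: tuple[int, int] = (4, 25),
) -> list[TruthEvent]:
    """Draw at most one splicing event per gene.

    Event types are drawn per gene from ``event_probs`` (the defaults:
    12.5% for each of the five aberration classes, 37.5% no event); the
    true PSI is uniform over ``psi_range``.  Alternative-site offsets are
    drawn from ``alt_offset_range`` and never land on the original
    boundary.  A gene that cannot host the drawn event is redrawn (logged);
    after 10 failed draws it gets no event.
    """
    probs = dict(event_probs or DEFAULT_EVENT_PROBS)
    total = sum(probs.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"event probabilities sum to {total}, not 1")
    types = sorted(probs)
    p = np.array([probs[t] for t in types])
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for seq in by_chrom.values():
        seq.sort(key=lambda m: m.start)

    events: list[TruthEvent] = []
    for model in models:
        event: TruthEvent | None = None
        for attempt in range(10):
            event_type = types[int(rng.choice(len(types), p=p))]
            if event_type == "none":
                event = TruthEvent(model.gene_id, "none", model.chrom, 0.0)
                event = None
                break
            partner = None
            if event_type == "fusion":
                peers = by_chrom[model.chrom]
                idx = peers.index(model)
                partner = peers[idx + 1] if idx + 1 < len(peers) else None
            event = _make_event(
                model, event_type, rng,
                psi_range=psi_range, alt_offset_range=alt_offset_range,
                partner=partner,
            )
            if event is not None:
                break
            log.info(
                "gene %s cannot host %s (attempt %d), resampling",
                model.gene_id, event_type, attempt + 1,
            )
        if event is not None:
            events.append(event)
    return events


def plant_fusion(
    gene_a: TranscriptModel,
    gene_b: TranscriptModel,
    true_psi: float = 0.5,
    seed: int = 0,
) -> TruthEvent:
    """Plant one same-chromosome fusion joining two genes (A 5' half to B 3')."""
    rng = np.random.default_rng(seed)
    ev = _make_event(
        gene_a, "fusion", rng, psi_range=(true_psi, true_psi),
        alt_offset_range=(4, 25), partner=gene_b,
    )
    if ev is None:
        raise ValueError(
            f"cannot fuse {gene_a.gene_id} with {gene_b.gene_id}: "
            "need two multi-exon genes in order on one chromosome"
        )
    return ev


# ---------------------------------------------------------------------------
# read simulation


def _tx_len(blocks: Sequence[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in blocks)


def _tx_interval_to_cigar(
    blocks: Sequence[tuple[int, int]], a: int, b: int
) -> tuple[int, list[tuple[int, int]]]:
    """Map transcript interval [a, b) (0-based) to (1-based pos, CIGAR).

    The CIGAR alternates M over exonic blocks and N over the introns
    between blocks the interval spans.
    """
    cigar: list[tuple[int, int]] = []
    pos1 = None
    offset = 0
    prev_end = None
    for s, e in blocks:
        blen = e - s + 1
        lo, hi = max(a, offset), min(b, offset + blen)
        if lo < hi:
            gstart = s + (lo - offset)
            if pos1 is None:
                pos1 = gstart
            elif prev_end is not None and gstart > prev_end + 1:
                cigar.append((3, gstart - prev_end - 1))  # N
            cigar.append((0, hi - lo))  # M
            prev_end = s + (hi - offset) - 1
        offset += blen
        if offset >= b:
            break
    assert pos1 is not None
    return pos1, cigar


def _genomic_to_tx(blocks: Sequence[tuple[int, int]], gpos: int) -> int | None:
    offset = 0
    for s, e in blocks:
        if s <= gpos <= e:
            return offset + (gpos - s)
        offset += e - s + 1
    return None


def _junction_tx_point(
    blocks: Sequence[tuple[int, int]], junction: tuple[int, int]
) -> int | None:
    """Transcript offset of the exon/exon boundary implied by a junction."""
    offset = 0
    for (s, e), nxt in zip(blocks, blocks[1:]):
        offset += e - s + 1
        if e == junction[0] - 1 and nxt[0] == junction[1] + 1:
            return offset
    return None


def simulate_alignments(
    reference: Reference,
    truth: Sequence[TruthEvent],
    out_sam: str,
    depth: float = 60.0,
    read_len: int = 100,
    frag_len: int = 250,
    frag_sd: float = 40.0,
    seed: int = 0,
    error_rate: float = 0.0,
    expression_sigma: float = 0.0,
    support_min_anchor: int = 5,
) -> str:
    """Simulate paired-end alignments expressing each gene at ``depth``.

    Per gene, fragments are drawn from the canonical isoform or (with
    probability = the event's true PSI) the aberrant one; spliced reads
    carry N over introns, retention reads M straight through.  Fragment
    lengths are normal(frag_len, frag_sd) clipped to [read_len, isoform
    length] — fragments longer than the isoform are shortened to it.  With
    ``expression_sigma`` > 0 a log-normal factor scales each gene's depth.
    Records are coordinate-sorted under a sorted reference dictionary and
    written as SAM text.  ``truth[i].support`` is updated in place with
    the number of reads evidencing each event (anchored split reads, or
    unspliced probe-base coverage for retention).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    truth_by_gene = {t.gene_id: t for t in truth if t.event_type != "none"}
    for t in truth_by_gene.values():
        t.support = 0

    reads: list[tuple] = []  # (chrom, pos1, qname, flag, cigar, seq)
    for model in reference.models:
        canonical = _blocks(model)
        event = truth_by_gene.get(model.gene_id)
        tx_len = _tx_len(canonical)
        factor = float(rng.lognormal(0.0, expression_sigma)) if expression_sigma else 1.0
        n_frags = max(1, round(depth * factor * tx_len / (2 * read_len)))
        aberrant = event.aberrant_blocks if event is not None else None
        # precompute truth landmarks in aberrant-transcript coordinates
        jx_point = probe_points = None
        if event is not None:
            if event.junction is not None:
                jx_point = _junction_tx_point(aberrant, event.junction)
            if event.retained_intron is not None:
                s, e = event.retained_intron
                probe_points = [
                    _genomic_to_tx(aberrant, s + 2),
                    _genomic_to_tx(aberrant, e - 2),
                ]
        for i in range(n_frags):
            use_aberrant = event is not None and rng.random() < event.true_psi
            blocks = aberrant if use_aberrant else canonical
            iso_len = _tx_len(blocks)
            flen = int(round(rng.normal(frag_len, frag_sd)))
            flen = max(read_len, min(flen, iso_len))
            start = int(rng.integers(0, iso_len - flen + 1))
            r1 = (start, start + min(read_len, flen))
            r2 = (start + flen - min(read_len, flen), start + flen)
            qname = f"{model.transcript_id}.f{i}"
            mates = []
            for (a, b), flag in ((r1, 99), (r2, 147)):
                pos1, cigar = _tx_interval_to_cigar(blocks, a, b)
                seq = _read_sequence(
                    reference.genome[model.chrom], pos1, cigar, rng, error_rate
                )
                mates.append([model.chrom, pos1, qname, flag, cigar, seq, 0])
                if use_aberrant:
                    _tally_support(
                        event, a, b, jx_point, probe_points, support_min_anchor
                    )
            mates[0][6] = mates[1][1]  # mate position
            mates[1][6] = mates[0][1]
            reads.extend(tuple(m) for m in mates)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": chrom, "LN": len(reference.genome[chrom])}
                for chrom in sorted(reference.genome)
            ],
        }
    )
    reads.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        for chrom, pos1, qname, flag, cigar, seq, pnext1 in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = qname
            seg.flag = flag
            seg.reference_name = chrom
            seg.reference_start = pos1 - 1
            seg.mapping_quality = 60
            seg.cigartuples = cigar
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            seg.next_reference_name = chrom
            seg.next_reference_start = pnext1 - 1
            out.write(seg)
    return out_sam


def _read_sequence(
    chrom_seq: str,
    pos1: int,
    cigar: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    error_rate: float,
) -> str:
    parts = []
    ref = pos1 - 1  # 0-based
    for op, length in cigar:
        if op == 0:
            parts.append(chrom_seq[ref : ref + length])
            ref += length
        elif op == 3:
            ref += length
    seq = "".join(parts)
    if error_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hits = rng.random(len(arr)) < error_rate
        arr[hits] = _BASES[rng.integers(0, 4, size=int(hits.sum()))]
        seq = arr.tobytes().decode()
    return seq


def _tally_support(
    event: TruthEvent,
    a: int,
    b: int,
    jx_point: int | None,
    probe_points: Sequence[int | None] | None,
    min_anchor: int,
) -> None:
    if jx_point is not None:
        if a <= jx_point - min_anchor and b >= jx_point + min_anchor:
            event.support += 1
    elif probe_points:
        if any(t is not None and a <= t < b for t in probe_points):
            event.support += 1


def simulate_junction_reads(
    chrom: str,
    chrom_len: int,
    alternatives: Sequence[tuple[tuple[int, int], float]],
    n_reads: int,
    seed: int,
    read_half: int = 50,
) -> list[pysam.AlignedSegment]:
    """Reads spanning competing junctions that share a splice site.

    Each read is drawn independently among ``alternatives`` (intron
    interval, weight) and spans its junction with ``read_half`` aligned
    bases on each side — a minimal fixture for PSI sampling behaviour.
    """
    rng = np.random.default_rng(seed)
    weights = np.array([w for _, w in alternatives], dtype=float)
    weights = weights / weights.sum()
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    )
    reads = []
    for i in range(n_reads):
        (s, e), _ = alternatives[int(rng.choice(len(alternatives), p=weights))]
        seg = pysam.AlignedSegment(header)
        seg.query_name = f"r{i}"
        seg.flag = 0
        seg.reference_name = chrom
        seg.reference_start = s - read_half - 1
        seg.mapping_quality = 60
        seg.cigartuples = [(0, read_half), (3, e - s + 1), (0, read_half)]
        seg.query_sequence = "A" * (2 * read_half)
        reads.append(seg)
    return reads


def write_chimeric_table(
    path: str,
    rows: Sequence[tuple[str, int, str, str, int, str]],
    reads_per_row: Sequence[int] | int = 1,
) -> str:
    """Write a STAR-style chimeric junction table (one line per read).

    Each row is (chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b); the
    row is repeated once per supporting read.
    """
    if isinstance(reads_per_row, int):
        reads_per_row = [reads_per_row] * len(rows)
    with open(path, "wt") as out:
        n = 0
        for row, count in zip(rows, reads_per_row):
            chrom_a, pos_a, strand_a, chrom_b, pos_b, strand_b = row
            for _ in range(count):
                fields = [
                    chrom_a, str(pos_a), strand_a,
                    chrom_b, str(pos_b), strand_b,
                    "0", "-1", "-1", f"chim{n}",
                    str(pos_a), "50M", str(pos_b), "50M",
                ]
                out.write("\t".join(fields) + "\n")
                n += 1
    return path


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one truth event against the call set."""

    gene_id: str
    event_type: str
    status: str  # exact | near | miss
    coordinate_delta: int
    support: int = 0


@dataclass
class ScoreResult:
    matches: list[MatchResult]
    spurious: list[EventRecord]
    n_calls: int
    n_matched: int = 0

    def recall(
        self,
        event_type: str | None = None,
        include_near: bool = True,
        min_support: int = 0,
    ) -> float:
        pool = [
            m
            for m in self.matches
            if event_type in (None, m.event_type) and m.support >= min_support
        ]
        if not pool:
            return float("nan")
        ok = {"exact", "near"} if include_near else {"exact"}
        return sum(m.status in ok for m in pool) / len(pool)

    def precision(self) -> float:
        """Matched calls over matched + spurious (attributed calls excluded)."""
        denom = self.n_matched + len(self.spurious)
        return self.n_matched / denom if denom else float("nan")


_REPORTABLE = frozenset(
    {
        JunctionClass.PLAUSIBLE,
        JunctionClass.ANCHORED,
        JunctionClass.UNKNOWN,
        JunctionClass.NOSPLICE,
    }
)


def _junction_delta(rec: EventRecord, junction: tuple[int, int]) -> int:
    return max(abs(rec.start - junction[0]), abs(rec.end - junction[1]))


def score_calls(
    records: Sequence[EventRecord],
    truth: Sequence[TruthEvent],
    tolerance: int = 10,
    reportable: frozenset[JunctionClass] = _REPORTABLE,
) -> ScoreResult:
    """Match caller output against planted truth.

    A junction-type truth matches a junction call exactly when both intron
    ends agree, nearly when both ends are within ``tolerance`` bp (and not
    exact).  Retention truth matches a no-splice call at either flanking
    site.  Calls of a reportable class matching no truth are spurious —
    except no-splice calls at the displaced boundary of an alternative-site
    event, which that event's exon elongation necessarily produces; these
    are attributed to the event but counted neither as recall nor as
    spurious.  Symmetric in input order: candidates are ranked by
    (delta, coordinates), not encounter order.  Support cutoffs are
    applied when *reading* the result (``ScoreResult.recall``), never when
    matching, so low-support truth still claims its calls.
    """
    truth = [t for t in truth if t.event_type != "none"]
    calls = [r for r in records if r.klass in reportable]
    junction_calls = [r for r in calls if r.kind == "junction"]
    nosplice_calls = [r for r in calls if r.kind == "nosplice"]

    matched_ids: set[int] = set()
    matches: list[MatchResult] = []
    for t in sorted(truth, key=lambda t: (t.chrom, t.junction or t.retained_intron)):
        best: tuple[int, int, EventRecord] | None = None  # (delta, start, rec)
        if t.junction is not None:
            for rec in junction_calls:
                if rec.chrom != t.chrom or id(rec) in matched_ids:
                    continue
                delta = _junction_delta(rec, t.junction)
                if delta <= tolerance and (best is None or (delta, rec.start) < best[:2]):
                    best = (delta, rec.start, rec)
        elif t.retained_intron is not None:
            s, e = t.retained_intron
            for rec in nosplice_calls:
                if rec.chrom != t.chrom or id(rec) in matched_ids:
                    continue
                delta = min(abs(rec.start - s), abs(rec.start - e))
                if delta <= tolerance and (best is None or (delta, rec.start) < best[:2]):
                    best = (delta, rec.start, rec)
        if best is None:
            matches.append(
                MatchResult(t.gene_id, t.event_type, "miss", -1, t.support)
            )
        else:
            delta, _, rec = best
            matched_ids.add(id(rec))
            matches.append(
                MatchResult(
                    t.gene_id,
                    t.event_type,
                    "exact" if delta == 0 else "near",
                    delta,
                    t.support,
                )
            )

    # signal necessarily produced alongside an event, attributed to it:
    # exon elongation of alt events at the displaced annotated boundary,
    # and the second flanking site of a matched retained intron
    explained_sites = {
        (t.chrom, pos)
        for t in truth
        if t.event_type in ("alt5", "alt3") and t.base_intron is not None
        for pos in t.base_intron
    }
    explained_sites |= {
        (t.chrom, pos)
        for t in truth
        if t.retained_intron is not None
        for pos in t.retained_intron
    }
    spurious = []
    for rec in calls:
        if id(rec) in matched_ids:
            continue
        if rec.kind == "nosplice" and (rec.chrom, rec.start) in explained_sites:
            continue
        spurious.append(rec)
    return ScoreResult(
        matches=matches,
        spurious=spurious,
        n_calls=len(calls),
        n_matched=len(matched_ids),
    )
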