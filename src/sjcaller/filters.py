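"""Tiered stringency filters, output tables, per-gene junction summaries.

Four tiers are provided — none, sensitive, intermediate, stringent — with
thresholds non-decreasing across the ladder, so survivor sets are nested.
`none` reports every record; the filtering tiers report novel events only
(Plausible, Anchored, Unknown, NoSplice), leaving Annotated and Trivial
rows to the unfiltered table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .events import EventRecord, JunctionClass

__all__ = [
    "FilterTier",
    "TIERS",
    "get_tier",
    "apply_filter",
    "write_tables",
    "records_to_frame",
    "frame_to_records",
    "gene_report",
]

_ALL_CLASSES = frozenset(JunctionClass)
_NOVEL_CLASSES = frozenset(
    {
        JunctionClass.PLAUSIBLE,
        JunctionClass.ANCHORED,
        JunctionClass.UNKNOWN,
        JunctionClass.NOSPLICE,
    }
)


@dataclass(frozen=True)
class FilterTier:
    name: str
    min_reads: int
    min_psi: float
    classes_reported: frozenset[JunctionClass]


# Default thresholds; all overridable through get_tier(overrides=...).
TIERS: dict[str, FilterTier] = {
    "none": FilterTier("none", 0, 0.0, _ALL_CLASSES),
    "sensitive": FilterTier("sensitive", 5, 0.01, _NOVEL_CLASSES),
    "intermediate": FilterTier("intermediate", 10, 0.05, _NOVEL_CLASSES),
    "stringent": FilterTier("stringent", 20, 0.10, _NOVEL_CLASSES),
}


def get_tier(name: str, overrides: Mapping[str, Mapping] | None = None) -> FilterTier:
    """Look up a tier by name, applying per-tier config overrides.

    ``overrides`` maps tier name to a dict with any of ``min_reads``,
    ``min_psi``, ``classes_reported`` (class value strings).
    """
    if name not in TIERS:
        raise ValueError(
            f"unknown filter tier {name!r}; valid tiers: {', '.join(TIERS)}"
        )
    tier = TIERS[name]
    if overrides and name in overrides:
        spec = dict(overrides[name])
        if "classes_reported" in spec:
            spec["classes_reported"] = frozenset(
                JunctionClass(v) for v in spec["classes_reported"]
            )
        tier = replace(tier, **spec)
    return tier


def apply_filter(
    records: Sequence[EventRecord], tier: FilterTier | str
) -> list[EventRecord]:
    """Keep records of a reported class meeting the read and PSI floors.

    A record passes when its class is reported by the tier, its evidence
    count reaches ``min_reads`` and the larger of its two PSI values
    reaches ``min_psi`` (records with both PSI undefined pass only when
    ``min_psi`` is 0).  Output order is (chrom, start, end).
    """
    if isinstance(tier, str):
        tier = get_tier(tier)
    kept = []
    for rec in records:
        if rec.klass not in tier.classes_reported:
            continue
        if rec.split_reads < tier.min_reads:
            continue
        psi = rec.max_psi
        if psi is None:
            if tier.min_psi > 0:
                continue
        elif psi < tier.min_psi:
            continue
        kept.append(rec)
    kept.sort(key=lambda r: (r.chrom, r.start, r.end, r.kind))
    return kept


_COLUMNS = [
    "sample",
    "chrom",
    "start",
    "end",
    "strand",
    "class",
    "split_reads",
    "nosplice_depth_left",
    "nosplice_depth_right",
    "psi_left",
    "psi_right",
    "genes_left",
    "genes_right",
    "shift_applied",
]


def _fmt_psi(p: float | None) -> str:
    return "." if p is None else f"{p:.6g}"


def _fmt_genes(genes: frozenset[str]) -> str:
    return ",".join(sorted(genes)) if genes else "."


def records_to_frame(records: Iterable[EventRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample": r.sample_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "class": r.klass.value,
            "split_reads": r.split_reads,
            "nosplice_depth_left": r.nosplice_depth_left,
            "nosplice_depth_right": r.nosplice_depth_right,
            "psi_left": _fmt_psi(r.psi_left),
            "psi_right": _fmt_psi(r.psi_right),
            "genes_left": _fmt_genes(r.genes_left),
            "genes_right": _fmt_genes(r.genes_right),
            "shift_applied": r.shift_applied,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[EventRecord]:
    """Rebuild :class:`EventRecord` objects from a written table (round-trip)."""
    out = []
    for row in frame.itertuples(index=False):
        klass = JunctionClass(row[5])
        is_junction = klass not in (JunctionClass.NOSPLICE, JunctionClass.TRIVIAL)

        def parse_psi(v) -> float | None:
            return None if str(v) == "." else float(v)

        def parse_genes(v) -> frozenset[str]:
            return frozenset() if str(v) == "." else frozenset(str(v).split(","))

        psi_left, psi_right = parse_psi(row[9]), parse_psi(row[10])
        out.append(
            EventRecord(
                kind="junction" if is_junction else "nosplice",
                chrom=str(row[1]),
                start=int(row[2]),
                end=int(row[3]),
                strand=str(row[4]),
                klass=klass,
                split_reads=int(row[6]),
                psi_left=psi_left,
                psi_right=psi_right,
                genes_left=parse_genes(row[11]),
                genes_right=parse_genes(row[12]),
                nosplice_depth_left=int(row[7]),
                nosplice_depth_right=int(row[8]),
                shift_applied=int(row[13]),
                sample_id=str(row[0]),
                site_side=None
                if is_junction
                else ("left" if int(row[7]) > 0 or psi_left is not None else "right"),
            )
        )
    return out


def write_tables(
    records: Sequence[EventRecord],
    unfiltered_records: Sequence[EventRecord],
    out_prefix: str,
) -> tuple[str, str]:
    """Write the filtered and unfiltered junction tables as TSV.

    Undefined PSI is written as '.'; empty gene sets likewise.  Returns
    the two paths (``<prefix>.filtered.tsv``, ``<prefix>.unfiltered.tsv``).
    """
    filtered_path = f"{out_prefix}.filtered.tsv"
    unfiltered_path = f"{out_prefix}.unfiltered.tsv"
    records_to_frame(records).to_csv(filtered_path, sep="\t", index=False)
    records_to_frame(unfiltered_records).to_csv(unfiltered_path, sep="\t", index=False)
    return filtered_path, unfiltered_path


def gene_report(
    records: Sequence[EventRecord],
    models: Sequence,
    gene_id: str,
    sample_id: str,
    path: str | None = None,
):
    """Per-gene summary: exon structure with junction arcs scaled by support.

    Only produced when the gene has at least one filtered record in the
    sample; returns None otherwise.  Arcs are labelled with the larger of
    the two PSI values; no-splice records are drawn as markers on their
    site.  Returns the matplotlib Figure (saved to ``path`` if given).
    """
    gene_models = [m for m in models if m.gene_id == gene_id]
    if not gene_models:
        return None
    hits = [
        r
        for r in records
        if r.sample_id == sample_id and gene_id in (r.genes_left | r.genes_right)
    ]
    if not hits:
        return None

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Arc

    fig, ax = plt.subplots(figsize=(8, 2 + 0.5 * len(gene_models)))
    max_reads = max((r.split_reads for r in hits), default=1) or 1
    for i, model in enumerate(gene_models):
        y = -i
        for exon in model.exons:
            ax.add_patch(
                plt.Rectangle((exon.start, y - 0.15), exon.end - exon.start + 1, 0.3,
                              color="steelblue")
            )
        ax.plot([model.start, model.end], [y, y], color="steelblue", lw=0.8, zorder=0)
    for r in hits:
        if r.kind == "junction":
            width = r.end - r.start + 1
            mid = (r.start + r.end) / 2
            height = 0.6 + 1.2 * (r.split_reads / max_reads)
            ax.add_patch(
                Arc((mid, 0.2), width, height, theta1=0, theta2=180,
                    lw=0.5 + 2.5 * (r.split_reads / max_reads), color="firebrick")
            )
            label = _fmt_psi(r.max_psi)
            ax.annotate(f"{r.split_reads} ({label})", (mid, 0.2 + height / 2),
                        ha="center", fontsize=7)
        else:
            ax.plot([r.start], [0.25], marker="v", color="darkorange")
            ax.annotate(f"IR {r.split_reads}", (r.start, 0.35), ha="center", fontsize=7)
    span_lo = min(m.start for m in gene_models)
    span_hi = max(m.end for m in gene_models)
    pad = max((span_hi - span_lo) // 20, 10)
    ax.set_xlim(span_lo - pad, span_hi + pad)
    ax.set_ylim(-len(gene_models) - 0.5, 2.2)
    ax.set_yticks([])
    ax.set_xlabel(f"{gene_models[0].chrom} position")
    ax.set_title(f"{gene_id} — {sample_id}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
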