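"""Per-locus views: which variants sit in which cell-type-active elements.

A locus view has one row per variant in a genomic span, and per-column
lists of the cell types in which the variant is promoter-active,
enhancer-active, in open chromatin, an eQTL, or PolII-bound.  Rows are
derived entirely from per-cell regulatory calls — the view adds no logic
of its own.  Positional grouping is single-linkage: consecutive variants
closer than ``gap_bp`` share a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .classify import classify_regulatory, overlaps
from .io import EqtlTable, PeakTrack, Variant


@dataclass(frozen=True)
class LocusRow:
    variant_id: str
    pos: int
    promoter_cells: tuple[str, ...]
    enhancer_cells: tuple[str, ...]
    open_chromatin_cells: tuple[str, ...]
    eqtl_cells: tuple[str, ...]
    polii_cells: tuple[str, ...]


@dataclass
class LocusView:
    """A labelled span plus one row per variant (Table-2-style layout)."""

    label: str
    chrom: str
    start: int
    end: int
    rows: list[LocusRow]

    def to_frame(self) -> pd.DataFrame:
        def fmt(cells: tuple[str, ...]) -> str:
            return ", ".join(cells) if cells else "No"

        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.rows],
                "pos": [r.pos for r in self.rows],
                "promoter": [fmt(r.promoter_cells) for r in self.rows],
                "enhancer": [fmt(r.enhancer_cells) for r in self.rows],
                "open_chromatin": [fmt(r.open_chromatin_cells) for r in self.rows],
                "eqtl": [fmt(r.eqtl_cells) for r in self.rows],
                "polii": [fmt(r.polii_cells) for r in self.rows],
            }
        )


def build_locus_view(
    span: tuple[str, int, int],
    variants: Sequence[Variant],
    tracks: Sequence[PeakTrack],
    eqtl: EqtlTable | None = None,
    label: str | None = None,
    require_marks: bool = False,
) -> LocusView:
    """Build the per-cell activity table for all variants in a span.

    ``span`` is (chrom, start, end), 1-based inclusive.  Cells are taken
    from the track manifest; a cell appears in a column iff the
    corresponding per-cell flag is true there.  The PolII column reports
    raw PolII occupancy per cell (it equals the promoter flag but is kept
    as its own column to mirror the report layout).
    """
    chrom, start, end = span
    if end < start:
        raise ValueError(f"empty span {chrom}:{start}-{end}")
    in_span = sorted(
        (v for v in variants if v.chrom == chrom and start <= v.pos <= end),
        key=lambda v: v.pos,
    )
    if not in_span:
        raise ValueError(f"no variants in span {chrom}:{start}-{end}")
    cells = sorted({t.cell for t in tracks if t.kind == "chip"})
    rows = []
    for v in in_span:
        per_cell = {
            cell: classify_regulatory(
                v, tracks, scope=cell, eqtl=eqtl, require_marks=require_marks
            )
            for cell in cells
        }
        polii_cells = tuple(
            c for c in cells
            if any(
                t.cell == c and t.mark == "PolII" and t.kind == "chip" and overlaps(v, t)
                for t in tracks
            )
        )
        rows.append(
            LocusRow(
                variant_id=v.id,
                pos=v.pos,
                promoter_cells=tuple(c for c in cells if per_cell[c].promoter),
                enhancer_cells=tuple(c for c in cells if per_cell[c].enhancer),
                open_chromatin_cells=tuple(c for c in cells if per_cell[c].dnase),
                eqtl_cells=tuple(c for c in cells if per_cell[c].eqtl),
                polii_cells=polii_cells,
            )
        )
    return LocusView(
        label=label or f"{chrom}:{start}-{end}", chrom=chrom, start=start, end=end, rows=rows
    )


def group_variants_by_position(
    variants: Sequence[Variant], gap_bp: int = 20_000
) -> list[list[Variant]]:
    """Single-linkage positional clusters: gaps <= ``gap_bp`` join a cluster.

    The result is invariant to input order (variants are sorted first).
    The 20 kb default separates groups tens of kilobases apart while
    keeping promoter-proximal variant runs together.
    """
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos))
    clusters: list[list[Variant]] = []
    for v in ordered:
        if (
            clusters
            and clusters[-1][-1].chrom == v.chrom
            and v.pos - clusters[-1][-1].pos <= gap_bp
        ):
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return clusters
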