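"""Rule-based promoter/enhancer/insulator calling from peak-track overlaps.

The operational definitions, applied per scope (one cell type or the
multi-cell union of all tracks per mark):

* promoter  — RNA polymerase II (PolII) occupancy at the variant;
* enhancer  — H3K27Ac, H3K36me3 and/or H3K27me3 occupancy *in the absence
  of* PolII occupancy (the repressive mark H3K27me3 is kept in the default
  list deliberately; ``enhancer_marks`` makes the rule configurable);
* insulator — CTCF occupancy;
* dnase     — DNase I hypersensitive site at the variant;
* eqtl      — membership in the supplied eQTL table for the scope.

``primary_motif`` is a display convenience ranking promoter > enhancer >
insulator > none; a variant may carry several flags at once.  TF tracks
(``kind="tf"``) contribute only pass-through ``tf_hits`` labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import EqtlTable, PeakTrack, Variant, format_pct, to_zero_based

MULTI_CELL = "multi-cell"

DEFAULT_ENHANCER_MARKS = ("H3K27Ac", "H3K36me3", "H3K27me3")

#: Flag columns of a regulatory call, in report order.
FLAGS = ("promoter", "enhancer", "insulator", "dnase", "eqtl")


@dataclass(frozen=True)
class RegulatoryCall:
    variant_id: str
    scope: str
    promoter: bool
    enhancer: bool
    insulator: bool
    dnase: bool
    eqtl: bool
    primary_motif: str
    tf_hits: tuple[str, ...] = ()

    @property
    def any_flag(self) -> bool:
        return self.promoter or self.enhancer or self.insulator or self.dnase or self.eqtl

    @property
    def annotated(self) -> bool:
        """Any regulatory evidence at all, including TF binding."""
        return self.any_flag or bool(self.tf_hits)


def overlaps(variant: Variant, track: PeakTrack, strict_contig: bool = False) -> bool:
    """True iff the variant base falls inside a track interval.

    Intervals are 0-based half-open; the variant's base index is
    ``pos - 1``.  A contig absent from the track is False (or an error
    with ``strict_contig``) — an empty track on the right contig and a
    track of another contig are both genuine non-overlaps by default.
    """
    starts, ends = track.intervals(variant.chrom)
    if starts.size == 0:
        if strict_contig and variant.chrom not in track.chroms:
            raise ValueError(
                f"{variant.id}: contig {variant.chrom!r} not covered by track "
                f"({track.cell}, {track.mark})"
            )
        return False
    p0 = to_zero_based(variant.pos)
    i = int(np.searchsorted(starts, p0, side="right")) - 1
    return bool(i >= 0 and p0 < ends[i])


def _tracks_in_scope(tracks: Sequence[PeakTrack], scope: str) -> list[PeakTrack]:
    if scope == MULTI_CELL:
        return list(tracks)
    return [t for t in tracks if t.cell == scope]


def classify_regulatory(
    variant: Variant,
    tracks: Sequence[PeakTrack],
    scope: str = MULTI_CELL,
    eqtl: EqtlTable | None = None,
    enhancer_marks: Sequence[str] = DEFAULT_ENHANCER_MARKS,
    require_marks: bool = True,
) -> RegulatoryCall:
    """Apply the regulatory rule set to one variant in one scope.

    With ``require_marks`` (default), the marks the rules need — PolII,
    CTCF, DNase and at least one enhancer mark — must each have a track in
    scope (an empty track counts as present; a missing manifest entry does
    not), and their absence raises an error naming the missing marks.
    """
    in_scope = _tracks_in_scope(tracks, scope)
    if require_marks:
        present = {t.mark for t in in_scope if t.kind == "chip"}
        missing = [m for m in ("PolII", "CTCF", "DNase") if m not in present]
        if not present.intersection(enhancer_marks):
            missing.append("/".join(enhancer_marks))
        if missing:
            raise ValueError(
                f"scope {scope!r}: no track for required mark(s) {', '.join(missing)}"
            )
    hit_marks = {
        t.mark for t in in_scope if t.kind == "chip" and overlaps(variant, t)
    }
    tf_hits = tuple(
        sorted({t.mark for t in in_scope if t.kind == "tf" and overlaps(variant, t)})
    )
    promoter = "PolII" in hit_marks
    enhancer = bool(hit_marks.intersection(enhancer_marks)) and not promoter
    insulator = "CTCF" in hit_marks
    dnase = "DNase" in hit_marks
    has_eqtl = False
    if eqtl is not None:
        has_eqtl = eqtl.has(variant.id, None if scope == MULTI_CELL else scope)
    if promoter:
        primary = "promoter"
    elif enhancer:
        primary = "enhancer"
    elif insulator:
        primary = "insulator"
    else:
        primary = "none"
    return RegulatoryCall(
        variant.id, scope, promoter, enhancer, insulator, dnase, has_eqtl, primary, tf_hits
    )


def classify_all(
    variants: Iterable[Variant],
    tracks: Sequence[PeakTrack],
    scope: str = MULTI_CELL,
    eqtl: EqtlTable | None = None,
    **kwargs,
) -> list[RegulatoryCall]:
    return [classify_regulatory(v, tracks, scope, eqtl, **kwargs) for v in variants]


def coverage_summary(calls: Sequence[RegulatoryCall]) -> pd.DataFrame:
    """Per-flag counts/percentages plus the overall regulatory coverage.

    ``no_flag`` counts variants with all five flags false.  ``coverage``
    is the percentage of variants with *any* regulatory evidence — a flag
    or a TF-binding hit — so a variant whose only evidence is TF binding
    counts toward coverage while still lacking a motif flag.
    """
    if not calls:
        raise ValueError("no regulatory calls to summarize")
    n = len(calls)
    rows = []
    for flag in FLAGS:
        k = sum(1 for c in calls if getattr(c, flag))
        rows.append((flag, k, format_pct(k, n)))
    n_no_flag = sum(1 for c in calls if not c.any_flag)
    rows.append(("no_flag", n_no_flag, format_pct(n_no_flag, n)))
    n_annot = sum(1 for c in calls if c.annotated)
    rows.append(("coverage", n_annot, format_pct(n_annot, n)))
    return pd.DataFrame(rows, columns=["flag", "count", "pct"]).set_index("flag")


def calls_to_frame(calls: Sequence[RegulatoryCall]) -> pd.DataFrame:
    """Tabular view of regulatory calls (one row per variant)."""
    return pd.DataFrame(
        {
            "variant_id": [c.variant_id for c in calls],
            "scope": [c.scope for c in calls],
            **{flag: [getattr(c, flag) for c in calls] for flag in FLAGS},
            "primary_motif": [c.primary_motif for c in calls],
            "tf_hits": [",".join(c.tf_hits) for c in calls],
        }
    )
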