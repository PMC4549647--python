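"""Genic-location classification of variants against transcript models.

Each variant receives exactly one primary class from::

    exonic_missense, exonic_other, utr5, utr3, splice_donor, intronic,
    upstream, downstream, intergenic

Within a gene the precedence is CDS > UTR > splice donor > intron.  A
variant inside any transcript is genic (distance 0) and beats flanking
calls; among several candidate genes the smallest distance wins, ties
broken by lexicographic gene id.  Flanking calls are strand-aware within
``flank_bp`` of the transcript boundaries; beyond that the variant is
intergenic.  The 10 kb default flank mirrors the usual "intergenic means
more than 10 kb from any gene" convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io import GeneModel, Variant, format_pct

LOCATION_CLASSES = (
    "exonic_missense",
    "exonic_other",
    "utr5",
    "utr3",
    "splice_donor",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)

DEFAULT_FLANK_BP = 10_000


@dataclass(frozen=True)
class LocationCall:
    variant_id: str
    primary_class: str
    distance_to_gene: int
    gene_id: str | None

    def __post_init__(self) -> None:
        if self.primary_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown location class {self.primary_class!r}")


def _cds_offset(gene: GeneModel, pos: int) -> int:
    """0-based offset of a genomic position within the coding sequence."""
    off = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            off += pos - s
            if gene.strand == "-":
                return gene.cds_len - 1 - off
            return off
        off += e - s + 1
    raise ValueError(f"{gene.gene_id}: position {pos} is not in the CDS")


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def call_missense(variant: Variant, gene: GeneModel, cds_sequence: str | None = None) -> bool:
    """True iff substituting ``alt`` changes the encoded amino acid.

    ``cds_sequence`` defaults to the gene's attached coding sequence; its
    length must be a multiple of three.  Alleles are given on the plus
    genome strand and are reverse-complemented for minus-strand genes.
    Nonsense changes (stop gain or loss) are deliberately *not* missense.
    """
    seq = cds_sequence if cds_sequence is not None else gene.cds_seq
    if seq is None:
        raise ValueError(f"{gene.gene_id}: no coding sequence available")
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length {len(seq)} not divisible by 3")
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise ValueError(f"{variant.id}: only single-base substitutions supported")
    off = _cds_offset(gene, variant.pos)
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if gene.strand == "-":
        try:
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        except KeyError:
            raise ValueError(f"{variant.id}: ambiguous base in {variant.ref}/{variant.alt}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"{variant.id}: ambiguous base in {variant.ref}/{variant.alt}")
    if seq[off] != ref:
        raise ValueError(
            f"{variant.id}: ref allele {ref} does not match CDS base {seq[off]} "
            f"at coding offset {off} of {gene.gene_id}"
        )
    codon_i = off // 3
    codon = seq[3 * codon_i : 3 * codon_i + 3]
    mutated = codon[: off % 3] + alt + codon[off % 3 + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    return aa_ref != aa_alt and "*" not in (aa_ref, aa_alt)


def _splice_donor_positions(gene: GeneModel) -> set[int]:
    """First two intronic bases 3' of each exon, in transcription direction."""
    out: set[int] = set()
    for is_, ie in gene.introns:
        if gene.strand == "+":
            out.update((is_, min(is_ + 1, ie)))
        else:
            out.update((ie, max(ie - 1, is_)))
    return out


def _within(pos: int, ivals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in ivals)


def _genic_class(variant: Variant, gene: GeneModel) -> str:
    pos = variant.pos
    if _within(pos, gene.cds):
        if gene.cds_seq is not None and len(variant.ref) == 1 and len(variant.alt) == 1:
            try:
                return "exonic_missense" if call_missense(variant, gene) else "exonic_other"
            except ValueError:
                return "exonic_other"
        return "exonic_other"
    if _within(pos, gene.utr5):
        return "utr5"
    if _within(pos, gene.utr3):
        return "utr3"
    if _within(pos, gene.exons):
        return "exonic_other"  # non-coding exon outside annotated UTRs
    if pos in _splice_donor_positions(gene):
        return "splice_donor"
    return "intronic"


def classify_location(
    variant: Variant,
    genes: Sequence[GeneModel],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> LocationCall:
    """Assign the variant its genic-location class (see module docstring)."""
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    known_contigs = {g.chrom for g in genes}
    if variant.chrom not in known_contigs:
        raise ValueError(
            f"{variant.id}: contig {variant.chrom!r} carries no gene model "
            f"(known: {sorted(known_contigs)})"
        )
    pos = variant.pos
    # candidates: (distance, gene_id, class); genic candidates have distance 0
    candidates: list[tuple[int, str, str]] = []
    nearest: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != variant.chrom:
            continue
        if g.contains(pos):
            candidates.append((0, g.gene_id, _genic_class(variant, g)))
            continue
        if pos < g.tx_start:
            dist = g.tx_start - pos
            flank_class = "upstream" if g.strand == "+" else "downstream"
        else:
            dist = pos - g.tx_end
            flank_class = "downstream" if g.strand == "+" else "upstream"
        if dist <= flank_bp:
            candidates.append((dist, g.gene_id, flank_class))
        if nearest is None or dist < nearest[0]:
            nearest = (dist, g.gene_id)
    if candidates:
        dist, gene_id, cls = min(candidates)
        return LocationCall(variant.id, cls, dist, gene_id)
    assert nearest is not None
    return LocationCall(variant.id, "intergenic", nearest[0], nearest[1])


def classify_locations(
    variants: Iterable[Variant],
    genes: Sequence[GeneModel],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[LocationCall]:
    return [classify_location(v, genes, flank_bp) for v in variants]


def summarize_locations(calls: Sequence[LocationCall]) -> pd.DataFrame:
    """Counts and one-decimal percentages per location class.

    Returns a DataFrame indexed by class (all classes listed, zeros kept)
    with columns ``count`` and ``pct``; counts always sum to ``len(calls)``.
    """
    if not calls:
        raise ValueError("no location calls to summarize")
    n = len(calls)
    counts = {c: 0 for c in LOCATION_CLASSES}
    for call in calls:
        counts[call.primary_class] += 1
    df = pd.DataFrame(
        {
            "count": [counts[c] for c in LOCATION_CLASSES],
            "pct": [format_pct(counts[c], n) for c in LOCATION_CLASSES],
        },
        index=pd.Index(LOCATION_CLASSES, name="location"),
    )
    return df
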