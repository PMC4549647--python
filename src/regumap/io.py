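"""Record types and readers/writers for the formats the pipeline touches.

Coordinate conventions are enforced here and nowhere else:

* variants are 1-based (VCF/dbSNP convention),
* peak intervals are 0-based half-open (BED convention),
* gene features are 1-based inclusive (GFF3 convention).

The single point of conversion between the variant and peak worlds is
:func:`to_zero_based`; overlap logic elsewhere must go through it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Closed ChIP/accessibility mark vocabulary.  Keeping this closed catches
#: manifest typos early: the regulatory rules are mark-specific, so a
#: misspelled mark would silently drop a rule input.
MARKS: tuple[str, ...] = (
    "PolII",
    "H3K27Ac",
    "H3K36me3",
    "H3K27me3",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9Ac",
    "CTCF",
    "DNase",
)

_CANONICAL_MARK = {m.lower(): m for m in MARKS}


def canonical_mark(label: str) -> str:
    """Case-normalise a mark label to its canonical spelling.

    Raises ``ValueError`` for labels outside the closed vocabulary.
    """
    try:
        return _CANONICAL_MARK[label.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown mark {label!r}; known marks: {', '.join(MARKS)}"
        ) from None


def to_zero_based(pos: int) -> int:
    """Convert a 1-based variant position to its 0-based base index.

    A variant at 1-based position ``p`` overlaps a BED interval ``[s, e)``
    iff ``s <= p - 1 < e``.
    """
    return pos - 1


@dataclass(frozen=True)
class Variant:
    """One point mutation: identity, coordinates, alleles and provenance.

    ``source`` distinguishes seed (input) variants from LD proxies added by
    expansion.  ``flags`` carries pass-through consequence labels from the
    input (e.g. ``NMD_target``) that the pipeline reports but never computes.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    source: str = "seed"
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")
        if self.source not in ("seed", "ld_proxy"):
            raise ValueError(f"{self.id}: unknown source {self.source!r}")


def _check_intervals(name: str, ivals: Sequence[tuple[int, int]], lo: int, hi: int) -> None:
    prev_end = None
    for s, e in ivals:
        if s > e:
            raise ValueError(f"{name}: interval ({s}, {e}) has start > end")
        if s < lo or e > hi:
            raise ValueError(f"{name}: interval ({s}, {e}) outside [{lo}, {hi}]")
        if prev_end is not None and s <= prev_end:
            raise ValueError(f"{name}: intervals overlap or are unsorted at ({s}, {e})")
        prev_end = e


@dataclass
class GeneModel:
    """A transcript model: span, strand, exon/CDS/UTR intervals.

    All coordinates are 1-based inclusive.  ``cds_seq`` optionally holds the
    coding sequence (5'->3' in the reading frame) so that missense status of
    CDS variants can be decided; without it CDS variants are still located
    but not typed as missense.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (1 <= self.tx_start <= self.tx_end):
            raise ValueError(f"{self.gene_id}: bad transcript span")
        self.exons = sorted(tuple(x) for x in self.exons)
        self.cds = sorted(tuple(x) for x in self.cds)
        self.utr5 = sorted(tuple(x) for x in self.utr5)
        self.utr3 = sorted(tuple(x) for x in self.utr3)
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        _check_intervals(self.gene_id, self.exons, self.tx_start, self.tx_end)
        _check_intervals(self.gene_id, self.cds, self.tx_start, self.tx_end)
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"{self.gene_id}: CDS ({s}, {e}) not inside an exon")
        n = self.cds_len
        if self.cds_seq is not None and len(self.cds_seq) != n:
            raise ValueError(
                f"{self.gene_id}: cds_seq length {len(self.cds_seq)} != CDS span {n}"
            )

    @property
    def cds_len(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def contains(self, pos: int) -> bool:
        return self.tx_start <= pos <= self.tx_end


class PeakTrack:
    """The merged intervals of one (cell type, mark) assay.

    Intervals are stored per contig as parallel ``starts``/``ends`` arrays,
    0-based half-open, sorted and merged, so point queries are a binary
    search.  ``kind`` is ``"chip"`` for vocabulary marks and ``"tf"`` for
    transcription-factor tracks whose labels are free-form and which only
    feed pass-through ``tf_hits`` annotations.
    """

    def __init__(
        self,
        cell: str,
        mark: str,
        intervals: Iterable[tuple[str, int, int]] = (),
        kind: str = "chip",
    ) -> None:
        if kind not in ("chip", "tf"):
            raise ValueError(f"unknown track kind {kind!r}")
        self.cell = cell
        self.mark = canonical_mark(mark) if kind == "chip" else mark
        self.kind = kind
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if e <= s:
                raise ValueError(
                    f"track ({cell}, {self.mark}): interval [{s}, {e}) has end <= start"
                )
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            merged: list[list[int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            arr = np.asarray(merged, dtype=np.int64)
            self._by_chrom[chrom] = (arr[:, 0], arr[:, 1])

    @property
    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _ in self._by_chrom.values())

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one contig (empty arrays if absent)."""
        if chrom not in self._by_chrom:
            z = np.empty(0, dtype=np.int64)
            return z, z
        return self._by_chrom[chrom]

    def iter_intervals(self) -> Iterable[tuple[str, int, int]]:
        for chrom in sorted(self._by_chrom):
            starts, ends = self._by_chrom[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield chrom, s, e

    def coverage_bp(self, chrom: str | None = None) -> int:
        chroms = [chrom] if chrom is not None else sorted(self._by_chrom)
        total = 0
        for c in chroms:
            starts, ends = self.intervals(c)
            total += int((ends - starts).sum())
        return total

    def __repr__(self) -> str:  # pragma: no cover
        return f"PeakTrack({self.cell!r}, {self.mark!r}, n={self.n_intervals})"


class EqtlTable:
    """Rows of (variant id, target gene, cell label), unique triples."""

    COLUMNS = ("variant_id", "gene_id", "cell")

    def __init__(self, rows: Iterable[tuple[str, str, str]] = ()) -> None:
        df = pd.DataFrame(list(rows), columns=list(self.COLUMNS))
        if df.duplicated().any():
            dupes = df[df.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate eQTL row {tuple(dupes)}")
        self.df = df

    def cells_for(self, variant_id: str) -> set[str]:
        sub = self.df[self.df["variant_id"] == variant_id]
        return set(sub["cell"])

    def genes_for(self, variant_id: str) -> set[str]:
        sub = self.df[self.df["variant_id"] == variant_id]
        return set(sub["gene_id"])

    def has(self, variant_id: str, cell: str | None = None) -> bool:
        """True if the variant is an eQTL, optionally in a specific cell."""
        cells = self.cells_for(variant_id)
        if cell is None:
            return bool(cells)
        return cell in cells

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

VARIANT_TSV_COLUMNS = ("id", "chrom", "pos", "ref", "alt")


def read_variants(path: str | Path, fmt: str | None = None) -> list[Variant]:
    """Load variants from a TSV (``id chrom pos ref alt [flags]``) or a VCF.

    TSV parse errors name the offending line.  Duplicate ids are rejected.
    The returned list is sorted by (chrom, pos); unsorted input is accepted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" in path.suffix.lower() and "vcf" or "tsv"
    if fmt == "vcf":
        variants = _read_variants_vcf(path)
    elif fmt == "tsv":
        variants = _read_variants_tsv(path)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")
    seen: set[str] = set()
    for v in variants:
        if v.id in seen:
            raise ValueError(f"duplicate variant id {v.id!r} in {path}")
        seen.add(v.id)
    if not variants:
        warnings.warn(f"{path}: no variants loaded", stacklevel=2)
    return sorted(variants, key=lambda v: (v.chrom, v.pos, v.id))


def _read_variants_tsv(path: Path) -> list[Variant]:
    out: list[Variant] = []
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header[:5]) != VARIANT_TSV_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: expected header starting "
                        f"{' '.join(VARIANT_TSV_COLUMNS)}, got {' '.join(header)}"
                    )
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
            vid, chrom, pos_s, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: position {pos_s!r} is not an integer")
            flags = frozenset(
                f for f in (fields[5].split(",") if len(fields) > 5 and fields[5] else []) if f
            )
            try:
                out.append(Variant(vid, chrom, pos, ref, alt, flags=flags))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def _read_variants_vcf(path: Path) -> list[Variant]:
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        out.append(Variant(vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    return out


def read_gene_models(
    gff3_path: str | Path, cds_fasta: str | Path | None = None
) -> list[GeneModel]:
    """Load transcript models from a GFF3 subset.

    Recognised feature types: ``gene``, ``mRNA``, ``exon``, ``CDS``,
    ``five_prime_UTR``, ``three_prime_UTR``.  One transcript per gene is
    assumed (isoform resolution is out of scope).  ``cds_fasta`` optionally
    supplies coding sequences keyed by gene id.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    seqs: dict[str, str] = {}
    if cds_fasta is not None:
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta), "fasta")}

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(g.id):
            span = (child.start, child.end)
            if child.featuretype == "exon":
                exons.append(span)
            elif child.featuretype == "CDS":
                cds.append(span)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(span)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(span)
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                tx_start=g.start,
                tx_end=g.end,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                cds_seq=seqs.get(g.id),
            )
        )
    genes.sort(key=lambda gm: (gm.chrom, gm.tx_start))
    return genes


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED3 file (0-based half-open); ``end <= start`` is an error."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, s, e = fields[0], int(fields[1]), int(fields[2])
            if e <= s:
                raise ValueError(f"{path}:{lineno}: BED interval [{s}, {e}) has end <= start")
            out.append((chrom, s, e))
    return out


def read_tracks(
    manifest_path: str | Path, allow_custom_marks: bool = False
) -> list[PeakTrack]:
    """Load peak tracks declared in a YAML manifest.

    The manifest is a list of ``{file, cell, mark}`` entries (paths relative
    to the manifest).  An optional ``kind: tf`` marks a transcription-factor
    track, whose label bypasses the mark vocabulary.  ``allow_custom_marks``
    relaxes the vocabulary for chip tracks as well.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise ValueError(f"{manifest_path}: manifest must be a list of entries")
    tracks = []
    for entry in entries:
        missing = {"file", "cell", "mark"} - set(entry)
        if missing:
            raise ValueError(f"{manifest_path}: entry {entry} lacks {sorted(missing)}")
        bed_path = manifest_path.parent / entry["file"]
        if not bed_path.exists():
            raise FileNotFoundError(f"{manifest_path}: no such track file {bed_path}")
        kind = entry.get("kind", "chip")
        mark = entry["mark"]
        if kind == "chip" and allow_custom_marks and mark.lower() not in _CANONICAL_MARK:
            kind = "tf"  # treated as a pass-through label
        tracks.append(PeakTrack(entry["cell"], mark, read_bed(bed_path), kind=kind))
    return tracks


def read_eqtl(path: str | Path) -> EqtlTable:
    """Load an eQTL table TSV with header ``variant_id gene_id cell``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if tuple(df.columns[:3]) != EqtlTable.COLUMNS:
        raise ValueError(
            f"{path}: expected columns {' '.join(EqtlTable.COLUMNS)}, got {' '.join(df.columns)}"
        )
    return EqtlTable(df.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_variants(variants: Iterable[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_TSV_COLUMNS + ("flags",)) + "\n")
        for v in variants:
            flags = ",".join(sorted(v.flags))
            fh.write(f"{v.id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{flags}\n")


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write transcript models as a GFF3 subset (gene/mRNA/exon/CDS/UTR)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tregumap"
            attrs = f"ID={g.gene_id}"
            fh.write(f"{base}\tgene\t{g.tx_start}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{base}\tmRNA\t{g.tx_start}\t{g.tx_end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for ftype, ivals in (
                ("exon", g.exons),
                ("CDS", g.cds),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in ivals:
                    frame = "0" if ftype == "CDS" else "."
                    fh.write(
                        f"{base}\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t{frame}\tParent={mrna_id}\n"
                    )


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def write_tracks(
    tracks: Iterable[PeakTrack], outdir: str | Path, manifest_name: str = "manifest.yaml"
) -> Path:
    """Dump tracks as BED files plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in tracks:
        fname = f"{t.cell}_{t.mark}.bed".replace("/", "_")
        write_bed(t.iter_intervals(), outdir / fname)
        entry = {"file": fname, "cell": t.cell, "mark": t.mark}
        if t.kind != "chip":
            entry["kind"] = t.kind
        entries.append(entry)
    manifest = outdir / manifest_name
    with open(manifest, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
    return manifest


def format_pct(k: int, n: int) -> float:
    """Percentage rounded to one decimal, the report-rendering convention."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, 1)


def write_report(obj: Mapping | pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a result mapping or table as JSON or TSV (lossless round trip)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    if fmt == "json":
        if isinstance(obj, pd.DataFrame):
            obj.to_json(path, orient="table", indent=2)
        else:
            with open(path, "w") as fh:
                json.dump(dict(obj), fh, indent=2)
                fh.write("\n")
    elif fmt == "tsv":
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False)
        else:
            pd.DataFrame(
                {"key": list(obj.keys()), "value": list(obj.values())}
            ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path: str | Path, fmt: str | None = None):
    """Inverse of :func:`write_report` (mapping for JSON dicts, DataFrame else)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    if fmt == "json":
        with open(path) as fh:
            head = fh.read(64)
        if '"schema"' in head:  # DataFrame written with orient="table"
            return pd.read_json(path, orient="table")
        with open(path) as fh:
            return json.load(fh)
    return pd.read_csv(path, sep="\t")
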