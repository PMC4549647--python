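"""Synthetic inputs: haplotype panels with block LD, gene models, peak
tracks with planted enrichment, and the packaged 72-variant worked example.

Every generator is a pure function of its config — the random stream is
created from ``config.seed`` inside each call, so identical configs give
byte-identical outputs.

LD model
--------
Haplotypes are built by founder copying, not coalescent recombination: the
two founders of a block carry complementary alleles (0 vs 1) at every
site, each haplotype picks one founder per block, and every (haplotype,
site) allele then flips independently with probability ``f =
within_block_flip_prob``.  Each column is therefore a noisy copy of the
same Bernoulli(1/2) founder indicator, so for two sites in one block

    corr(X_s, X_t) = (1 - 2 f)**2    and    E[r2] ~ (1 - 2 f)**4,

which makes the expected within-block r2 directly tunable (f = 0 gives
r2 = 1 exactly).  Sites in different blocks use independent founder
indicators and are uncorrelated.  This deliberately ignores recombination
maps, demography and realistic frequency spectra: it controls the one
quantity the expansion step consumes, pairwise r2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .io import (
    EqtlTable,
    GeneModel,
    PeakTrack,
    Variant,
    read_eqtl,
    read_gene_models,
    read_tracks,
    read_variants,
)
from .ld import HaplotypePanel

log = logging.getLogger(__name__)

#: The three cell types of the worked example: a lymphoblastoid B-cell
#: line, CD14+ monocytes and an epithelial (lung adenocarcinoma) line.
DEFAULT_CELLS = ("GM12878", "CD14", "A549")

#: All vocabulary marks; peak-track simulation emits one track per
#: (cell, mark) pair.
DEFAULT_MARKS = (
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


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic generators (see field comments for units)."""

    seed: int = 0
    n_haplotypes: int = 200            # phased haplotypes (2 x samples)
    n_sites: int = 200                 # polymorphic sites requested
    block_length_bp: int = 20_000      # LD block size
    within_block_flip_prob: float = 0.05   # founder-copy error; controls r2 decay
    genome_length_bp: int = 1_000_000  # synthetic contig ("chrS") length
    n_genes: int = 10
    background_peak_fraction: float = 0.02  # genome fraction covered per track
    planted_fold: float = 1.0          # target enrichment at designated variants
    peak_width_bp: int = 200
    cells: tuple[str, ...] = DEFAULT_CELLS
    marks: tuple[str, ...] = DEFAULT_MARKS
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if min(self.n_haplotypes, self.n_sites, self.block_length_bp,
               self.genome_length_bp, self.n_genes, self.peak_width_bp) < 1:
            raise ValueError("all counts and lengths must be >= 1")
        if not (0 <= self.within_block_flip_prob <= 1):
            raise ValueError("within_block_flip_prob must be in [0, 1]")
        if not (0 <= self.background_peak_fraction <= 1):
            raise ValueError("background_peak_fraction must be in [0, 1]")
        if self.planted_fold < 1:
            raise ValueError("planted_fold must be >= 1")
        if not self.cells or not self.marks:
            raise ValueError("need at least one cell and one mark")


def gen_haplotype_panel(config: SimulationConfig) -> HaplotypePanel:
    """Simulate a phased panel with block LD (see module docstring).

    Monomorphic columns (possible when all haplotypes happen to agree) are
    dropped rather than resampled, so the returned panel may have slightly
    fewer than ``n_sites`` sites; every remaining column is polymorphic.
    """
    if config.n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes for meaningful r2")
    rng = np.random.default_rng(config.seed)
    positions = np.sort(
        rng.choice(config.genome_length_bp, size=config.n_sites, replace=False)
    ) + 1
    blocks = (positions - 1) // config.block_length_bp
    n = config.n_haplotypes
    matrix = np.empty((n, config.n_sites), dtype=np.int8)
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        founder = rng.integers(0, 2, size=n, dtype=np.int8)  # founder choice per haplotype
        flips = rng.random((n, cols.size)) < config.within_block_flip_prob
        matrix[:, cols] = founder[:, None] ^ flips
    freqs = matrix.mean(axis=0)
    keep = (freqs > 0) & (freqs < 1)
    if not keep.all():
        log.info("dropping %d monomorphic site(s)", int((~keep).sum()))
    positions = positions[keep]
    matrix = matrix[:, keep]
    site_ids = [f"sim{p:08d}" for p in positions.tolist()]
    return HaplotypePanel(site_ids, positions, matrix, chrom=config.chrom)


def gen_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping transcripts, each with >= 2 exons, CDS and UTRs.

    Genes are laid out one per equal slot of the contig so flanking and
    intergenic space always exists between neighbours; a slot too small
    for a transcript raises (infeasible packing).  A random coding
    sequence is attached so missense calling works on simulated genes.
    """
    rng = np.random.default_rng(config.seed + 1)
    slot = config.genome_length_bp // config.n_genes
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 400, size=n_exons)
        intron_lens = rng.integers(500, 2000, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        if span + 2 > slot:
            raise ValueError(
                f"infeasible packing: transcript of {span} bp does not fit a "
                f"{slot} bp slot ({config.n_genes} genes on {config.genome_length_bp} bp)"
            )
        offset = int(rng.integers(0, slot - span - 1))
        tx_start = i * slot + offset + 1
        exons = []
        pos = tx_start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j]) - 1))
            pos = exons[-1][1] + 1
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        tx_end = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        # UTRs: first/last 60 bp of the transcript (in genomic orientation
        # for + strand, swapped for -); CDS is the rest, trimmed to frame.
        utr_len = 60
        first_s, first_e = exons[0]
        last_s, last_e = exons[-1]
        head = (first_s, first_s + utr_len - 1)
        tail = (last_e - utr_len + 1, last_e)
        cds = []
        for s, e in exons:
            cs = max(s, head[1] + 1)
            ce = min(e, tail[0] - 1)
            if cs <= ce:
                cds.append((cs, ce))
        cds_len = sum(e - s + 1 for s, e in cds)
        trim = cds_len % 3
        if trim:
            if strand == "+":
                s, e = cds[-1]
                cds[-1] = (s, e - trim)
            else:
                s, e = cds[0]
                cds[0] = (s + trim, e)
        utr5, utr3 = ([head], [tail]) if strand == "+" else ([tail], [head])
        cds_len = sum(e - s + 1 for s, e in cds)
        seq = "".join(rng.choice(list("ACGT"), size=cds_len))
        genes.append(
            GeneModel(
                gene_id=f"g{i:03d}",
                chrom=config.chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                cds_seq=seq,
            )
        )
    return genes


def gen_peak_tracks(
    config: SimulationConfig,
    target_variants: Sequence[Variant] = (),
    target_cell: str | None = None,
    target_marks: Sequence[str] | None = None,
) -> list[PeakTrack]:
    """One track per (cell, mark): background peaks plus planted enrichment.

    Background intervals of width ``peak_width_bp`` are dropped uniformly
    so that roughly ``background_peak_fraction`` of the contig is covered.
    In the designated cell's designated marks (defaults: the first cell,
    all marks), background peaks overlapping a target variant are removed
    and each target is instead covered by a planted peak with probability
    ``min(1, planted_fold * background_peak_fraction)`` — so the true fold
    enrichment at targets is exactly ``planted_fold`` (capped), and target
    coverage in every other cell stays at the background rate.
    """
    rng = np.random.default_rng(config.seed + 2)
    L = config.genome_length_bp
    w = config.peak_width_bp
    f = config.background_peak_fraction
    p_plant = config.planted_fold * f
    if p_plant > 1:
        log.warning(
            "planted_fold * background (%.3f) exceeds 1; planting capped at certainty",
            p_plant,
        )
        p_plant = 1.0
    cell0 = target_cell if target_cell is not None else config.cells[0]
    marks0 = set(target_marks) if target_marks is not None else set(config.marks)
    target_p0 = np.array(sorted(v.pos - 1 for v in target_variants), dtype=np.int64)
    # uniformly dropped intervals overlap each other, so n * w / L would
    # undershoot the requested coverage; solve 1 - (1 - w/L)^n = f instead
    n_bg = int(round(-np.log1p(-f) * L / w)) if f < 1 else int(np.ceil(L / w))
    tracks = []
    for cell in config.cells:
        for mark in config.marks:
            starts = rng.integers(0, max(1, L - w), size=n_bg)
            ivals = [(config.chrom, int(s), int(s) + w) for s in np.sort(starts)]
            planted = cell == cell0 and mark in marks0 and target_p0.size > 0
            if planted:
                ivals = [
                    (c, s, e)
                    for c, s, e in ivals
                    if not _covers_any(s, e, target_p0)
                ]
                accept = rng.random(target_p0.size) < p_plant
                for p0 in target_p0[accept].tolist():
                    s = max(0, p0 - w // 2)
                    ivals.append((config.chrom, s, s + w))
            tracks.append(PeakTrack(cell, mark, ivals))
    return tracks


def _covers_any(s: int, e: int, sorted_points: np.ndarray) -> bool:
    i = int(np.searchsorted(sorted_points, s, side="left"))
    return i < sorted_points.size and sorted_points[i] < e


# ---------------------------------------------------------------------------
# packaged 72-variant worked example
# ---------------------------------------------------------------------------


@dataclass
class Ss72Fixture:
    """The packaged worked example: 72 risk variants on a synthetic contig
    with gene models, per-(cell, mark) peak tracks and an eQTL table whose
    end-to-end analysis reproduces the published category counts."""

    variants: list[Variant]
    genes: list[GeneModel]
    tracks: list[PeakTrack]
    eqtl: EqtlTable
    manifest_path: object = None

    cells: tuple[str, ...] = DEFAULT_CELLS


def emit_ss72_fixture() -> Ss72Fixture:
    """Load the packaged 72-variant fixture (deterministic, shipped as data)."""
    root = resources.files("regumap").joinpath("data/ss72")
    variants = read_variants(root / "variants.tsv")
    genes = read_gene_models(root / "genes.gff3", cds_fasta=root / "cds.fasta")
    manifest = root / "manifest.yaml"
    tracks = read_tracks(manifest)
    eqtl = read_eqtl(root / "eqtl.tsv")
    return Ss72Fixture(variants, genes, tracks, eqtl, manifest_path=manifest)


#: Alias matching the "load the worked example" phrasing used in docs.
load_ss72 = emit_ss72_fixture
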