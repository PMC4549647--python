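"""Construct the packaged 72-variant worked-example fixture.

Writes variants.tsv, genes.gff3, cds.fasta, per-(cell, mark) BED tracks,
manifest.yaml and eqtl.tsv into src/regumap/data/ss72/.  The construction
is fully deterministic (no RNG): coordinates are synthetic, laid out on a
400 kb contig so that the full pipeline reproduces the worked example's
category counts exactly.  Run from the repository root:

    python scripts/build_ss72_fixture.py
"""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from regumap.io import GeneModel, Variant, write_bed, write_gene_models, write_variants  # noqa: E402

OUT = ROOT / "src" / "regumap" / "data" / "ss72"

CHROM = "chrS"
CELLS = ("GM12878", "CD14", "A549")
MARKS = (
    "PolII", "H3K27Ac", "H3K36me3", "H3K27me3", "H3K4me1",
    "H3K4me2", "H3K4me3", "H3K9Ac", "CTCF", "DNase",
)
PEAK_HALF = 10  # planted peaks are 20 bp, centred on the variant base

GGA100 = "GGA" * 100  # poly-glycine CDS for the four coding genes


def coding_gene(gid: str, start: int) -> GeneModel:
    """Two-exon gene, CDS = exons (300 nt), used for the missense variants."""
    return GeneModel(
        gene_id=gid, chrom=CHROM, strand="+",
        tx_start=start, tx_end=start + 399,
        exons=[(start, start + 99), (start + 200, start + 399)],
        cds=[(start, start + 99), (start + 200, start + 399)],
        cds_seq=GGA100,
    )


def build_genes() -> list[GeneModel]:
    g05_start = 180_000
    g06_start = 260_000
    return [
        coding_gene("g01", 20_000),
        coding_gene("g02", 60_000),
        coding_gene("g03", 100_000),
        coding_gene("g04", 140_000),
        # g05: non-coding two-exon transcript with a 50 kb intron that
        # hosts all 40 intronic variants well away from splice sites
        GeneModel(
            gene_id="g05", chrom=CHROM, strand="+",
            tx_start=g05_start, tx_end=g05_start + 50_399,
            exons=[(g05_start, g05_start + 199), (g05_start + 50_200, g05_start + 50_399)],
        ),
        # g06: coding gene with annotated 5'/3' UTRs for the UTR variants
        GeneModel(
            gene_id="g06", chrom=CHROM, strand="+",
            tx_start=g06_start, tx_end=g06_start + 999,
            exons=[(g06_start, g06_start + 199), (g06_start + 400, g06_start + 999)],
            cds=[(g06_start + 100, g06_start + 199), (g06_start + 400, g06_start + 701)],
            utr5=[(g06_start, g06_start + 99)],
            utr3=[(g06_start + 702, g06_start + 999)],
        ),
    ]


def build_variants() -> list[Variant]:
    out: list[Variant] = []

    def add(i: int, pos: int, ref: str = "A", alt: str = "G", flags: tuple[str, ...] = ()):
        out.append(Variant(f"ss{i:03d}", CHROM, pos, ref, alt, flags=frozenset(flags)))

    # 4 coding missense variants (poly-Gly CDS: each substitution below
    # changes the encoded amino acid without creating a stop)
    add(1, 20_000, "G", "A")    # GGA -> AGA, Gly -> Arg
    add(2, 60_003, "G", "C")    # GGA -> CGA, Gly -> Arg
    add(3, 100_001, "G", "T")   # GGA -> GTA, Gly -> Val
    add(4, 140_001, "G", "C")   # GGA -> GCA, Gly -> Ala
    # 40 intronic variants, 1 kb apart, deep inside g05's big intron;
    # four carry the pass-through NMD-target consequence flag
    for i in range(5, 45):
        flags = ("NMD_target",) if i in (20, 21, 22, 23) else ()
        add(i, 181_000 + (i - 5) * 1_000, flags=flags)
    # 2 x 5'UTR + 1 x 3'UTR in g06
    add(45, 260_010)
    add(46, 260_050)
    add(47, 260_750)
    # 12 upstream variants (1-2 kb 5' of each gene's tx_start, + strand)
    up_positions = [
        19_000, 18_000, 59_000, 58_000, 99_000, 98_000,
        139_000, 138_000, 179_000, 178_000, 259_000, 258_000,
    ]
    for j, pos in enumerate(up_positions):
        add(48 + j, pos)
    # 7 downstream variants (1-2.1 kb 3' of tx_end)
    down_positions = [21_400, 22_400, 61_400, 62_400, 101_400, 102_400, 141_400]
    for j, pos in enumerate(down_positions):
        add(60 + j, pos)
    # 6 intergenic variants (> 10 kb from every transcript)
    for j, pos in enumerate([5_000, 6_000, 7_000, 300_000, 310_000, 320_000]):
        add(67 + j, pos)
    return out


def ids(*specs: str) -> list[str]:
    """Expand 'ss005-ss018'-style ranges into id lists."""
    out: list[str] = []
    for spec in specs:
        if "-" in spec:
            lo, hi = spec.split("-")
            out.extend(f"ss{i:03d}" for i in range(int(lo[2:]), int(hi[2:]) + 1))
        else:
            out.append(spec)
    return out


# which variants each (cell, mark) track covers; every flag in the worked
# example traces back to exactly these placements
TRACK_CONTENT: dict[tuple[str, str], list[str]] = {
    # promoters: PolII occupancy (21 variants; ss001 is the missense promoter)
    ("GM12878", "PolII"): ids("ss001", "ss005-ss018"),
    ("CD14", "PolII"): ids("ss019-ss024"),
    # enhancer marks, never at a PolII-bound variant (41 enhancer variants)
    ("GM12878", "H3K27Ac"): ids(
        "ss028-ss038", "ss045-ss047", "ss048-ss059", "ss070", "ss071",
        # activity at promoter variants too: masked by PolII in the rules
        "ss005-ss008",
    ),
    ("CD14", "H3K27Ac"): ids("ss060-ss066"),
    ("GM12878", "H3K36me3"): ids("ss039", "ss040", "ss067", "ss068"),
    ("A549", "H3K27me3"): ids("ss041", "ss069"),
    # insulators: CTCF (5 variants; ss002/ss003 are the missense insulators)
    ("GM12878", "CTCF"): ids("ss002", "ss003", "ss025-ss027"),
    # open chromatin (34 variants)
    ("GM12878", "DNase"): ids("ss001", "ss005-ss015", "ss025", "ss028-ss040"),
    ("CD14", "DNase"): ids("ss045", "ss047", "ss048-ss053"),
    # promoter-activity histone marks (report-only; no rule consumes them)
    ("GM12878", "H3K4me2"): ids("ss001", "ss005-ss024"),
    ("GM12878", "H3K4me3"): ids("ss001", "ss005-ss024"),
    ("GM12878", "H3K9Ac"): ids("ss001", "ss005-ss024"),
    ("CD14", "H3K4me2"): ids("ss019-ss024"),
    ("GM12878", "H3K4me1"): ids("ss028-ss038"),
}

# transcription-factor tracks: pass-through tf_hits only.  ss072 carries
# TF-binding evidence but none of the five motif/eQTL flags.
TF_CONTENT: dict[str, list[str]] = {
    "NFKB": ids("ss001", "ss005-ss008", "ss028-ss030", "ss072"),
    "STAT": ids("ss009-ss011"),
    "EGR1": ids("ss012-ss014"),
}

EQTL_ROWS = [
    *[(v, "g05", "GM12878") for v in ids("ss005-ss009")],
    *[(v, "g05", "GM12878") for v in ids("ss028-ss031")],
    ("ss046", "g06", "GM12878"),
    ("ss047", "g06", "GM12878"),
    ("ss060", "g01", "CD14"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    variants = build_variants()
    pos_by_id = {v.id: v.pos for v in variants}
    assert len(variants) == 72

    write_variants(variants, OUT / "variants.tsv")
    write_gene_models(build_genes(), OUT / "genes.gff3")
    with open(OUT / "cds.fasta", "w") as fh:
        for gid in ("g01", "g02", "g03", "g04"):
            fh.write(f">{gid}\n{GGA100}\n")

    manifest_entries = []
    for cell in CELLS:
        for mark in MARKS:
            covered = TRACK_CONTENT.get((cell, mark), [])
            ivals = []
            for vid in covered:
                p0 = pos_by_id[vid] - 1
                ivals.append((CHROM, p0 - PEAK_HALF, p0 + PEAK_HALF))
            fname = f"{cell}_{mark}.bed"
            write_bed(sorted(ivals), OUT / fname)
            manifest_entries.append({"file": fname, "cell": cell, "mark": mark})
    for tf, covered in TF_CONTENT.items():
        ivals = [
            (CHROM, pos_by_id[vid] - 1 - PEAK_HALF, pos_by_id[vid] - 1 + PEAK_HALF)
            for vid in covered
        ]
        fname = f"GM12878_TF_{tf}.bed"
        write_bed(sorted(ivals), OUT / fname)
        manifest_entries.append(
            {"file": fname, "cell": "GM12878", "mark": tf, "kind": "tf"}
        )

    import yaml

    with open(OUT / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest_entries, fh, sort_keys=False)

    with open(OUT / "eqtl.tsv", "w") as fh:
        fh.write("variant_id\tgene_id\tcell\n")
        for row in EQTL_ROWS:
            fh.write("\t".join(row) + "\n")

    print(f"wrote fixture to {OUT}")


if __name__ == "__main__":
    main()
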