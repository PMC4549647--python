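"""Pairwise r-squared from phased haplotypes and seed-to-proxy expansion.

r2 between two biallelic sites is computed from phased haplotype counts::

    D  = p_AB - p_A * p_B
    r2 = D**2 / (p_A (1 - p_A) p_B (1 - p_B))

which equals the squared Pearson correlation of the two 0/1 allele
columns.  Expansion collects, for each seed, every panel site with
``r2 >= r2_min`` within ``max_dist_bp`` of the seed (defaults 0.80 and
200 kb, the usual proxy-search settings for covering enhancer elements),
excluding the seed itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import Variant

log = logging.getLogger(__name__)

DEFAULT_R2_MIN = 0.80
DEFAULT_MAX_DIST_BP = 200_000


class HaplotypePanel:
    """Phased 0/1 allele matrix over sites of one contig.

    ``matrix`` is ``n_haplotypes x n_sites``; every column must be
    polymorphic (r2 is undefined at a monomorphic site) and positions must
    be strictly increasing.  ``ref``/``alt`` allele labels are optional and
    only used when proxies are materialised as :class:`Variant` records.
    """

    def __init__(
        self,
        site_ids: Sequence[str],
        positions: Sequence[int],
        matrix: np.ndarray,
        chrom: str = "chrS",
        ref: Sequence[str] | None = None,
        alt: Sequence[str] | None = None,
    ) -> None:
        matrix = np.asarray(matrix, dtype=np.int8)
        if matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (haplotypes x sites)")
        n_hap, n_sites = matrix.shape
        if n_hap < 4:
            raise ValueError(f"need >= 4 haplotypes for reliable r2, got {n_hap}")
        if len(site_ids) != n_sites or len(positions) != n_sites:
            raise ValueError("site_ids/positions length must match matrix columns")
        if not np.isin(matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        positions = np.asarray(positions, dtype=np.int64)
        if n_sites > 1 and not (np.diff(positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        freqs = matrix.mean(axis=0)
        mono = (freqs == 0) | (freqs == 1)
        if mono.any():
            bad = [site_ids[i] for i in np.flatnonzero(mono)[:5]]
            raise ValueError(f"monomorphic sites in panel (e.g. {bad})")
        self.chrom = chrom
        self.site_ids = list(site_ids)
        self.positions = positions
        self.matrix = matrix
        self.ref = list(ref) if ref is not None else ["A"] * n_sites
        self.alt = list(alt) if alt is not None else ["G"] * n_sites
        self._index = {sid: i for i, sid in enumerate(self.site_ids)}
        if len(self._index) != n_sites:
            raise ValueError("site ids must be unique")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def site_index(self, site: str | int) -> int:
        if isinstance(site, str):
            try:
                return self._index[site]
            except KeyError:
                raise KeyError(f"site {site!r} not in panel") from None
        return int(site)

    def variant_at(self, i: int, source: str = "ld_proxy") -> Variant:
        return Variant(
            self.site_ids[i], self.chrom, int(self.positions[i]),
            self.ref[i], self.alt[i], source=source,
        )


@dataclass
class ProxySet:
    """All proxies of one seed: (site id, r2, distance in bp) triples."""

    seed_id: str
    proxies: list[tuple[str, float, int]] = field(default_factory=list)

    @property
    def proxy_ids(self) -> set[str]:
        return {sid for sid, _, _ in self.proxies}

    def __len__(self) -> int:
        return len(self.proxies)


def compute_r2(site_a: str | int, site_b: str | int, panel: HaplotypePanel) -> float:
    """r2 between two panel sites from phased haplotype counts."""
    ia, ib = panel.site_index(site_a), panel.site_index(site_b)
    if ia > ib:  # canonical order makes symmetry exact, not just to rounding
        ia, ib = ib, ia
    x = panel.matrix[:, ia].astype(np.float64)
    y = panel.matrix[:, ib].astype(np.float64)
    pa, pb = x.mean(), y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("r2 undefined at a monomorphic site")
    d = (x * y).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def _r2_vector(panel: HaplotypePanel, i: int, js: np.ndarray) -> np.ndarray:
    """Vectorised r2 of column ``i`` against columns ``js``."""
    x = panel.matrix[:, i].astype(np.float64)
    y = panel.matrix[:, js].astype(np.float64)
    pa = x.mean()
    pb = y.mean(axis=0)
    d = (x[:, None] * y).mean(axis=0) - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def expand_ld(
    seeds: Iterable[Variant],
    panel: HaplotypePanel,
    r2_min: float = DEFAULT_R2_MIN,
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
) -> list[ProxySet]:
    """Expand each seed to its proxy set (r2 and distance filtered).

    Seeds absent from the panel are skipped with a warning.  The seed's own
    panel column never appears in its proxy list: proxies are by definition
    *new* variants relative to the seeds.
    """
    if not (0 < r2_min <= 1):
        raise ValueError(f"r2_min must be in (0, 1], got {r2_min}")
    if max_dist_bp <= 0:
        raise ValueError("max_dist_bp must be positive")
    out = []
    for seed in seeds:
        if seed.id not in panel._index:
            warnings.warn(f"seed {seed.id} absent from panel; skipped", stacklevel=2)
            continue
        i = panel.site_index(seed.id)
        pos = panel.positions[i]
        lo = int(np.searchsorted(panel.positions, pos - max_dist_bp, side="left"))
        hi = int(np.searchsorted(panel.positions, pos + max_dist_bp, side="right"))
        js = np.arange(lo, hi)
        js = js[js != i]
        pset = ProxySet(seed.id)
        if js.size:
            r2s = _r2_vector(panel, i, js)
            for j, r2 in zip(js.tolist(), r2s.tolist()):
                if r2 >= r2_min:
                    pset.proxies.append(
                        (panel.site_ids[j], r2, int(abs(panel.positions[j] - pos)))
                    )
        out.append(pset)
    return out


def proxies_to_variants(
    proxy_sets: Iterable[ProxySet],
    panel: HaplotypePanel,
    exclude_ids: Iterable[str] = (),
) -> list[Variant]:
    """De-duplicated union of proxies as variants tagged ``source=ld_proxy``.

    ``exclude_ids`` (typically the seed ids) are dropped so the union counts
    only variants new relative to the seeds.
    """
    excluded = set(exclude_ids)
    seen: set[str] = set()
    out = []
    for pset in proxy_sets:
        for sid, _, _ in pset.proxies:
            if sid in seen or sid in excluded:
                continue
            seen.add(sid)
            out.append(panel.variant_at(panel.site_index(sid)))
    out.sort(key=lambda v: (v.chrom, v.pos, v.id))
    return out


@dataclass
class ProxyAnnotation:
    """Location + regulatory calls for the proxy union, plus novelty report."""

    proxies: list[Variant]
    location_calls: list
    regulatory_calls: list
    new_genes: set[str]
    missense_ids: list[str]


def annotate_proxies(
    proxy_sets: Sequence[ProxySet],
    panel: HaplotypePanel,
    genes,
    tracks,
    eqtl=None,
    seeds: Sequence[Variant] = (),
    flank_bp: int | None = None,
) -> ProxyAnnotation:
    """Run the locator and regulatory classifier over the proxy union.

    "New genes" are genes hit (genically) by a proxy but by no seed — the
    added value of the LD expansion.  Missense proxies are listed
    separately.  An empty proxy union yields an empty report.
    """
    from .classify import classify_regulatory
    from .locate import DEFAULT_FLANK_BP, classify_locations

    flank = DEFAULT_FLANK_BP if flank_bp is None else flank_bp
    proxies = proxies_to_variants(proxy_sets, panel, exclude_ids={s.id for s in seeds})
    if not proxies:
        return ProxyAnnotation([], [], [], set(), [])
    loc_calls = classify_locations(proxies, genes, flank)
    # exploratory annotation: tolerate an incomplete mark panel
    reg_calls = [
        classify_regulatory(v, tracks, eqtl=eqtl, require_marks=False) for v in proxies
    ]
    seed_genes = {
        c.gene_id
        for c in classify_locations(seeds, genes, flank)
        if c.distance_to_gene == 0 and c.gene_id is not None
    } if seeds else set()
    proxy_genes = {
        c.gene_id for c in loc_calls if c.distance_to_gene == 0 and c.gene_id is not None
    }
    missense = [c.variant_id for c in loc_calls if c.primary_class == "exonic_missense"]
    return ProxyAnnotation(proxies, loc_calls, reg_calls, proxy_genes - seed_genes, missense)


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------


def write_panel_vcf(panel: HaplotypePanel, path: str | Path, contig_length: int | None = None) -> None:
    """Write the panel as a minimal phased VCF (haploid pairs -> GT a|b)."""
    n_hap = panel.n_haplotypes
    if n_hap % 2 != 0:
        raise ValueError("VCF output needs an even haplotype count (diploid samples)")
    n_samples = n_hap // 2
    length = int(contig_length if contig_length is not None else panel.positions[-1] + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"S{i:04d}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(panel.n_sites):
            col = panel.matrix[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(n_samples))
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t{panel.site_ids[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_panel_vcf(path: str | Path) -> HaplotypePanel:
    """Load a phased single-contig VCF into a haplotype panel."""
    from cyvcf2 import VCF

    site_ids, positions, rows, refs, alts = [], [], [], [], []
    chrom = None
    for rec in VCF(str(path)):
        if chrom is None:
            chrom = rec.CHROM
        elif rec.CHROM != chrom:
            raise ValueError("panel VCF must be single-contig")
        alleles = []
        for gt in rec.genotypes:
            a, b, phased = gt[0], gt[1], gt[2]
            if not phased:
                raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
            alleles.extend((a, b))
        site_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(alleles)
    matrix = np.asarray(rows, dtype=np.int8).T
    return HaplotypePanel(site_ids, positions, matrix, chrom or "chrS", refs, alts)


def write_panel_tsv(panel: HaplotypePanel, path: str | Path) -> None:
    """Plain 0/1 matrix TSV: header row of site ids, then one row per haplotype."""
    with open(path, "w") as fh:
        fh.write("#chrom\t" + panel.chrom + "\n")
        fh.write("#pos\t" + "\t".join(map(str, panel.positions.tolist())) + "\n")
        fh.write("id\t" + "\t".join(panel.site_ids) + "\n")
        for i in range(panel.n_haplotypes):
            fh.write(f"h{i:04d}\t" + "\t".join(map(str, panel.matrix[i].tolist())) + "\n")


def read_panel_tsv(path: str | Path) -> HaplotypePanel:
    chrom = "chrS"
    positions: list[int] = []
    site_ids: list[str] = []
    rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#chrom":
                chrom = fields[1]
            elif fields[0] == "#pos":
                positions = [int(x) for x in fields[1:]]
            elif fields[0] == "id":
                site_ids = fields[1:]
            else:
                rows.append([int(x) for x in fields[1:]])
    return HaplotypePanel(site_ids, positions, np.asarray(rows, dtype=np.int8), chrom)
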