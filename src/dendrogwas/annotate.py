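"""Gene-context annotation of SNPs from a GFF3 gene model set.

Each SNP receives exactly one of six mutually exclusive categories:
exon, intron, five_prime_region, three_prime_region (within a flank of a
gene boundary, default 10 kb, with the side named by the nearest gene's
strand), or intergenic, together with the nearest gene and its exact
boundary distance in bp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from intervaltree import IntervalTree

CATEGORIES = (
    "exon",
    "intron",
    "five_prime_region",
    "three_prime_region",
    "intergenic",
)


@dataclass
class GeneModel:
    """One gene: 1-based inclusive span, strand, exon intervals, product."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for a, b in self.exons:
            if a < self.start or b > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {a}-{b} outside span "
                    f"{self.start}-{self.end}"
                )


@dataclass
class SnpAnnotation:
    """Gene-context classification of one SNP."""

    snp_id: str
    chrom: str
    pos: int
    category: str
    gene_id: str | None = None
    distance: int | None = None  # bp to nearest gene boundary; 0 if genic
    product: str = ""
    within_flank: bool = False  # the paper's "within 10 kb" alias
    tied_gene_ids: list[str] = field(default_factory=list)
    note: str = ""


def _validate_gff_lines(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 tab-separated fields")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from e
            if start > end:
                raise ValueError(f"{path}:{ln}: start > end")


def load_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 file into gene models (gene/mRNA/exon hierarchy).

    1-based inclusive coordinates are preserved.  Malformed lines raise
    with the offending line number; an empty file yields an empty list.
    """
    import gffutils

    _validate_gff_lines(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as e:
        if "empty" in str(e).lower() or isinstance(e, ValueError):
            return []
        raise
    genes = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        product = ""
        for key in ("product", "description", "Name"):
            if key in gene.attributes:
                product = gene.attributes[key][0]
                break
        genes.append(
            GeneModel(
                gene.id, gene.seqid, gene.start, gene.end, gene.strand or ".",
                exons, product,
            )
        )
    return genes


class GeneIndex:
    """Interval index of gene models per chromosome."""

    def __init__(self, genes: list[GeneModel]) -> None:
        self.genes = {g.gene_id: g for g in genes}
        self.gene_trees: dict[str, IntervalTree] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            # IntervalTree is half-open; store [start, end+1)
            self.gene_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end + 1, g.gene_id
            )
            for a, b in g.exons:
                self.exon_trees.setdefault(g.chrom, IntervalTree()).addi(
                    a, b + 1, g.gene_id
                )
            self.by_chrom.setdefault(g.chrom, []).append(g)


def classify_snp(
    snp_id: str,
    chrom: str,
    pos: int,
    index: GeneIndex,
    flank: int = 10000,
) -> SnpAnnotation:
    """Assign one SNP its gene-context category.

    Inside an exon -> exon; inside a gene but no exon -> intron; within
    `flank` bp of a gene boundary -> five_prime_region/three_prime_region
    by the nearest gene's strand and side; otherwise intergenic with the
    exact distance to the nearest gene.  Equidistant genes are tied toward
    the lexicographically lower gene id, all ties reported.
    """
    if chrom not in index.gene_trees:
        return SnpAnnotation(
            snp_id, chrom, pos, "intergenic",
            note="no annotated gene on chromosome",
        )
    exon_hits = index.exon_trees.get(chrom, IntervalTree())[pos]
    if exon_hits:
        gid = sorted(h.data for h in exon_hits)[0]
        return SnpAnnotation(
            snp_id, chrom, pos, "exon", gid, 0, index.genes[gid].product
        )
    gene_hits = index.gene_trees[chrom][pos]
    if gene_hits:
        gid = sorted(h.data for h in gene_hits)[0]
        return SnpAnnotation(
            snp_id, chrom, pos, "intron", gid, 0, index.genes[gid].product
        )
    # nearest gene by boundary distance
    best: list[tuple[int, str]] = []
    for g in index.by_chrom[chrom]:
        d = g.start - pos if pos < g.start else pos - g.end
        if not best or d < best[0][0]:
            best = [(d, g.gene_id)]
        elif d == best[0][0]:
            best.append((d, g.gene_id))
    dist = best[0][0]
    tied = sorted(gid for _, gid in best)
    gid = tied[0]
    g = index.genes[gid]
    upstream = pos < g.start  # before the gene in coordinate order
    if dist <= flank:
        if g.strand == "-":
            category = "three_prime_region" if upstream else "five_prime_region"
        else:
            category = "five_prime_region" if upstream else "three_prime_region"
        return SnpAnnotation(
            snp_id, chrom, pos, category, gid, dist, g.product,
            within_flank=True, tied_gene_ids=tied[1:],
        )
    return SnpAnnotation(
        snp_id, chrom, pos, "intergenic", gid, dist, g.product,
        tied_gene_ids=tied[1:],
    )


def annotate_snps(
    snps: list[tuple[str, str, int]],
    genes: list[GeneModel],
    flank: int = 10000,
) -> list[SnpAnnotation]:
    """Classify a list of (snp_id, chrom, pos) against a gene model set."""
    index = GeneIndex(genes)
    return [classify_snp(sid, c, p, index, flank) for sid, c, p in snps]
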