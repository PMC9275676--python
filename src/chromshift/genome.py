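"""Genome and gene models.

Coordinates are 0-based, half-open throughout the package; conversion to
1-based conventions happens only at format boundaries (none of the formats
used here require it). A gene's TSS/TES are single base positions: for a
plus-strand gene ``tss < tes``; for a minus-strand gene transcription runs
right-to-left, so ``tss > tes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    tss: int
    tes: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        """Half-open end of the gene body (one past the last transcribed base)."""
        return max(self.tss, self.tes) + 1

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")
        exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for s, e in exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
        if not exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")


@dataclass
class GenomeModel:
    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel] = field(default_factory=list)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def length(self) -> int:
        return sum(size for _, size in self.chromosomes)

    def validate(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(size <= 0 for _, size in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        sizes = self.chrom_sizes
        for gene in self.genes:
            gene.validate()
            if gene.chrom not in sizes:
                raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
            if gene.start < 0 or gene.end > sizes[gene.chrom]:
                raise ValueError(f"gene {gene.gene_id}: outside chromosome bounds")


def write_gene_models(genome: GenomeModel, path) -> None:
    """Write gene models as a tab table (one row per gene, exon blocks as
    comma-separated start/end lists, BED12-like)."""
    rows = []
    for g in genome.genes:
        starts = ",".join(str(s) for s, _ in sorted(g.exons))
        ends = ",".join(str(e) for _, e in sorted(g.exons))
        rows.append((g.gene_id, g.chrom, g.strand, g.tss, g.tes, starts, ends))
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "tes", "exon_starts", "exon_ends"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_models(path, chromosomes: list[tuple[str, int]]) -> GenomeModel:
    df = pd.read_csv(path, sep="\t", dtype={"exon_starts": str, "exon_ends": str})
    genes = []
    for row in df.itertuples(index=False):
        exons = list(
            zip(
                (int(x) for x in str(row.exon_starts).split(",")),
                (int(x) for x in str(row.exon_ends).split(",")),
            )
        )
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                tes=int(row.tes),
                exons=exons,
            )
        )
    genome = GenomeModel(chromosomes=list(chromosomes), genes=genes)
    genome.validate()
    return genome


def write_chrom_sizes(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        for name, size in genome.chromosomes:
            fh.write(f"{name}\t{size}\n")


def read_chrom_sizes(path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            out.append((name, int(size)))
    return out
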