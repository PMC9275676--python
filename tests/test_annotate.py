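"""Annotation: prioritized context labels against a brute-force per-base
footprint oracle, boundary exactness, and gene assignment."""

import numpy as np
import pandas as pd
import pytest

from chromshift import annotate as ann
from chromshift.genome import GeneModel, GenomeModel


def plus_gene(gene_id="gp", tss=100_000, tes=104_999, chrom="chr1"):
    return GeneModel(gene_id=gene_id, chrom=chrom, strand="+", tss=tss, tes=tes,
                     exons=[(tss, tss + 1000), (tss + 3000, tes + 1)])


def minus_gene(gene_id="gm", tss=104_999, tes=100_000, chrom="chr1"):
    return GeneModel(gene_id=gene_id, chrom=chrom, strand="-", tss=tss, tes=tes,
                     exons=[(tes, tes + 1000), (tes + 3000, tss + 1)])


def single_gene_genome(gene, size=400_000):
    g = GenomeModel(chromosomes=[(gene.chrom, size)], genes=[gene])
    g.validate()
    return g


def regions(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# brute-force oracle


def context_oracle(genome, region_df):
    """Materialize all footprints as per-base boolean masks, then label each
    region with the first class having any covered base in it."""
    sizes = genome.chrom_sizes
    masks = {
        c: {ch: np.zeros(n, dtype=bool) for ch, n in sizes.items()}
        for c in ann.CONTEXT_ORDER[:-1]
    }

    def paint(cls, chrom, lo, hi):
        lo, hi = max(0, lo), min(sizes[chrom], hi)
        if lo < hi:
            masks[cls][chrom][lo:hi] = True

    for g in genome.genes:
        t = g.tss
        if g.strand == "+":
            paint("Promoter.Up", g.chrom, t - 2000, t)
            paint("Promoter.Down", g.chrom, t, t + 2000)
            paint("5' Distal", g.chrom, t - 50_000, t - 2000)
            paint("3' Distal", g.chrom, t + 2000, t + 50_000)
        else:
            paint("Promoter.Up", g.chrom, t + 1, t + 2001)
            paint("Promoter.Down", g.chrom, t - 1999, t + 1)
            paint("5' Distal", g.chrom, t + 2001, t + 50_001)
            paint("3' Distal", g.chrom, t - 49_999, t - 1999)
        for s, e in g.exons:
            paint("Exons", g.chrom, s, e)
        exons = sorted(g.exons)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            paint("Introns", g.chrom, e0, s1)
        paint("TES", g.chrom, g.tes - 1000, g.tes + 1000)
    labels = []
    for r in region_df.itertuples(index=False):
        for cls in ann.CONTEXT_ORDER[:-1]:
            if masks[cls][r.chrom][r.start : r.end].any():
                labels.append(cls)
                break
        else:
            labels.append("Intergenic")
    return pd.Series(labels, index=region_df.index)


def test_context_matches_per_base_oracle_on_random_regions(two_chrom_genome):
    rng = np.random.default_rng(0)
    n = 1000
    chroms = rng.choice(["chr1", "chr2"], n)
    starts = rng.integers(0, 498_000, n)
    df = pd.DataFrame({"chrom": chroms, "start": starts,
                       "end": starts + rng.integers(50, 1000, n)})
    got = ann.assign_context(df, two_chrom_genome)
    expected = context_oracle(two_chrom_genome, df)
    assert (got == expected).all()


def test_context_oracle_covers_all_classes_and_strands():
    """Long, sparse genes so every class (incl. Introns and Intergenic) is
    reachable; labels still equal the per-base oracle."""
    from chromshift import simulate

    genome = simulate.simulate_genome(
        2, 500_000, 6, gene_length_range=(20_000, 40_000), seed=3
    )
    rng = np.random.default_rng(1)
    n = 1000
    chroms = rng.choice(["chr1", "chr2"], n)
    starts = rng.integers(0, 498_000, n)
    df = pd.DataFrame({"chrom": chroms, "start": starts,
                       "end": starts + rng.integers(50, 1000, n)})
    got = ann.assign_context(df, genome)
    expected = context_oracle(genome, df)
    assert (got == expected).all()
    assert set(got.unique()) == set(ann.CONTEXT_ORDER)
    assert {g.strand for g in genome.genes} == {"+", "-"}


def test_priority_overlap_promoter_beats_exon():
    g = plus_gene()
    genome = single_gene_genome(g)
    # region covering both the first exon and the Promoter.Down window
    lab = ann.assign_context(regions([("chr1", g.tss + 100, g.tss + 500)]), genome)
    assert lab.iloc[0] == "Promoter.Down"
    # 1 kb upstream of the TSS
    lab2 = ann.assign_context(regions([("chr1", g.tss - 1500, g.tss - 900)]), genome)
    assert lab2.iloc[0] == "Promoter.Up"
    # beyond 50 kb of everything
    lab3 = ann.assign_context(regions([("chr1", 300_000, 300_100)]), genome)
    assert lab3.iloc[0] == "Intergenic"


def test_priority_monotonicity_when_footprint_removed():
    g = plus_gene()
    genome = single_gene_genome(g)
    region = regions([("chr1", g.tss + 100, g.tss + 500)])  # promoter+exon overlap
    assert ann.assign_context(region, genome).iloc[0] == "Promoter.Down"
    # shrinking the promoter windows away promotes the region to Exons,
    # never to something lower-priority than before
    lab = ann.assign_context(region, genome, promoter_bp=10)
    assert lab.iloc[0] == "Exons"


@pytest.mark.parametrize("make_gene", [plus_gene, minus_gene])
def test_promoter_boundary_exactness_per_strand(make_gene):
    g = make_gene()
    genome = single_gene_genome(g)
    t = g.tss
    if g.strand == "+":
        outside = regions([("chr1", t - 2500, t - 2000)])  # ends exactly at window start
        inside = regions([("chr1", t - 2500, t - 1999)])
    else:
        outside = regions([("chr1", t + 2001, t + 2500)])  # starts exactly past window
        inside = regions([("chr1", t + 2000, t + 2500)])
    assert ann.assign_context(outside, genome).iloc[0] != "Promoter.Up"
    assert ann.assign_context(inside, genome).iloc[0] == "Promoter.Up"
    assert ann.assign_genes(outside, genome).query("mode=='promoter_associated'").empty
    got = ann.assign_genes(inside, genome)
    assert (got["mode"] == "promoter_associated").all() and len(got) == 1


def test_gene_assignment_multi_promoter_and_enhancer():
    ga = plus_gene("ga", tss=100_000, tes=104_999)
    gb = minus_gene("gb", tss=102_000, tes=97_500)
    genome = GenomeModel(chromosomes=[("chr1", 400_000)], genes=[ga, gb])
    genome.validate()
    # region inside both promoter windows
    both = ann.assign_genes(regions([("chr1", 100_500, 101_000)]), genome)
    assert sorted(both["gene_id"]) == ["ga", "gb"]
    assert (both["mode"] == "promoter_associated").all()
    # region 30 kb upstream of ga's TSS only -> enhancer for ga (and gb if in range)
    up = ann.assign_genes(regions([("chr1", 69_900, 70_000)]), genome)
    assert "ga" in set(up["gene_id"])
    assert (up["mode"] == "enhancer_associated").all()
    row = up[up["gene_id"] == "ga"].iloc[0]
    assert row["distance"] == -(100_000 - 69_999)
    # region beyond 50 kb of every TSS -> nothing
    far = ann.assign_genes(regions([("chr1", 350_000, 350_100)]), genome)
    assert far.empty


def test_enhancer_distance_boundary_50kb():
    g = plus_gene("g", tss=100_000, tes=104_999)
    genome = single_gene_genome(g)
    at_49999 = ann.assign_genes(regions([("chr1", 49_900, 50_002)]), genome)
    assert len(at_49999) == 1 and at_49999.iloc[0]["distance"] == -49_999
    at_50001 = ann.assign_genes(regions([("chr1", 49_900, 50_000)]), genome)
    assert at_50001.empty  # nearest edge is 50,001 bp upstream


def test_build_region_gene_sets_dedup_and_empty_warning():
    assignments = pd.DataFrame(
        {
            "region_id": ["r1", "r2", "r3", "r4"],
            "gene_id": ["A", "B", "B", "C"],
            "mode": ["promoter_associated"] * 4,
            "distance": [0, 0, 0, 0],
        }
    )
    calls = pd.Series({"r1": "up", "r2": "up", "r3": "up", "r4": "down"})
    name, members = ann.build_region_gene_sets(calls, assignments, "demo_up", call="up")
    assert (name, members) == ("demo_up", ["A", "B"])
    with pytest.warns(UserWarning, match="empty"):
        _, none = ann.build_region_gene_sets(
            pd.Series({"r1": "ns"}), assignments, "none_up", call="up"
        )
    assert none == []
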