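"""Prioritized genomic-context annotation and region-to-gene assignment.

Every region receives exactly one context label: the first class in a fixed
priority order whose strand-aware footprint overlaps it by at least 1 bp —
(1) Promoter.Up (2 kb upstream of a TSS), (2) Promoter.Down (2 kb downstream),
(3) Exons, (4) Introns, (5) TES (+/- 1 kb around transcription end sites),
(6) 5' Distal (up to 50 kb upstream of a TSS, promoter excluded),
(7) 3' Distal (up to 50 kb downstream, promoter excluded), (8) Intergenic.
All gene isoforms contribute footprints.

Gene assignment is two-stage: a region overlapping any gene's TSS +/- 2 kb
promoter window is promoter-associated with every such gene; only regions
with no promoter assignment at all are enhancer-associated with every gene
whose TSS lies within 50 kb of the nearest region edge. Distances are signed
by transcription direction (upstream negative).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .intervals import merge_intervals, overlaps_any

CONTEXT_ORDER = [
    "Promoter.Up",
    "Promoter.Down",
    "Exons",
    "Introns",
    "TES",
    "5' Distal",
    "3' Distal",
    "Intergenic",
]

PROMOTER_BP = 2_000
TES_BP = 1_000
DISTAL_BP = 50_000


def _clip(rows: list[tuple[str, int, int]], sizes: dict[str, int]) -> pd.DataFrame:
    out = []
    for chrom, s, e in rows:
        s, e = max(0, s), min(sizes[chrom], e)
        if s < e:
            out.append((chrom, s, e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def context_footprints(
    genome: GenomeModel, promoter_bp: int = PROMOTER_BP, tes_bp: int = TES_BP, distal_bp: int = DISTAL_BP
) -> dict[str, pd.DataFrame]:
    """Merged per-class footprints (Intergenic excluded — it is the
    fall-through). Half-open windows of exactly ``promoter_bp`` bases per
    promoter side, strand-aware; the TES window is +/- ``tes_bp`` around the
    transcription end position."""
    sizes = genome.chrom_sizes
    rows: dict[str, list[tuple[str, int, int]]] = {c: [] for c in CONTEXT_ORDER[:-1]}
    for g in genome.genes:
        t = g.tss
        if g.strand == "+":
            rows["Promoter.Up"].append((g.chrom, t - promoter_bp, t))
            rows["Promoter.Down"].append((g.chrom, t, t + promoter_bp))
            rows["5' Distal"].append((g.chrom, t - distal_bp, t - promoter_bp))
            rows["3' Distal"].append((g.chrom, t + promoter_bp, t + distal_bp))
        else:
            rows["Promoter.Up"].append((g.chrom, t + 1, t + 1 + promoter_bp))
            rows["Promoter.Down"].append((g.chrom, t + 1 - promoter_bp, t + 1))
            rows["5' Distal"].append((g.chrom, t + 1 + promoter_bp, t + 1 + distal_bp))
            rows["3' Distal"].append((g.chrom, t + 1 - distal_bp, t + 1 - promoter_bp))
        for s, e in g.exons:
            rows["Exons"].append((g.chrom, s, e))
        exons = sorted(g.exons)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 > e0:
                rows["Introns"].append((g.chrom, e0, s1))
        rows["TES"].append((g.chrom, g.tes - tes_bp, g.tes + tes_bp))
    return {c: merge_intervals(_clip(r, sizes)) for c, r in rows.items()}


def assign_context(regions: pd.DataFrame, genome: GenomeModel, **footprint_kwargs) -> pd.Series:
    """One prioritized context label per region."""
    fps = context_footprints(genome, **footprint_kwargs)
    labels = pd.Series("Intergenic", index=regions.index, name="context")
    unassigned = np.ones(len(regions), dtype=bool)
    for cls in CONTEXT_ORDER[:-1]:
        fp = fps[cls]
        if len(fp) == 0:
            continue
        hits = overlaps_any(regions, fp)
        take = unassigned & hits
        labels.iloc[np.flatnonzero(take)] = cls
        unassigned &= ~hits
    return labels


def _tss_distance(start: int, end: int, gene) -> int:
    """Signed nearest-edge distance from region [start, end) to the TSS;
    0 when the region covers the TSS, negative upstream of it."""
    t = gene.tss
    if start <= t < end:
        return 0
    dist = (start - t) if start > t else (t - (end - 1))
    genomic_left = end - 1 < t  # region entirely left of the TSS
    upstream = genomic_left if gene.strand == "+" else not genomic_left
    return -dist if upstream else dist


def assign_genes(
    regions: pd.DataFrame,
    genome: GenomeModel,
    promoter_bp: int = PROMOTER_BP,
    distal_bp: int = DISTAL_BP,
) -> pd.DataFrame:
    """Two-stage promoter/enhancer gene assignment.

    Returns one row per (region, gene) pair: region_id, gene_id, mode
    (promoter_associated | enhancer_associated), distance (signed bp to TSS).
    Regions beyond ``distal_bp`` of every TSS get no rows.
    """
    rows = []
    genes_by_chrom: dict[str, list] = {}
    for g in genome.genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for idx, region in zip(regions.index, regions.itertuples(index=False)):
        rid = f"{region.chrom}:{region.start}-{region.end}"
        promoter_hits = []
        enhancer_hits = []
        for g in genes_by_chrom.get(region.chrom, []):
            t = g.tss
            if g.strand == "+":
                ps, pe = t - promoter_bp, t + promoter_bp
            else:
                ps, pe = t + 1 - promoter_bp, t + 1 + promoter_bp
            if region.start < pe and region.end > ps:
                promoter_hits.append((g, _tss_distance(region.start, region.end, g)))
            else:
                d = _tss_distance(region.start, region.end, g)
                if abs(d) <= distal_bp:
                    enhancer_hits.append((g, d))
        hits = (
            [(g, d, "promoter_associated") for g, d in promoter_hits]
            if promoter_hits
            else [(g, d, "enhancer_associated") for g, d in enhancer_hits]
        )
        for g, d, mode in hits:
            rows.append((idx, rid, g.gene_id, mode, d))
    return pd.DataFrame(rows, columns=["region_index", "region_id", "gene_id", "mode", "distance"])


def build_region_gene_sets(
    calls: pd.Series, assignments: pd.DataFrame, set_name: str, call: str = "up"
) -> tuple[str, list[str]]:
    """Unique genes assigned (either mode) to regions carrying the given
    call; the result is a GMT-ready (name, members) pair."""
    wanted = set(calls.index[calls == call])
    members = sorted(
        assignments.loc[assignments["region_id"].isin(wanted), "gene_id"].unique()
    )
    if not members:
        warnings.warn(f"gene set {set_name!r} is empty (no regions called {call!r})", stacklevel=2)
    return set_name, members
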