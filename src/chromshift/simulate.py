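"""Synthetic ChIP-seq / RNA-seq fixtures with recorded ground truth.

The generator emulates the statistical structure the analysis assumes:
planted enrichment regions over a uniform background, a genome-wide
multiplicative shift applied to a chosen fraction of peaks in one condition,
negative-binomial replicate variability, a small gene annotation, and RNA
count matrices whose true effects in two perturbations are correlated by
construction.

Fragment model: background fragment starts arrive at a uniform per-base rate
``background_rate * library_size / genome_length``; inside a planted peak the
rate is multiplied by that peak's condition-specific enrichment. Per-region
fragment counts are drawn negative-binomial (gamma-Poisson) with a common
dispersion, starts uniform within the region, fragment length fixed. A
sample's total fragment count therefore exceeds ``library_size`` by the
library-composition factor, exactly as extra occupancy adds fragments to a
real library.

Randomness: one generator per sample, seeded by (seed, sample index); regions
are consumed in canonical (chrom, start) order, so outputs are reproducible
across platforms and re-orderings of the design table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeModel, read_gene_models, write_chrom_sizes, write_gene_models
from .tracks import FragmentSet, read_bed, write_bed

DEFAULT_CONDITIONS = ("WT", "KO")


@dataclass
class SimTruth:
    """Ground truth for a planted-peak ChIP fixture."""

    planted_peaks: pd.DataFrame  # chrom,start,end,shifted + mult_<condition> columns
    conditions: tuple[str, str]
    global_shift: float
    shift_fraction: float
    background_rate: float = 1.0
    dispersion: float = 0.05
    fragment_length: int = 200
    read_length: int = 50
    seed: int = 0

    def multipliers(self, condition: str) -> np.ndarray:
        return self.planted_peaks[f"mult_{condition}"].to_numpy()

    def regions(self) -> pd.DataFrame:
        return self.planted_peaks[["chrom", "start", "end"]].copy()

    def to_dict(self) -> dict:
        return {
            "planted_peaks": self.planted_peaks.to_dict(orient="list"),
            "conditions": list(self.conditions),
            "global_shift": self.global_shift,
            "shift_fraction": self.shift_fraction,
            "background_rate": self.background_rate,
            "dispersion": self.dispersion,
            "fragment_length": self.fragment_length,
            "read_length": self.read_length,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        d["planted_peaks"] = pd.DataFrame(d["planted_peaks"])
        d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass
class RnaTruth:
    """Ground truth for a two-perturbation RNA fixture."""

    effects: pd.DataFrame  # gene_id, lfc_<pert1>, lfc_<pert2>, shared, baseline_mean
    reference: str
    perturbations: tuple[str, str]
    rho_true: float
    dispersion: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "effects": self.effects.to_dict(orient="list"),
            "reference": self.reference,
            "perturbations": list(self.perturbations),
            "rho_true": self.rho_true,
            "dispersion": self.dispersion,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RnaTruth":
        d = dict(d)
        d["effects"] = pd.DataFrame(d["effects"])
        d["perturbations"] = tuple(d["perturbations"])
        return cls(**d)


# ---------------------------------------------------------------------------
# placement helpers


def _place_nonoverlapping(
    rng: np.random.Generator, chrom_length: int, n: int, width: int, min_gap: int
) -> np.ndarray:
    """Random non-overlapping placement by the spacing method: distribute the
    free slack uniformly among n blocks of (width + min_gap)."""
    need = n * (width + min_gap)
    if need > chrom_length:
        raise ValueError(
            f"cannot place {n} blocks of {width} bp (gap {min_gap}) on {chrom_length} bp"
        )
    slack = chrom_length - need
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    return offsets + np.arange(n) * (width + min_gap) + min_gap // 2


def _split_counts(rng: np.random.Generator, lengths: list[int], n: int) -> list[int]:
    """Apportion n items across chromosomes proportionally to length."""
    total = sum(lengths)
    raw = [n * l / total for l in lengths]
    counts = [int(np.floor(r)) for r in raw]
    rema = n - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for r in raw])
    for i in range(rema):
        counts[order[i]] += 1
    return counts


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    n_chroms: int = 2,
    chrom_length: int = 2_000_000,
    n_genes: int = 50,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (600, 3000),
    max_exons: int = 4,
) -> GenomeModel:
    """Random gene models on ``n_chroms`` chromosomes; gene bodies do not
    overlap, each gene has >= 1 exon, strands alternate randomly."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chromosomes = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chroms)]
    genes: list[GeneModel] = []
    if n_genes > 0:
        lmin, lmax = gene_length_range
        counts = _split_counts(rng, [chrom_length] * n_chroms, n_genes)
        gid = 0
        for (chrom, size), cnt in zip(chromosomes, counts):
            if cnt == 0:
                continue
            starts = _place_nonoverlapping(rng, size, cnt, lmax, min_gap=500)
            for s in starts:
                body = int(rng.integers(lmin, lmax + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                gstart, gend = int(s), int(s) + body  # body is [gstart, gend)
                n_ex = int(rng.integers(1, max_exons + 1))
                # split the body into 2*n_ex-1 alternating exon/intron blocks
                cuts = np.sort(rng.choice(np.arange(1, body), size=2 * n_ex - 2, replace=False)) if n_ex > 1 else np.array([], dtype=int)
                bounds = np.concatenate(([0], cuts, [body]))
                exons = [
                    (gstart + int(bounds[k]), gstart + int(bounds[k + 1]))
                    for k in range(0, len(bounds) - 1, 2)
                ]
                tss, tes = (gstart, gend - 1) if strand == "+" else (gend - 1, gstart)
                genes.append(
                    GeneModel(
                        gene_id=f"gene{gid:04d}",
                        chrom=chrom,
                        strand=strand,
                        tss=tss,
                        tes=tes,
                        exons=exons,
                    )
                )
                gid += 1
    genome = GenomeModel(chromosomes=chromosomes, genes=genes)
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# planted peaks


def plant_peaks(
    genome: GenomeModel,
    n_peaks: int = 2000,
    enrichment_range: tuple[float, float] = (2.0, 4.0),
    shift_fold: float = 1.0,
    shift_fraction: float = 0.0,
    peak_width: int = 400,
    min_gap: int = 400,
    background_rate: float = 1.0,
    dispersion: float = 0.05,
    fragment_length: int = 200,
    read_length: int = 50,
    seed: int = 0,
    conditions: tuple[str, str] = DEFAULT_CONDITIONS,
) -> SimTruth:
    """Plant non-overlapping enrichment regions; ``round(shift_fraction *
    n_peaks)`` of them carry ``mult_B = mult_A * shift_fold`` (a genome-wide
    gain for shift_fold > 1, loss for < 1); the rest are condition-balanced.
    """
    if not 0.0 <= shift_fraction <= 1.0:
        raise ValueError("shift_fraction must be in [0, 1]")
    if shift_fold <= 0:
        raise ValueError("shift_fold must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lengths = [size for _, size in genome.chromosomes]
    counts = _split_counts(rng, lengths, n_peaks)
    rows = []
    for (chrom, size), cnt in zip(genome.chromosomes, counts):
        if cnt == 0:
            continue
        starts = _place_nonoverlapping(rng, size, cnt, peak_width, min_gap)
        for s in starts:
            rows.append((chrom, int(s), int(s) + peak_width))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    lo, hi = enrichment_range
    mult_a = rng.uniform(lo, hi, size=len(peaks))
    n_shift = int(round(shift_fraction * n_peaks))
    shifted = np.zeros(len(peaks), dtype=bool)
    shifted[rng.choice(len(peaks), size=n_shift, replace=False)] = True
    mult_b = np.where(shifted, mult_a * shift_fold, mult_a)
    ca, cb = conditions
    peaks["shifted"] = shifted
    peaks[f"mult_{ca}"] = mult_a
    peaks[f"mult_{cb}"] = mult_b
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    return SimTruth(
        planted_peaks=peaks,
        conditions=conditions,
        global_shift=float(shift_fold),
        shift_fraction=float(shift_fraction),
        background_rate=background_rate,
        dispersion=dispersion,
        fragment_length=fragment_length,
        read_length=read_length,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fragments


def _region_table(truth: SimTruth, genome: GenomeModel, condition: str) -> pd.DataFrame:
    """Tile each chromosome into planted peaks and the background segments
    between them, with per-region enrichment multipliers."""
    rows = []
    peaks = truth.planted_peaks
    for chrom, size in genome.chromosomes:
        sub = peaks[peaks["chrom"] == chrom].sort_values("start")
        pos = 0
        for row in sub.itertuples(index=False):
            if row.start > pos:
                rows.append((chrom, pos, row.start, 1.0))
            rows.append((chrom, row.start, row.end, float(getattr(row, f"mult_{condition}"))))
            pos = row.end
        if pos < size:
            rows.append((chrom, pos, size, 1.0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mult"])


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_fragments(
    truth: SimTruth,
    genome: GenomeModel,
    design: list[tuple[str, str, int]],
    seed: int = 0,
) -> tuple[dict[str, FragmentSet], dict[str, FragmentSet]]:
    """Simulate per-sample fragment sets and matching stranded single-end
    reads for a design of (sample, condition, library_size) rows.

    Returns (fragments_by_sample, reads_by_sample). Each fragment yields one
    read of ``truth.read_length`` on a random strand anchored at the
    fragment's corresponding 5' end, so plus/minus 5' profiles are separated
    by the fragment length for cross-correlation tests.
    """
    genome_length = genome.length
    frags: dict[str, FragmentSet] = {}
    reads: dict[str, FragmentSet] = {}
    sizes = genome.chrom_sizes
    for idx, (sample, condition, library_size) in enumerate(design):
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        if condition not in truth.conditions:
            raise ValueError(f"condition {condition!r} not present in truth")
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))
        regions = _region_table(truth, genome, condition)
        rate = truth.background_rate * library_size / genome_length
        mean = rate * (regions["end"] - regions["start"]).to_numpy() * regions["mult"].to_numpy()
        counts = _nb_counts(rng, mean, truth.dispersion)
        chroms_out, starts_out = [], []
        for (row, cnt) in zip(regions.itertuples(index=False), counts):
            if cnt == 0:
                continue
            starts = rng.integers(row.start, row.end, size=cnt)
            chroms_out.append(np.full(cnt, row.chrom, dtype=object))
            starts_out.append(starts)
        chrom_arr = np.concatenate(chroms_out) if chroms_out else np.array([], dtype=object)
        start_arr = np.concatenate(starts_out) if starts_out else np.array([], dtype=int)
        size_arr = pd.Series(chrom_arr).map(sizes).to_numpy(dtype=int) if len(chrom_arr) else np.array([], dtype=int)
        end_arr = np.minimum(start_arr + truth.fragment_length, size_arr)
        strand = np.where(rng.random(len(start_arr)) < 0.5, "+", "-")
        fdf = pd.DataFrame(
            {"chrom": chrom_arr, "start": start_arr, "end": end_arr, "strand": strand}
        )
        frags[sample] = FragmentSet(sample=sample, condition=condition, intervals=fdf)
        plus = strand == "+"
        rstart = np.where(plus, start_arr, np.maximum(end_arr - truth.read_length, 0))
        rend = np.where(plus, np.minimum(start_arr + truth.read_length, size_arr), end_arr)
        rdf = pd.DataFrame({"chrom": chrom_arr, "start": rstart, "end": rend, "strand": strand})
        reads[sample] = FragmentSet(sample=sample, condition=condition, intervals=rdf)
    return frags, reads


# ---------------------------------------------------------------------------
# RNA counts


def simulate_rna_counts(
    genome: GenomeModel,
    n_shared_targets: int,
    rho_true: float,
    design: list[tuple[str, str]],
    seed: int = 0,
    reference: str = "WT",
    effect_sd: float = 1.5,
    baseline_log_mean: float = np.log(100.0),
    baseline_log_sd: float = 1.0,
    dispersion: float = 0.05,
):
    """Gene-by-sample NB counts for a reference condition and exactly two
    perturbations whose true log2 fold changes over ``n_shared_targets``
    shared target genes are bivariate-normal with correlation ``rho_true``.
    Non-target genes are unchanged in both perturbations.
    """
    from .chipnorm import CountMatrix  # local import to avoid a cycle

    if not -1.0 <= rho_true <= 1.0:
        raise ValueError("rho_true must be in [-1, 1]")
    genes = [g.gene_id for g in genome.genes]
    if n_shared_targets > len(genes):
        raise ValueError("n_shared_targets exceeds number of genes")
    conditions = [c for _, c in design]
    perturbations = tuple(sorted(set(conditions) - {reference}))
    if len(perturbations) != 2:
        raise ValueError("design must contain the reference and exactly two perturbations")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(genes)
    shared_idx = rng.choice(n, size=n_shared_targets, replace=False)
    shared = np.zeros(n, dtype=bool)
    shared[shared_idx] = True
    x = rng.normal(0.0, 1.0, size=n_shared_targets)
    z = rng.normal(0.0, 1.0, size=n_shared_targets)
    y = rho_true * x + np.sqrt(max(0.0, 1.0 - rho_true**2)) * z
    lfc_a = np.zeros(n)
    lfc_b = np.zeros(n)
    lfc_a[shared] = effect_sd * x
    lfc_b[shared] = effect_sd * y
    baseline = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n)
    pa, pb = perturbations
    effects = pd.DataFrame(
        {
            "gene_id": genes,
            f"lfc_{pa}": lfc_a,
            f"lfc_{pb}": lfc_b,
            "shared": shared,
            "baseline_mean": baseline,
        }
    )
    lfc_by_cond = {reference: np.zeros(n), pa: lfc_a, pb: lfc_b}
    counts = {}
    for sidx, (sample, condition) in enumerate(design):
        srng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1000 + sidx,)))
        mean = baseline * np.power(2.0, lfc_by_cond[condition])
        counts[sample] = _nb_counts(srng, mean, dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    lengths = pd.Series(
        {g.gene_id: sum(e - s for s, e in g.exons) for g in genome.genes}, name="length"
    )
    cm = CountMatrix(
        counts=counts_df,
        lengths=lengths.loc[genes],
        library_sizes=counts_df.sum(axis=0).astype(int),
        conditions=pd.Series(dict(design)),
    )
    truth = RnaTruth(
        effects=effects,
        reference=reference,
        perturbations=perturbations,
        rho_true=float(rho_true),
        dispersion=dispersion,
        seed=seed,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    directory,
    genome: GenomeModel,
    truth: SimTruth | None = None,
    fragments: dict[str, FragmentSet] | None = None,
    reads: dict[str, FragmentSet] | None = None,
    rna=None,  # (CountMatrix, RnaTruth)
    params: dict | None = None,
) -> dict:
    """Serialize a fixture to plain-text files plus a JSON manifest.

    Returns the manifest dict. ``params`` should hold every generator
    argument needed to regenerate the fixture from scratch.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"params": params or {}, "files": {}}
        write_chrom_sizes(genome, directory / "chrom.sizes")
        write_gene_models(genome, directory / "genes.tsv")
        manifest["files"]["chrom_sizes"] = "chrom.sizes"
        manifest["files"]["genes"] = "genes.tsv"
        if truth is not None:
            (directory / "chip_truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
            manifest["files"]["chip_truth"] = "chip_truth.json"
        if fragments:
            (directory / "fragments").mkdir(exist_ok=True)
            manifest["files"]["fragments"] = {}
            manifest["conditions"] = {}
            for sample, fs in sorted(fragments.items()):
                rel = f"fragments/{sample}.bed"
                write_bed(fs, directory / rel)
                manifest["files"]["fragments"][sample] = rel
                manifest["conditions"][sample] = fs.condition
        if reads:
            (directory / "reads").mkdir(exist_ok=True)
            manifest["files"]["reads"] = {}
            for sample, fs in sorted(reads.items()):
                rel = f"reads/{sample}.bed"
                write_bed(fs, directory / rel)
                manifest["files"]["reads"][sample] = rel
        if rna is not None:
            cm, rtruth = rna
            cm.to_tsv(directory / "rna_counts.tsv", directory / "rna_samples.json")
            (directory / "rna_truth.json").write_text(json.dumps(rtruth.to_dict(), indent=1))
            manifest["files"]["rna_counts"] = "rna_counts.tsv"
            manifest["files"]["rna_samples"] = "rna_samples.json"
            manifest["files"]["rna_truth"] = "rna_truth.json"
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except OSError as exc:
        raise OSError(f"cannot write fixture under {directory}: {exc}") from exc
    return manifest


def read_fixture(directory):
    """Load a fixture written by :func:`write_fixture`. Returns a dict with
    keys genome, truth, fragments, reads, rna (present when on disk)."""
    from .chipnorm import CountMatrix

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    files = manifest["files"]
    chromosomes = []
    with open(directory / files["chrom_sizes"]) as fh:
        for line in fh:
            name, size = line.split()
            chromosomes.append((name, int(size)))
    genome = read_gene_models(directory / files["genes"], chromosomes)
    out = {"genome": genome, "manifest": manifest}
    if "chip_truth" in files:
        out["truth"] = SimTruth.from_dict(json.loads((directory / files["chip_truth"]).read_text()))
    for key in ("fragments", "reads"):
        if key in files:
            conditions = manifest.get("conditions", {})
            out[key] = {
                sample: read_bed(directory / rel, sample=sample, condition=conditions.get(sample, ""))
                for sample, rel in files[key].items()
            }
    if "rna_counts" in files:
        cm = CountMatrix.from_tsv(directory / files["rna_counts"], directory / files["rna_samples"])
        rtruth = RnaTruth.from_dict(json.loads((directory / files["rna_truth"]).read_text()))
        out["rna"] = (cm, rtruth)
    return out
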