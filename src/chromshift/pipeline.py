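"""End-to-end orchestration: simulate -> tracks -> peaks -> normalize ->
test -> annotate -> enrich -> integrate.

The pipeline is configured by a single declarative mapping (YAML on disk).
Contrasts must state ``expected_global_change`` explicitly — it selects
pseudo-spike versus TMM normalization and there is deliberately no heuristic.
All randomness derives from one seed, so two runs with the same config
produce byte-identical output tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import annotate as ann
from . import chipnorm, diffstats, enrich, peakcall, simulate, tracks
from .genome import GenomeModel

log = logging.getLogger("chromshift")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {
        "n_chroms": 2,
        "chrom_length": 2_000_000,
        "n_genes": 800,
        "gene_length_range": [600, 1500],
    },
    "chip": {
        "n_peaks": 2000,
        "peak_width": 400,
        "enrichment_range": [2.0, 4.0],
        "shift_fold": 4.0,
        "shift_fraction": 0.9,
        "conditions": ["WT", "KO"],
        "replicates": 2,
        "library_size": 400_000,
        "dispersion": 0.05,
        "fragment_length": 200,
        "read_length": 50,
    },
    "chip_contrasts": [
        {
            "name": "chip_KO_vs_WT",
            "reference": "WT",
            "test": "KO",
            "expected_global_change": True,
            "replicated": True,
            "use_planted_reference": True,
        }
    ],
    "rna": {
        "n_shared_targets": 500,
        "rho_true": -0.6,
        "reference": "WT",
        "perturbations": ["KO_A", "KO_B"],
        "replicates": 2,
        "dispersion": 0.05,
        "effect_sd": 1.5,
    },
    "integration": {"gene_filter": "union_of_DE"},
    "gsea": {"n_perm": 500, "min_size": 5, "max_size": 5000},
    "thresholds": {"q_max": 0.05, "lfc_min": 1.0, "p_max": 0.05},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


# ---------------------------------------------------------------------------
# fixture construction


@dataclass
class ChipFixture:
    genome: GenomeModel
    truth: simulate.SimTruth
    fragments: dict[str, tracks.FragmentSet]
    reads: dict[str, tracks.FragmentSet]
    design: list[tuple[str, str, int]]


def build_chip_fixture(config: dict, seed: int) -> ChipFixture:
    g = config["genome"]
    c = config["chip"]
    genome = simulate.simulate_genome(
        n_chroms=g["n_chroms"],
        chrom_length=g["chrom_length"],
        n_genes=g["n_genes"],
        gene_length_range=tuple(g.get("gene_length_range", (600, 3000))),
        seed=seed,
    )
    truth = simulate.plant_peaks(
        genome,
        n_peaks=c["n_peaks"],
        enrichment_range=tuple(c["enrichment_range"]),
        shift_fold=c["shift_fold"],
        shift_fraction=c["shift_fraction"],
        peak_width=c["peak_width"],
        dispersion=c["dispersion"],
        fragment_length=c["fragment_length"],
        read_length=c["read_length"],
        seed=seed + 1,
        conditions=tuple(c["conditions"]),
    )
    design = [
        (f"{cond}_r{r + 1}", cond, int(c["library_size"]))
        for cond in c["conditions"]
        for r in range(c["replicates"])
    ]
    frags, reads = simulate.simulate_fragments(truth, genome, design, seed=seed + 2)
    return ChipFixture(genome=genome, truth=truth, fragments=frags, reads=reads, design=design)


def build_rna_fixture(config: dict, genome: GenomeModel, seed: int):
    r = config["rna"]
    design = [
        (f"{cond}_r{k + 1}", cond)
        for cond in [r["reference"], *r["perturbations"]]
        for k in range(r["replicates"])
    ]
    return simulate.simulate_rna_counts(
        genome,
        n_shared_targets=r["n_shared_targets"],
        rho_true=r["rho_true"],
        design=design,
        seed=seed + 3,
        reference=r["reference"],
        effect_sd=r["effect_sd"],
        dispersion=r["dispersion"],
    )


# ---------------------------------------------------------------------------
# ChIP contrast


@dataclass
class ChipContrastResult:
    name: str
    reference_peaks: pd.DataFrame
    counts: chipnorm.CountMatrix
    norm: chipnorm.NormFactors
    table: pd.DataFrame  # per-peak stats incl. call
    signal: pd.DataFrame  # per-peak mean normalized signal per sample
    wilcoxon: tuple[float, float]
    annotation: pd.DataFrame | None = None
    context: pd.Series | None = None
    gene_sets: dict[str, list[str]] = field(default_factory=dict)


def consensus_reference_peaks(
    fragments: dict[str, tracks.FragmentSet],
    chrom_sizes: dict[str, int],
    target: str = "chip",
    **caller_kwargs,
) -> pd.DataFrame:
    """Caller -> FDR50 per replicate -> all-replicate consensus per condition
    (high-confidence passthrough for single replicates) -> per-target union."""
    by_condition: dict[str, list[peakcall.PeakSet]] = {}
    for sample, fs in sorted(fragments.items()):
        scored = peakcall.call_peaks(fs, chrom_sizes, target=target, **caller_kwargs)
        by_condition.setdefault(fs.condition, []).append(scored)
    reproducible = []
    for cond, scored_sets in sorted(by_condition.items()):
        if len(scored_sets) == 1:
            log.info("consensus %s/%s: single replicate, high-confidence passthrough", target, cond)
            rep = peakcall.singleton_peaks(peakcall.threshold_peaks(scored_sets[0], 0.05))
        else:
            fdr50 = [peakcall.threshold_peaks(ps, 0.5) for ps in scored_sets]
            rep = peakcall.reproducible_peaks(fdr50)
        log.info("consensus %s/%s: %d reproducible regions", target, cond, len(rep))
        reproducible.append(rep)
    return peakcall.merge_reference_peaks(reproducible)


def run_chip_contrast(
    fixture: ChipFixture,
    contrast: dict,
    thresholds: dict | None = None,
    reference_peaks: pd.DataFrame | None = None,
    pseudo_spike_constant: float = 1e6,
    invert_pseudo_factors: bool = True,
    annotate_regions: bool = True,
) -> ChipContrastResult:
    """One differential-binding contrast, end to end."""
    th = {**DEFAULT_CONFIG["thresholds"], **(thresholds or {})}
    chrom_sizes = fixture.genome.chrom_sizes
    method = chipnorm.select_normalization(contrast.get("expected_global_change"))
    log.info("contrast %s: normalization=%s", contrast["name"], method)

    if reference_peaks is None:
        if contrast.get("use_planted_reference", False):
            reference_peaks = fixture.truth.regions()
        else:
            reference_peaks = consensus_reference_peaks(fixture.fragments, chrom_sizes)
    reference_peaks = reference_peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    log.info("contrast %s: %d reference peaks", contrast["name"], len(reference_peaks))

    samples = [
        s
        for s, fs in fixture.fragments.items()
        if fs.condition in (contrast["reference"], contrast["test"])
    ]
    frags = {s: fixture.fragments[s] for s in sorted(samples)}
    cm = chipnorm.count_fragments_in_peaks(frags, reference_peaks)

    cov = {
        s: tracks.build_coverage(fs, chrom_sizes, normalize_to=tracks.DEFAULT_NORMALIZE_TO)
        for s, fs in frags.items()
    }
    if method == "pseudo_spike":
        pseudo = pd.Series(
            {
                s: chipnorm.pseudo_spike_reads(cov[s], reference_peaks, pseudo_spike_constant)
                for s in frags
            }
        )
        norm = chipnorm.pseudo_spike_factors(
            pseudo, invert=invert_pseudo_factors, constant=pseudo_spike_constant
        )
    else:
        norm = diffstats.tmm_factors(cm)

    if contrast.get("replicated", True):
        design = diffstats.DesignMatrix.two_group(
            cm.conditions, contrast["reference"], contrast["test"]
        )
        logcpm, weights = diffstats.voom_weights(cm, norm, design)
        fit = diffstats.fit_moderated(logcpm, weights, design)
        table = fit.table.copy()
        table["call"] = diffstats.classify_differential(
            table, mode="replicated", q_max=th["q_max"], lfc_min=th["lfc_min"]
        )
    else:
        table = diffstats.fc_only_log2fc(cm, contrast["reference"], contrast["test"], norm=norm)
        table["call"] = diffstats.classify_differential(
            table, mode="fc_only", lfc_min=th["lfc_min"]
        )

    signal = pd.DataFrame(
        {s: tracks.mean_signal_per_region(cov[s], reference_peaks) for s in frags},
        index=cm.counts.index,
    )
    cond = cm.conditions
    sig_ref = signal[[s for s in signal if cond[s] == contrast["reference"]]].mean(axis=1)
    sig_test = signal[[s for s in signal if cond[s] == contrast["test"]]].mean(axis=1)
    wilcoxon = diffstats.wilcoxon_rank_sum(sig_ref.to_numpy(), sig_test.to_numpy())

    annotation = context = None
    gene_sets: dict[str, list[str]] = {}
    if annotate_regions and fixture.genome.genes:
        context = ann.assign_context(reference_peaks, fixture.genome)
        context.index = cm.counts.index
        annotation = ann.assign_genes(reference_peaks, fixture.genome)
        calls = table["call"]
        for direction in ("up", "down"):
            name, members = ann.build_region_gene_sets(
                calls, annotation, f"{contrast['name']}_{direction}", call=direction
            )
            if members:
                gene_sets[name] = members
    return ChipContrastResult(
        name=contrast["name"],
        reference_peaks=reference_peaks,
        counts=cm,
        norm=norm,
        table=table,
        signal=signal,
        wilcoxon=wilcoxon,
        annotation=annotation,
        context=context,
        gene_sets=gene_sets,
    )


# ---------------------------------------------------------------------------
# RNA contrast and integration


def run_rna_contrast(
    cm: chipnorm.CountMatrix,
    reference: str,
    test: str,
    thresholds: dict | None = None,
    min_cpm: float = 1.0,
    min_samples: int = 2,
) -> pd.DataFrame:
    """TMM + precision-weighted moderated fit + volcano calls (raw p < p_max,
    |log2FC| > lfc_min). Genes below ``min_cpm`` CPM in fewer than
    ``min_samples`` samples are filtered before normalization."""
    th = {**DEFAULT_CONFIG["thresholds"], **(thresholds or {})}
    sub = cm.subset_samples([s for s, c in cm.conditions.items() if c in (reference, test)])
    cpm = sub.counts / sub.library_sizes.to_numpy() * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    sub = chipnorm.CountMatrix(
        counts=sub.counts[keep],
        lengths=sub.lengths[keep],
        library_sizes=sub.library_sizes,
        conditions=sub.conditions,
    )
    norm = diffstats.tmm_factors(sub)
    design = diffstats.DesignMatrix.two_group(sub.conditions, reference, test)
    logcpm, weights = diffstats.voom_weights(sub, norm, design)
    fit = diffstats.fit_moderated(logcpm, weights, design)
    table = fit.table.copy()
    table["call"] = diffstats.classify_differential(
        table, mode="volcano", p_max=th["p_max"], lfc_min=th["lfc_min"]
    )
    return table


@dataclass
class IntegrationResult:
    pairs: pd.DataFrame  # gene, log2FC_a, log2FC_b
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    quadrants: dict[str, int]


def integrate_contrasts(
    de_a: pd.DataFrame, de_b: pd.DataFrame, gene_filter: str = "all_expressed"
) -> IntegrationResult:
    """Paired fold changes of two contrasts over their shared gene universe,
    with correlation statistics and per-quadrant counts.

    gene_filter: 'all_expressed' keeps every shared gene; 'union_of_DE' keeps
    genes called differential (non-ns) in either contrast.
    """
    common = de_a.index.intersection(de_b.index)
    if len(common) == 0:
        raise ValueError("contrasts share no genes")
    pairs = pd.DataFrame(
        {"log2FC_a": de_a.loc[common, "log2FC"], "log2FC_b": de_b.loc[common, "log2FC"]}
    )
    if gene_filter == "union_of_DE":
        mask = (de_a.loc[common, "call"] != "ns") | (de_b.loc[common, "call"] != "ns")
        pairs = pairs[mask.to_numpy()]
    elif gene_filter != "all_expressed":
        raise ValueError(f"unknown gene_filter {gene_filter!r}")
    if len(pairs) < 3:
        raise ValueError("too few genes after filtering to correlate")
    pr = sps.pearsonr(pairs["log2FC_a"], pairs["log2FC_b"])
    sr = sps.spearmanr(pairs["log2FC_a"], pairs["log2FC_b"])
    a, b = pairs["log2FC_a"].to_numpy(), pairs["log2FC_b"].to_numpy()
    quadrants = {
        "up_up": int(((a > 0) & (b > 0)).sum()),
        "up_down": int(((a > 0) & (b <= 0)).sum()),
        "down_up": int(((a <= 0) & (b > 0)).sum()),
        "down_down": int(((a <= 0) & (b <= 0)).sum()),
    }
    return IntegrationResult(
        pairs=pairs,
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        quadrants=quadrants,
    )


# ---------------------------------------------------------------------------
# run-all


def run_all(config: dict | str | Path, outdir, seed: int | None = None) -> dict:
    """Full analysis on a simulated fixture; every table written under
    ``outdir`` with a manifest. Returns the in-memory results."""
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"] if seed is None else seed)
    manifest: dict = {"seed": seed, "config": config, "outputs": {}}

    def save(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", **kwargs)
        manifest["outputs"][name] = name

    fixture = build_chip_fixture(config, seed)
    log.info("fixture: %d genes, %d planted peaks", len(fixture.genome.genes), len(fixture.truth.planted_peaks))
    chip_results = {}
    all_gene_sets: dict[str, list[str]] = {}
    for contrast in config["chip_contrasts"]:
        res = run_chip_contrast(fixture, contrast, thresholds=config["thresholds"])
        chip_results[contrast["name"]] = res
        save(res.table, f"{contrast['name']}.calls.tsv")
        save(res.reference_peaks, f"{contrast['name']}.reference_peaks.bed", index=False, header=False)
        res.norm.to_tsv(outdir / f"{contrast['name']}.factors.tsv")
        manifest["outputs"][f"{contrast['name']}.factors.tsv"] = f"{contrast['name']}.factors.tsv"
        save(res.signal, f"{contrast['name']}.signal.tsv")
        if res.annotation is not None:
            save(res.annotation, f"{contrast['name']}.gene_assignments.tsv", index=False)
            save(res.context.to_frame(), f"{contrast['name']}.context.tsv")
        all_gene_sets.update(res.gene_sets)

    rna_results = {}
    integration = None
    gsea_table = None
    if config.get("rna"):
        rna_cm, rna_truth = build_rna_fixture(config, fixture.genome, seed)
        rcfg = config["rna"]
        for pert in rcfg["perturbations"]:
            table = run_rna_contrast(rna_cm, rcfg["reference"], pert, thresholds=config["thresholds"])
            rna_results[pert] = table
            save(table, f"rna_{pert}_vs_{rcfg['reference']}.de.tsv")
        pa, pb = rcfg["perturbations"]
        integration = integrate_contrasts(
            rna_results[pa], rna_results[pb], gene_filter=config["integration"]["gene_filter"]
        )
        save(integration.pairs, "integration.pairs.tsv")
        manifest["integration"] = {
            "pearson_r": integration.pearson_r,
            "pearson_p": integration.pearson_p,
            "spearman_r": integration.spearman_r,
            "spearman_p": integration.spearman_p,
            "quadrants": integration.quadrants,
            "rho_true": rna_truth.rho_true,
        }
        if all_gene_sets:
            enrich.write_gmt(all_gene_sets, outdir / "region_gene_sets.gmt")
            manifest["outputs"]["region_gene_sets.gmt"] = "region_gene_sets.gmt"
            ranked = enrich.rank_genes(rna_results[pa]["log2FC"])
            g = config["gsea"]
            usable = {
                n: m for n, m in all_gene_sets.items()
                if g["min_size"] <= len(set(m) & set(ranked.index)) <= g["max_size"]
            }
            if usable:
                gres = enrich.gsea_prerank(
                    ranked, usable, min_size=g["min_size"], max_size=g["max_size"],
                    n_perm=g["n_perm"], seed=seed + 4,
                )
                gsea_table = gres.table
                save(gsea_table, "gsea.tsv")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return {
        "fixture": fixture,
        "chip": chip_results,
        "rna": rna_results,
        "integration": integration,
        "gsea": gsea_table,
    }
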