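"""Simplified narrow peak calling and cross-replicate consensus.

The caller is a windowed local-Poisson scan: fixed-width windows slide along
each chromosome, the fragment count in each window is tested one-sided
against the largest of the genome-wide rate, 1 kb / 10 kb local flank rates
and (when given) a depth-scaled control rate, and window p-values are BH
adjusted. Windows significant at the relaxed candidate threshold are merged
into peaks so that calls at a stricter q are always a subset of calls at a
looser one. This is a deliberately simple stand-in for an external
narrow-mode caller; externally produced narrowPeak files can be imported
instead.

Consensus: peaks called at q <= 0.5 ("FDR50") in every replicate of a
condition define its reproducible peaks; the per-target union of reproducible
peaks across conditions is the reference peak set used for counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust
from .intervals import merge_intervals, overlaps_any
from .tracks import FragmentSet, build_coverage

PEAK_COLS = ["chrom", "start", "end", "summit", "fold_enrichment", "p", "q"]


@dataclass
class PeakSet:
    target: str
    sample: str
    threshold_class: str  # "scored" | "high_confidence" | "FDR50"
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PEAK_COLS))

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> pd.DataFrame:
        return self.peaks[["chrom", "start", "end"]].copy()


def _window_counts(starts: np.ndarray, ends: np.ndarray, ws: np.ndarray, we: np.ndarray) -> np.ndarray:
    """Fragments overlapping [ws, we) by >= 1 bp, from sorted start/end arrays."""
    return np.searchsorted(starts, we, side="left") - np.searchsorted(ends, ws, side="right")


def call_peaks(
    treatment: FragmentSet,
    chrom_sizes: dict[str, int],
    control: FragmentSet | None = None,
    window: int = 200,
    step: int = 50,
    local_flanks: tuple[int, ...] = (1_000, 10_000),
    merge_gap: int = 100,
    candidate_q: float = 0.5,
    target: str = "",
) -> PeakSet:
    """Scored candidate peaks (merged at the relaxed candidate threshold so
    both the high-confidence and FDR50 sets are derivable by filtering)."""
    if treatment.n == 0:
        raise ValueError("treatment fragment set is empty")
    genome_length = sum(chrom_sizes.values())
    if window > min(chrom_sizes.values()):
        raise ValueError("window larger than a chromosome")
    frag_len = float((treatment.intervals["end"] - treatment.intervals["start"]).mean())
    lam_genome = treatment.n * (window + frag_len) / (genome_length + frag_len)
    if control is not None and control.n == 0:
        control = None
    depth_ratio = treatment.n / control.n if control is not None else None

    win_rows = []
    by_chrom_t: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_chrom_c: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for src, store in ((treatment, by_chrom_t), (control, by_chrom_c)):
        if src is None:
            continue
        for chrom, sub in src.intervals.groupby("chrom"):
            store[chrom] = (np.sort(sub["start"].to_numpy()), np.sort(sub["end"].to_numpy()))
    for chrom, size in sorted(chrom_sizes.items()):
        if size < window:
            continue
        ws = np.arange(0, size - window + 1, step)
        we = ws + window
        ts, te = by_chrom_t.get(chrom, (np.array([]), np.array([])))
        counts = _window_counts(ts, te, ws, we)
        center = ws + window // 2
        lam = np.full(len(ws), lam_genome)
        for flank in local_flanks:
            fs = np.maximum(center - flank // 2, 0)
            fe = np.minimum(center + flank // 2, size)
            fcount = _window_counts(ts, te, fs, fe)
            lam_f = fcount * (window + frag_len) / ((fe - fs) + frag_len)
            lam = np.maximum(lam, lam_f)
        if control is not None:
            cs, ce = by_chrom_c.get(chrom, (np.array([]), np.array([])))
            cfl = float((control.intervals["end"] - control.intervals["start"]).mean())
            for flank in (window,) + tuple(local_flanks):
                fs = np.maximum(center - flank // 2, 0)
                fe = np.minimum(center + flank // 2, size)
                ccount = _window_counts(cs, ce, fs, fe)
                lam_c = ccount * (window + cfl) / ((fe - fs) + cfl) * depth_ratio
                lam = np.maximum(lam, lam_c)
        win_rows.append(pd.DataFrame({"chrom": chrom, "start": ws, "end": we, "count": counts, "lam": lam}))
    windows = pd.concat(win_rows, ignore_index=True)
    windows["p"] = stats.poisson.sf(windows["count"] - 1, windows["lam"])
    windows["q"] = bh_adjust(windows["p"].to_numpy())

    cand = windows[windows["q"] <= candidate_q]
    peaks = []
    if len(cand):
        cov = build_coverage(treatment, chrom_sizes, normalize_to=None)
        for chrom, sub in cand.groupby("chrom"):
            sub = sub.sort_values("start")
            merged = merge_intervals(sub[["chrom", "start", "end"]], gap=merge_gap)
            for region in merged.itertuples(index=False):
                member = sub[(sub["start"] < region.end) & (sub["end"] > region.start)]
                best = member.loc[member["p"].idxmin()]
                arr = cov.values[chrom][region.start : region.end]
                summit = int(region.start + np.argmax(arr))
                fold = float(best["count"] / best["lam"]) if best["lam"] > 0 else np.inf
                peaks.append(
                    (chrom, int(region.start), int(region.end), summit, fold, float(best["p"]), float(best["q"]))
                )
    df = pd.DataFrame(peaks, columns=PEAK_COLS).sort_values(["chrom", "start"]).reset_index(drop=True)
    return PeakSet(target=target, sample=treatment.sample, threshold_class="scored", peaks=df)


def threshold_peaks(peakset: PeakSet, q_max: float) -> PeakSet:
    """Filter scored peaks at q <= q_max (0.05 labels the set high-confidence,
    0.5 labels it FDR50)."""
    if not 0.0 < q_max <= 1.0:
        raise ValueError("q_max must be in (0, 1]")
    label = {0.05: "high_confidence", 0.5: "FDR50"}.get(q_max, f"q<={q_max:g}")
    df = peakset.peaks[peakset.peaks["q"] <= q_max].reset_index(drop=True)
    return PeakSet(target=peakset.target, sample=peakset.sample, threshold_class=label, peaks=df)


def reproducible_peaks(fdr50_sets: list[PeakSet]) -> PeakSet:
    """Regions covered by FDR50 peaks in *all* replicates.

    The union of all replicates' peaks is merged (gap 0); a union region is
    kept iff every replicate contributes at least one peak to it, and the
    region's full merged span is reported. Chained overlaps therefore qualify
    transitively. An empty replicate yields an empty (valid) result.
    """
    if not fdr50_sets:
        raise ValueError("no replicates supplied")
    target = fdr50_sets[0].target
    sample = "+".join(ps.sample for ps in fdr50_sets)
    if any(len(ps) == 0 for ps in fdr50_sets):
        return PeakSet(target=target, sample=sample, threshold_class="reproducible",
                       peaks=pd.DataFrame(columns=PEAK_COLS))
    union = merge_intervals(pd.concat([ps.intervals() for ps in fdr50_sets], ignore_index=True), gap=0)
    keep = np.ones(len(union), dtype=bool)
    for ps in fdr50_sets:
        rep_merged = merge_intervals(ps.intervals(), gap=0)
        keep &= overlaps_any(union, rep_merged)
    df = union[keep].reset_index(drop=True)
    df = df.assign(summit=np.nan, fold_enrichment=np.nan, p=np.nan, q=np.nan)
    return PeakSet(target=target, sample=sample, threshold_class="reproducible", peaks=df)


def singleton_peaks(high_confidence_set: PeakSet) -> PeakSet:
    """No-replicate rule: the high-confidence (q <= 0.05) peaks stand in as
    the target's reproducible set."""
    df = high_confidence_set.peaks[high_confidence_set.peaks["q"] <= 0.05].reset_index(drop=True)
    return PeakSet(
        target=high_confidence_set.target,
        sample=high_confidence_set.sample,
        threshold_class="reproducible",
        peaks=df,
    )


def merge_reference_peaks(reproducible_sets: list[PeakSet]) -> pd.DataFrame:
    """Per-target union of reproducible peaks across conditions: overlapping
    or bookended intervals merged, sorted — the 'all reproducible peaks'
    counting universe."""
    targets = {ps.target for ps in reproducible_sets}
    if len(targets) > 1:
        raise ValueError(f"mixed targets in reference merge: {sorted(targets)}")
    all_peaks = pd.concat([ps.intervals() for ps in reproducible_sets], ignore_index=True)
    return merge_intervals(all_peaks, gap=0)


def overlap_peaks(a: pd.DataFrame, b: pd.DataFrame) -> tuple[int, int, int]:
    """Venn counts (a_only, overlap, b_only); overlap counted from a's side,
    >= 1 bp intersection. Both inputs must be internally merged."""
    a_hits = overlaps_any(a, merge_intervals(b)) if len(b) else np.zeros(len(a), dtype=bool)
    b_hits = overlaps_any(b, merge_intervals(a)) if len(a) else np.zeros(len(b), dtype=bool)
    return int((~a_hits).sum()), int(a_hits.sum()), int((~b_hits).sum())


# ---------------------------------------------------------------------------
# narrowPeak interoperability

NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
]


def read_narrowpeak(path, target: str = "", sample: str = "") -> PeakSet:
    """Read ENCODE narrowPeak (10 columns; p/q stored as -log10; summit
    offset -1 means undefined)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 10:
        raise ValueError(f"{path}: narrowPeak requires 10 columns, got {df.shape[1]}")
    df.columns = NARROWPEAK_COLS
    q = np.where(df["qValue"] < 0, np.nan, np.power(10.0, -df["qValue"]))
    p = np.where(df["pValue"] < 0, np.nan, np.power(10.0, -df["pValue"]))
    summit = np.where(df["peak"] < 0, np.nan, df["start"] + df["peak"])
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "summit": summit,
            "fold_enrichment": df["signalValue"],
            "p": p,
            "q": q,
        }
    )
    return PeakSet(target=target, sample=sample, threshold_class="scored", peaks=out)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    df = peakset.peaks
    with np.errstate(divide="ignore"):
        neglog_p = np.where(df["p"].isna(), -1.0, -np.log10(df["p"]))
        neglog_q = np.where(df["q"].isna(), -1.0, -np.log10(df["q"]))
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": [f"{peakset.target or 'peak'}_{i}" for i in range(len(df))],
            "score": 0,
            "strand": ".",
            "signalValue": df["fold_enrichment"].fillna(0.0),
            "pValue": neglog_p,
            "qValue": neglog_q,
            "peak": np.where(df["summit"].isna(), -1, df["summit"] - df["start"]).astype(int),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
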