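"""Per-peak counting, FPKM, and pseudo-spike scaling factors.

The pseudo-spike idea: for contrasts where a genome-wide occupancy change is
expected, compositional normalizations (TMM, CPM) erase exactly the signal of
interest. Instead, the median per-base depth-normalized track signal over the
reference peaks of each sample is integerized into a stand-in for spike-in
read counts; scaling factors derived from these preserve genome-wide shifts.

Factor algebra: pseudo reads are max-normalized (r_i = p_i / max_j p_j) and
divided by their geometric mean, giving multiplicative factors with geometric
mean exactly 1. By default the factors are inverted before use (see
``pseudo_spike_factors``): with edgeR-style semantics (effective library =
library_size x factor), non-inverted factors would cancel a genome-wide shift
— the median over reference peaks rises with the shift itself — whereas the
inverted orientation preserves its sign and pushes true fold changes past the
calling threshold. The orientation is pinned by the global-shift recovery
test and can be flipped with ``invert=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import count_overlaps
from .tracks import CoverageTrack, FragmentSet, median_signal_over_regions


@dataclass
class CountMatrix:
    """Features (peaks or genes) x samples integer counts."""

    counts: pd.DataFrame  # index: feature ids, columns: sample ids
    lengths: pd.Series  # feature lengths in bp
    library_sizes: pd.Series  # total mapped fragments per sample
    conditions: pd.Series  # sample -> condition label

    def __post_init__(self) -> None:
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.loc[self.counts.index]
        self.library_sizes = self.library_sizes.loc[self.counts.columns]
        self.conditions = self.conditions.loc[self.counts.columns]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[samples].copy(),
            lengths=self.lengths.copy(),
            library_sizes=self.library_sizes.loc[samples].copy(),
            conditions=self.conditions.loc[samples].copy(),
        )

    def to_tsv(self, counts_path, sidecar_path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(counts_path, sep="\t")
        sidecar = {
            "library_sizes": {s: int(v) for s, v in self.library_sizes.items()},
            "conditions": dict(self.conditions),
        }
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def from_tsv(cls, counts_path, sidecar_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = df.pop("length")
        sidecar = json.loads(Path(sidecar_path).read_text())
        return cls(
            counts=df,
            lengths=lengths,
            library_sizes=pd.Series(sidecar["library_sizes"]),
            conditions=pd.Series(sidecar["conditions"]),
        )


@dataclass
class NormFactors:
    """Per-sample multiplicative normalization factors, geometric mean 1."""

    factors: pd.Series
    method: str  # "tmm" | "pseudo_spike"
    pseudo_spike_reads: pd.Series | None = None
    constant: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(dtype=float)
        if (f <= 0).any():
            raise ValueError("normalization factors must be positive")
        gm = float(np.exp(np.mean(np.log(f))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"geometric mean of factors is {gm}, expected 1")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"sample": self.factors.index, "method": self.method, "factor": self.factors.to_numpy()})
        if self.pseudo_spike_reads is not None:
            df["pseudo_reads"] = self.pseudo_spike_reads.loc[self.factors.index].to_numpy()
        df.to_csv(path, sep="\t", index=False)


def count_fragments_in_peaks(
    fragments: dict[str, FragmentSet], reference: pd.DataFrame, conditions: dict[str, str] | None = None
) -> CountMatrix:
    """Count, per sample, the fragments overlapping (>= 1 bp) each reference
    peak. A fragment spanning two peaks increments both. Library size is the
    sample's total fragment count."""
    if len(reference) == 0:
        raise ValueError("reference peak set is empty")
    ref = reference.sort_values(["chrom", "start"]).reset_index(drop=True)
    ids = [f"{r.chrom}:{r.start}-{r.end}" for r in ref.itertuples(index=False)]
    data = {}
    lib = {}
    cond = {}
    for sample, fs in fragments.items():
        data[sample] = count_overlaps(ref, fs.intervals)
        lib[sample] = fs.n
        cond[sample] = conditions[sample] if conditions else fs.condition
    counts = pd.DataFrame(data, index=pd.Index(ids, name="peak"))
    lengths = pd.Series((ref["end"] - ref["start"]).to_numpy(), index=counts.index, name="length")
    return CountMatrix(
        counts=counts,
        lengths=lengths,
        library_sizes=pd.Series(lib),
        conditions=pd.Series(cond),
    )


def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of feature per million mapped fragments."""
    if (cm.lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    kb = cm.lengths.to_numpy()[:, None] / 1000.0
    per_million = cm.library_sizes.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        cm.counts.to_numpy() / (kb * per_million), index=cm.counts.index, columns=cm.counts.columns
    )


def pseudo_spike_reads(track: CoverageTrack, reference: pd.DataFrame, constant: float = 1e6) -> int:
    """Integerized median per-base signal over the reference peaks of a
    depth-normalized track, floored at 1 so a fully depleted sample still
    yields finite factors. The constant only rescales the integerization grid
    — the resulting factors are invariant to it up to rounding."""
    med = median_signal_over_regions(track, reference)
    return max(1, int(round(med * constant)))


def pseudo_spike_factors(
    reads: pd.Series | dict[str, int], invert: bool = True, constant: float | None = None
) -> NormFactors:
    """Scaling factors from pseudo-spike read counts.

    r_i = reads_i / max_j reads_j; base factors r_i / geomean(r). With
    ``invert=True`` (default) the reciprocals are shipped, the orientation
    under which, applied as multipliers of library size, genome-wide shifts
    survive differential calling (see module docstring).
    """
    reads = pd.Series(reads, dtype=float)
    if len(reads) < 2:
        raise ValueError("need at least two samples")
    if (reads <= 0).any():
        raise ValueError("pseudo-spike reads must be positive")
    r = reads / reads.max()
    f = r / np.exp(np.mean(np.log(r)))
    if invert:
        f = 1.0 / f
    return NormFactors(
        factors=f,
        method="pseudo_spike",
        pseudo_spike_reads=reads.astype(int),
        constant=constant,
        meta={"inverted": invert},
    )


def select_normalization(expected_global_change: bool | None) -> str:
    """Pseudo-spike for contrasts flagged as expecting a genome-wide change,
    TMM otherwise. The flag must be explicit — there is no heuristic."""
    if expected_global_change is None:
        raise ValueError(
            "contrast must declare expected_global_change: true/false "
            "(pseudo-spike vs TMM normalization)"
        )
    return "pseudo_spike" if expected_global_change else "tmm"
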