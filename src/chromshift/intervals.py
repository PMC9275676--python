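"""Half-open interval primitives on numpy arrays.

Interval collections are pandas DataFrames with at least ``chrom``,
``start``, ``end`` columns (0-based half-open). These helpers implement the
three operations the pipeline needs — merge, membership counting, and
pairwise overlap — with sorted-array arithmetic; each is checked against a
brute-force per-base oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union of intervals; intervals closer than or equal to ``gap`` are joined.

    gap=0 joins touching (bookended) intervals, matching the reference-peak
    merge rule.
    """
    if len(df) == 0:
        return pd.DataFrame(columns=BED_COLS)
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = np.sort(sub["start"].to_numpy())
        ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy(), kind="stable")]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLS)


def _require_merged(df: pd.DataFrame) -> None:
    for _, sub in df.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError("interval set must be merged (sorted, non-overlapping)")


def count_overlaps(features: pd.DataFrame, query: pd.DataFrame) -> np.ndarray:
    """For each feature (sorted, non-overlapping within a chromosome), count
    query intervals overlapping it by >= 1 bp. A query interval spanning two
    features increments both."""
    _require_merged(features)
    counts = np.zeros(len(features), dtype=np.int64)
    feat = features.reset_index(drop=True)
    for chrom, fsub in feat.groupby("chrom"):
        fsub = fsub.sort_values("start")
        idx = fsub.index.to_numpy()
        fstart = fsub["start"].to_numpy()
        fend = fsub["end"].to_numpy()
        qsub = query[query["chrom"] == chrom]
        if len(qsub) == 0:
            continue
        qs = qsub["start"].to_numpy()
        qe = qsub["end"].to_numpy()
        # features overlapping query [s,e): those with end > s and start < e
        lo = np.searchsorted(fend, qs, side="right")
        hi = np.searchsorted(fstart, qe, side="left")
        valid = hi > lo
        delta = np.zeros(len(fsub) + 1, dtype=np.int64)
        np.add.at(delta, lo[valid], 1)
        np.add.at(delta, hi[valid], -1)
        counts[idx] = np.cumsum(delta[:-1])
    return counts


def overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean vector: does each interval of ``a`` intersect (>=1 bp) any
    interval of ``b``? ``b`` must be merged per chromosome."""
    _require_merged(b)
    hits = np.zeros(len(a), dtype=bool)
    a_ = a.reset_index(drop=True)
    for chrom, asub in a_.groupby("chrom"):
        bsub = b[b["chrom"] == chrom].sort_values("start")
        if len(bsub) == 0:
            continue
        bs = bsub["start"].to_numpy()
        be = bsub["end"].to_numpy()
        lo = np.searchsorted(be, asub["start"].to_numpy(), side="right")
        hi = np.searchsorted(bs, asub["end"].to_numpy(), side="left")
        hits[asub.index.to_numpy()] = hi > lo
    return hits


def total_length(df: pd.DataFrame) -> int:
    return int((df["end"] - df["start"]).sum())
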