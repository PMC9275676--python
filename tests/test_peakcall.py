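"""Peak caller calibration/power, threshold nesting, consensus logic, and
narrowPeak interoperability."""

import numpy as np
import pandas as pd
import pytest

from chromshift import peakcall, simulate
from chromshift.intervals import merge_intervals, overlaps_any


def peakset(rows, target="t", sample="s", cls="FDR50"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df = df.assign(summit=df["start"], fold_enrichment=1.0, p=0.01, q=0.01)
    return peakcall.PeakSet(target=target, sample=sample, threshold_class=cls, peaks=df)


@pytest.fixture(scope="module")
def planted_call():
    genome = simulate.simulate_genome(1, 1_000_000, 0, seed=5)
    truth = simulate.plant_peaks(
        genome, n_peaks=40, enrichment_range=(8.0, 8.0), peak_width=500, min_gap=2000, seed=5
    )
    frags, _ = simulate.simulate_fragments(truth, genome, [("s1", "WT", 200_000)], seed=5)
    scored = peakcall.call_peaks(frags["s1"], genome.chrom_sizes)
    return genome, truth, scored


def test_planted_peaks_recovered_with_high_precision(planted_call):
    _, truth, scored = planted_call
    hc = peakcall.threshold_peaks(scored, 0.05)
    called = hc.intervals()
    planted = truth.regions()
    recall = overlaps_any(planted, merge_intervals(called)).mean()
    precision = overlaps_any(called, merge_intervals(planted)).mean()
    assert recall >= 0.9 and precision >= 0.9


def test_threshold_nesting_and_filter_oracle(planted_call):
    _, _, scored = planted_call
    hc = peakcall.threshold_peaks(scored, 0.05)
    fdr50 = peakcall.threshold_peaks(scored, 0.5)
    assert hc.threshold_class == "high_confidence" and fdr50.threshold_class == "FDR50"
    assert len(hc) <= len(fdr50)
    ids = lambda ps: set(map(tuple, ps.peaks[["chrom", "start", "end"]].to_numpy()))
    assert ids(hc) <= ids(fdr50)
    assert len(hc) == (scored.peaks["q"] <= 0.05).sum()
    assert len(peakcall.threshold_peaks(scored, 1.0)) == len(scored)
    tiny = peakcall.threshold_peaks(scored, min(scored.peaks["q"].min() / 2, 1e-300))
    assert len(tiny) == 0
    with pytest.raises(ValueError):
        peakcall.threshold_peaks(scored, 0.0)


def test_null_background_fdr_control():
    genome = simulate.simulate_genome(1, 1_000_000, 0, seed=0)
    fracs = []
    for seed in range(5):
        truth = simulate.plant_peaks(genome, n_peaks=0, seed=seed)
        frags, _ = simulate.simulate_fragments(truth, genome, [("s", "WT", 200_000)], seed=seed)
        hc = peakcall.threshold_peaks(peakcall.call_peaks(frags["s"], genome.chrom_sizes), 0.05)
        fracs.append((hc.peaks["end"] - hc.peaks["start"]).sum() / genome.length)
    assert np.mean(fracs) <= 0.01


def test_call_peaks_empty_treatment_and_oversized_window():
    genome = simulate.simulate_genome(1, 1_000, 0, seed=0)
    from chromshift.tracks import FragmentSet
    empty = FragmentSet("s", "c", pd.DataFrame(columns=["chrom", "start", "end", "strand"]))
    with pytest.raises(ValueError, match="empty"):
        peakcall.call_peaks(empty, genome.chrom_sizes)
    one = FragmentSet("s", "c", pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}))
    with pytest.raises(ValueError, match="window"):
        peakcall.call_peaks(one, genome.chrom_sizes, window=5000)


# ---------------------------------------------------------------------------
# consensus


def test_reproducible_requires_all_replicates():
    r1 = peakset([("chr1", 100, 200), ("chr1", 1000, 1100)], sample="r1")
    r2 = peakset([("chr1", 150, 250), ("chr1", 1050, 1150)], sample="r2")
    r3 = peakset([("chr1", 120, 220)], sample="r3")
    out = peakcall.reproducible_peaks([r1, r2, r3])
    # first region present (overlapping) in 3/3 -> kept; second in 2/3 -> dropped
    assert len(out) == 1
    assert out.peaks.iloc[0][["start", "end"]].tolist() == [100, 250]


def test_reproducible_chained_overlap_qualifies_transitively():
    # A(0-100), B(90-190), C(180-280): A and C do not intersect, but every
    # replicate contributes to the merged union region, which qualifies.
    a = peakset([("chr1", 0, 100)], sample="a")
    b = peakset([("chr1", 90, 190)], sample="b")
    c = peakset([("chr1", 180, 280)], sample="c")
    out = peakcall.reproducible_peaks([a, b, c])
    assert len(out) == 1
    assert out.peaks.iloc[0][["start", "end"]].tolist() == [0, 280]


def test_reproducible_permutation_invariance_and_empty_replicate():
    r1 = peakset([("chr1", 100, 200), ("chr1", 500, 600)], sample="r1")
    r2 = peakset([("chr1", 150, 260)], sample="r2")
    out12 = peakcall.reproducible_peaks([r1, r2]).peaks
    out21 = peakcall.reproducible_peaks([r2, r1]).peaks
    pd.testing.assert_frame_equal(out12[["chrom", "start", "end"]], out21[["chrom", "start", "end"]])
    empty = peakset([], sample="r3")
    assert len(peakcall.reproducible_peaks([r1, r2, empty])) == 0


def test_singleton_passthrough_keeps_only_high_confidence():
    rows = [("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500)]
    ps = peakset(rows)
    ps.peaks["q"] = [0.01, 0.3, 0.04]
    out = peakcall.singleton_peaks(ps)
    assert out.threshold_class == "reproducible"
    assert len(out) == 2
    assert (out.peaks["q"] <= 0.05).all()


def test_merge_reference_peaks_union_oracle():
    s1 = peakset([("chr1", 0, 150)], cls="reproducible")
    s2 = peakset([("chr1", 100, 250), ("chr2", 0, 50)], cls="reproducible")
    ref = peakcall.merge_reference_peaks([s1, s2])
    assert ref.values.tolist() == [["chr1", 0, 250], ["chr2", 0, 50]]
    # idempotent on identical sets
    same = peakcall.merge_reference_peaks([s1, s1])
    assert same.values.tolist() == [["chr1", 0, 150]]
    with pytest.raises(ValueError, match="mixed"):
        peakcall.merge_reference_peaks([s1, peakset([("chr1", 0, 9)], target="other")])


# ---------------------------------------------------------------------------
# overlap counting


def test_overlap_peaks_trivial_and_bruteforce():
    a = merge_intervals(pd.DataFrame({"chrom": "chr1", "start": [0, 100, 300, 600, 900],
                                      "end": [50, 200, 400, 700, 950]}))
    assert peakcall.overlap_peaks(a, a) == (0, 5, 0)
    b = merge_intervals(pd.DataFrame({"chrom": "chr1", "start": [2000, 3000], "end": [2100, 3100]}))
    assert peakcall.overlap_peaks(a, b) == (5, 0, 2)
    c = merge_intervals(pd.DataFrame({"chrom": "chr1", "start": [40, 150, 500, 940],
                                      "end": [60, 160, 550, 960]}))
    n_a, n_ov, n_b = peakcall.overlap_peaks(a, c)
    # brute force from both perspectives
    ov_a = sum(any(r.start < x.end and r.end > x.start for x in c.itertuples(index=False))
               for r in a.itertuples(index=False))
    ov_b = sum(any(r.start < x.end and r.end > x.start for x in a.itertuples(index=False))
               for r in c.itertuples(index=False))
    assert (n_a, n_ov, n_b) == (len(a) - ov_a, ov_a, len(c) - ov_b)


# ---------------------------------------------------------------------------
# narrowPeak


def test_narrowpeak_roundtrip_and_encoding(tmp_path, planted_call):
    _, _, scored = planted_call
    path = tmp_path / "peaks.narrowPeak"
    peakcall.write_narrowpeak(scored, path)
    back = peakcall.read_narrowpeak(path)
    np.testing.assert_allclose(back.peaks["q"], scored.peaks["q"], rtol=1e-6)
    np.testing.assert_allclose(back.peaks["summit"], scored.peaks["summit"])


def test_narrowpeak_q_decoding_and_summit_sentinel(tmp_path):
    path = tmp_path / "x.narrowPeak"
    path.write_text("chr1\t0\t100\tp1\t0\t.\t5.0\t2.0\t1.30103\t10\n"
                    "chr1\t200\t300\tp2\t0\t.\t5.0\t2.0\t1.0\t-1\n")
    ps = peakcall.read_narrowpeak(path)
    assert ps.peaks["q"].iloc[0] == pytest.approx(0.05, rel=1e-5)
    assert ps.peaks["summit"].iloc[0] == 10
    assert np.isnan(ps.peaks["summit"].iloc[1])
    bad = tmp_path / "bad.narrowPeak"
    bad.write_text("chr1\t0\t100\n")
    with pytest.raises(ValueError, match="10 columns"):
        peakcall.read_narrowpeak(bad)
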