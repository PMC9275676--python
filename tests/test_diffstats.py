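"""Statistical core: TMM against an independently coded direct-formula
oracle, voom weight behavior, moderated-t limits, BH against its definition,
calling rules, and the auxiliary tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromshift import diffstats
from chromshift.chipnorm import CountMatrix

from conftest import nb_count_matrix


# ---------------------------------------------------------------------------
# TMM oracle: a second, plain-loop transcription of the published formula


def tmm_oracle(counts: np.ndarray, lib: np.ndarray, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    nsamp = counts.shape[1]
    q75 = []
    for j in range(nsamp):
        q75.append(np.quantile(counts[:, j] / lib[j], 0.75))
    ref = min(range(nsamp), key=lambda j: abs(q75[j] - np.mean(q75)))
    log2f = []
    for j in range(nsamp):
        if j == ref:
            log2f.append(0.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(counts.shape[0]):
            o, r = counts[g, j], counts[g, ref]
            if o == 0 or r == 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            m_vals.append(np.log2(po / pr))
            a_vals.append(0.5 * np.log2(po * pr))
            w_vals.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        m_vals, a_vals, w_vals = map(np.asarray, (m_vals, a_vals, w_vals))
        n = len(m_vals)
        rank_of = lambda arr: {i: k + 1 for k, i in enumerate(np.argsort(arr, kind="stable"))}
        rm, ra = rank_of(m_vals), rank_of(a_vals)
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= n + 1 - lo_m and lo_a <= ra[i] <= n + 1 - lo_a:
                num += m_vals[i] / w_vals[i]
                den += 1.0 / w_vals[i]
        log2f.append(num / den if den > 0 else 0.0)
    f = 2.0 ** np.asarray(log2f)
    return f / np.exp(np.mean(np.log(f)))


@pytest.mark.parametrize("seed", range(10))
def test_tmm_matches_direct_formula_oracle(seed):
    cm = nb_count_matrix(seed, nfeat=200, n_per_group=2)
    got = diffstats.tmm_factors(cm).factors.to_numpy()
    expected = tmm_oracle(cm.counts.to_numpy(float), cm.library_sizes.to_numpy(float))
    np.testing.assert_allclose(got, expected, atol=1e-8)


def test_tmm_identical_and_scaled_columns():
    base = np.random.default_rng(0).integers(10, 1000, 300)
    counts = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
    cm = CountMatrix(
        counts=counts,
        lengths=pd.Series(500, index=counts.index),
        library_sizes=counts.sum(axis=0),
        conditions=pd.Series({"a": "x", "b": "x", "c": "y"}),
    )
    f = diffstats.tmm_factors(cm).factors
    np.testing.assert_allclose(f, 1.0, atol=1e-12)  # pure depth: all M are 0
    counts["d"] = 0
    cm2 = CountMatrix(counts=counts, lengths=pd.Series(500, index=counts.index),
                      library_sizes=counts.sum(axis=0) + 1,
                      conditions=pd.Series({"a": "x", "b": "x", "c": "y", "d": "y"}))
    with pytest.raises(ValueError, match="zero"):
        diffstats.tmm_factors(cm2)


# ---------------------------------------------------------------------------
# voom weights


def test_voom_logcpm_offsets_and_weight_positivity():
    cm = nb_count_matrix(3, nfeat=150, n_per_group=3)
    cm.counts.iloc[0] = 0  # a zero-count feature
    design = diffstats.DesignMatrix.two_group(cm.conditions, "A", "B")
    logcpm, w = diffstats.voom_weights(cm, None, design)
    lib0 = cm.library_sizes.iloc[0]
    assert logcpm.iloc[0, 0] == pytest.approx(np.log2(0.5 / (lib0 + 1.0) * 1e6))
    assert (w > 0).all()


def test_voom_weights_flat_for_homoskedastic_input():
    # large counts with constant log-scale variance: the trend is flat
    rng = np.random.default_rng(4)
    base = rng.uniform(1e3, 1e5, 300)
    counts = pd.DataFrame(
        np.round(base[:, None] * rng.lognormal(0.0, 0.2, size=(300, 6))).astype(int),
        columns=[f"s{i}" for i in range(6)],
    )
    cm = CountMatrix(counts=counts, lengths=pd.Series(500, index=counts.index),
                     library_sizes=counts.sum(axis=0),
                     conditions=pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns))
    design = diffstats.DesignMatrix.two_group(cm.conditions, "A", "B")
    _, w = diffstats.voom_weights(cm, None, design)
    assert w.max() / w.min() < 1.5


def test_voom_requires_residual_df():
    cm = nb_count_matrix(5, nfeat=20, n_per_group=1)
    design = diffstats.DesignMatrix.two_group(cm.conditions, "A", "B")
    with pytest.raises(ValueError, match="fewer samples"):
        diffstats.voom_weights(cm, None, design)


# ---------------------------------------------------------------------------
# moderated fit


@pytest.fixture(scope="module")
def null_fit_inputs():
    cm = nb_count_matrix(6, nfeat=400, n_per_group=3)
    design = diffstats.DesignMatrix.two_group(cm.conditions, "A", "B")
    logcpm, w = diffstats.voom_weights(cm, None, design)
    return logcpm, w, design


def test_prior_df_zero_recovers_ordinary_t(null_fit_inputs):
    logcpm, w, design = null_fit_inputs
    fit = diffstats.fit_moderated(logcpm, w, design, prior_df=0.0)
    t_ordinary = fit.table["log2FC"] / (fit.table["se_unscaled"] * fit.table["sigma"])
    np.testing.assert_allclose(fit.table["t"], t_ordinary, atol=1e-10)
    p_ordinary = 2 * stats.t.sf(np.abs(t_ordinary), fit.table["df_resid"])
    np.testing.assert_allclose(fit.table["p"], p_ordinary, atol=1e-10)


def test_prior_df_infinite_pools_to_s0(null_fit_inputs):
    logcpm, w, design = null_fit_inputs
    fit = diffstats.fit_moderated(logcpm, w, design, prior_df=np.inf)
    t_pooled = fit.table["log2FC"] / (fit.table["se_unscaled"] * np.sqrt(fit.s0_sq))
    np.testing.assert_allclose(fit.table["t"], t_pooled, atol=1e-10)


def test_null_fit_centered_and_calibrated(null_fit_inputs):
    logcpm, w, design = null_fit_inputs
    fit = diffstats.fit_moderated(logcpm, w, design)
    assert abs(np.median(fit.table["log2FC"])) < 0.05
    assert stats.kstest(fit.table["p"], "uniform").pvalue > 0.01
    assert fit.d0 > 0


# ---------------------------------------------------------------------------
# BH


def test_bh_hand_case_and_single_p():
    np.testing.assert_allclose(diffstats.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert diffstats.bh_adjust([0.2])[0] == 0.2
    with pytest.raises(ValueError):
        diffstats.bh_adjust([0.5, 1.5])


@pytest.mark.parametrize("seed", range(20))
def test_bh_matches_definitional_oracle(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(rng.integers(1, 60))
    got = diffstats.bh_adjust(p)
    n = len(p)
    order = np.argsort(p, kind="stable")
    expected = np.empty(n)
    for rank_pos, i in enumerate(order, start=1):
        expected[i] = min(
            min(p[j] * n / r for r, j in enumerate(order, start=1) if r >= rank_pos), 1.0
        )
    np.testing.assert_allclose(got, expected, rtol=0, atol=0)


# ---------------------------------------------------------------------------
# calling rules


def test_classification_rules():
    table = pd.DataFrame(
        {
            "log2FC": [1.5, 0.5, -1.2, 1.5, -1.2, 1.5],
            "p": [0.001, 0.001, 0.01, 0.2, 0.04, 0.06],
            "q": [0.01, 0.01, 0.04, 0.5, 0.2, 0.2],
        },
        index=list("abcdef"),
    )
    rep = diffstats.classify_differential(table, "replicated")
    assert rep.tolist() == ["up", "ns", "down", "ns", "ns", "ns"]
    fc = diffstats.classify_differential(table, "fc_only")
    assert fc.tolist() == ["up", "ns", "down", "up", "down", "up"]
    volcano = diffstats.classify_differential(table, "volcano")
    assert volcano.tolist() == ["up", "ns", "down", "ns", "down", "ns"]
    with pytest.raises(ValueError, match="mode"):
        diffstats.classify_differential(table, "bogus")


def test_fc_only_uses_fpkm_with_floor():
    counts = pd.DataFrame({"wt": [100, 0], "ko": [400, 0]}, index=["p1", "p2"])
    cm = CountMatrix(counts=counts, lengths=pd.Series([1000, 1000], index=counts.index),
                     library_sizes=pd.Series({"wt": 1_000_000, "ko": 1_000_000}),
                     conditions=pd.Series({"wt": "WT", "ko": "KO"}))
    t = diffstats.fc_only_log2fc(cm, "WT", "KO")
    assert t.loc["p1", "log2FC"] == pytest.approx(np.log2(400.1 / 100.1))
    assert t.loc["p2", "log2FC"] == 0.0  # floor avoids 0/0


# ---------------------------------------------------------------------------
# Wilcoxon / t / G


def test_wilcoxon_exact_hand_cases():
    w, p = diffstats.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert w == 6 and p == pytest.approx(0.1)
    _, p_same = diffstats.wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3])
    assert p_same == 1.0
    with pytest.raises(ValueError):
        diffstats.wilcoxon_rank_sum([], [1.0])


@pytest.mark.parametrize("seed", range(5))
def test_wilcoxon_exact_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=7), rng.normal(size=8)
    _, p = diffstats.wilcoxon_rank_sum(x, y)
    sp = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    assert p == pytest.approx(sp, abs=1e-12)


def test_wilcoxon_exact_vs_normal_path_agree_at_n8():
    rng = np.random.default_rng(10)
    for _ in range(10):
        x, y = rng.normal(size=8), rng.normal(size=8)
        _, p_exact = diffstats.wilcoxon_rank_sum(x, y, exact_max=8)
        _, p_normal = diffstats.wilcoxon_rank_sum(x, y, exact_max=0)
        assert abs(p_exact - p_normal) <= 0.02


def test_ttest_hand_case_and_scipy_agreement():
    assert diffstats.unpaired_ttest([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)
    t, p = diffstats.unpaired_ttest([1, 2, 3], [2, 3, 4])
    assert t == pytest.approx(-1.2247, abs=1e-4)
    assert p == pytest.approx(0.2879, abs=1e-4)
    rng = np.random.default_rng(11)
    for _ in range(10):
        x, y = rng.normal(size=5), rng.normal(1, 2, size=9)
        tt, pp = diffstats.unpaired_ttest(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert tt == pytest.approx(ref.statistic) and pp == pytest.approx(ref.pvalue)


def test_g_test_hand_cases_and_chisquare_oracle():
    g, p = diffstats.g_test(10, 10, 100, 100)
    assert g == 0.0 and p == 1.0
    g2, _ = diffstats.g_test(10, 0, 100, 100)
    assert g2 == pytest.approx(2 * 10 * np.log(2), abs=1e-9)
    rng = np.random.default_rng(12)
    for _ in range(10):
        oa, ob = int(rng.integers(1, 50)), int(rng.integers(1, 50))
        g3, p3 = diffstats.g_test(oa, ob, 500, 700)
        e = np.array([500, 700]) / 1200 * (oa + ob)
        g_ref = 2 * (oa * np.log(oa / e[0]) + ob * np.log(ob / e[1]))
        assert g3 == pytest.approx(g_ref)
        assert p3 == pytest.approx(stats.chi2.sf(g_ref, 1))
    with pytest.raises(ValueError):
        diffstats.g_test(-1, 0, 10, 10)
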