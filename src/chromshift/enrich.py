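"""Pre-ranked gene-set enrichment.

Weighted Kolmogorov-Smirnov-style running-sum enrichment score (weight
exponent 1 by default), gene-label permutation null, sign-stratified
normalized scores and FDR. The per-gene metric is a log2 fold-change
equivalent taken from a differential-expression fit.

Permutation nulls are computed once per distinct effective set size and
shared between sets of that size — in pre-ranked mode the null distribution
of a random membership set depends only on its size, so this is statistically
identical to per-set sampling and much cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "chromshift") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def rank_genes(metric: pd.Series) -> pd.Series:
    """Descending ranked list; ties broken by gene id (lexicographic) so
    permutation nulls are reproducible. Duplicate gene ids are an error."""
    if metric.index.duplicated().any():
        dupes = metric.index[metric.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in ranking metric: {dupes[:5]}")
    if not np.isfinite(metric.to_numpy(dtype=float)).all():
        raise ValueError("ranking metric must be finite")
    df = metric.rename("metric").rename_axis("gene").reset_index()
    df = df.sort_values(["metric", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(df["metric"].to_numpy(), index=df["gene"].to_numpy(), name="metric")


def enrichment_score(
    ranked: pd.Series, gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """(ES, running sum, leading edge) for one gene set.

    Hits advance the running sum by |metric|^p / sum over hits of |metric|^p;
    misses retreat by 1/(N - N_h). ES is the signed maximum deviation; the
    leading edge is the hit genes up to (ES > 0) or from (ES < 0) the
    extremum.
    """
    genes = ranked.index.to_numpy()
    hit = np.isin(genes, list(gene_set))
    if not hit.any():
        raise ValueError("gene set has no overlap with the ranked list")
    n = len(genes)
    n_h = int(hit.sum())
    if n_h == n:
        raise ValueError("gene set covers the whole ranked universe")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    s = w[hit].sum()
    steps = np.where(hit, (w / s if s > 0 else np.full(n, 1.0 / n_h)), -1.0 / (n - n_h))
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return es, running, leading


def _null_es_pool(
    w: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution for random membership sets of a given size."""
    n = len(w)
    order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :size]
    hit = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hit, order, True, axis=1)
    s = np.where(hit, w[None, :], 0.0).sum(axis=1)
    s = np.where(s > 0, s, 1.0)
    steps = np.where(hit, w[None, :] / s[:, None], -1.0 / (n - size))
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


@dataclass
class GSEAResult:
    table: pd.DataFrame  # set, size, ES, NES, p, q, leading_edge
    excluded: dict[str, str]


def _signed_mean(null_es: np.ndarray, sign: float) -> float:
    same = null_es[np.sign(null_es) == sign] if sign != 0 else null_es
    if len(same) == 0:
        return float(np.mean(np.abs(null_es))) or 1.0
    return float(np.mean(np.abs(same)))


def gsea_prerank(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    min_size: int = 5,
    max_size: int = 5000,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    share_nulls: bool = True,
) -> GSEAResult:
    """Pre-ranked GSEA over a gene-set collection.

    Sets are intersected with the ranked universe and filtered to
    [min_size, max_size]. Nominal p is the one-sided fraction of same-sign
    null ES at least as extreme; NES = ES / mean(|null ES|, same sign); FDR q
    is the sign-stratified pooled-null ratio, clipped to [0, 1].

    With ``share_nulls`` (default) sets of equal size share one permutation
    pool — in pre-ranked mode the null depends only on set size, so this is
    distributionally identical and much cheaper; ``share_nulls=False`` draws
    an independent pool per set, making p-values of distinct sets independent
    given the ranking.
    """
    universe = set(ranked.index)
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    effective: dict[str, list[str]] = {}
    excluded: dict[str, str] = {}
    for name, members in gene_sets.items():
        inside = sorted(set(members) & universe)
        if not min_size <= len(inside) <= min(max_size, len(universe) - 1):
            excluded[name] = f"size {len(inside)} outside [{min_size}, {max_size}]"
        else:
            effective[name] = inside
    if not effective:
        raise ValueError(f"no gene set within size bounds; exclusions: {excluded}")
    if share_nulls:
        by_size = {k: _null_es_pool(w, k, n_perm, rng) for k in sorted({len(m) for m in effective.values()})}
    rows = []
    null_nes_all = []
    for name in effective:
        members = effective[name]
        es, _, leading = enrichment_score(ranked, members, weight_p)
        pool = by_size[len(members)] if share_nulls else _null_es_pool(w, len(members), n_perm, rng)
        sign = np.sign(es) if es != 0 else 1.0
        same = pool[np.sign(pool) == sign]
        if len(same):
            p = float((np.abs(same) >= abs(es)).sum() / len(same))
        else:
            p = 1.0 / n_perm
        nes = es / _signed_mean(pool, sign)
        rows.append((name, len(members), es, nes, p, leading))
        pos_mean, neg_mean = _signed_mean(pool, 1.0), _signed_mean(pool, -1.0)
        null_nes_all.append(np.where(pool >= 0, pool / pos_mean, pool / neg_mean))
    null_nes = np.concatenate(null_nes_all)
    obs_nes = np.array([r[3] for r in rows])
    qs = []
    for _, _, es, nes, _, _ in rows:
        sign = 1.0 if nes >= 0 else -1.0
        null_same = null_nes[np.sign(null_nes) == sign]
        obs_same = obs_nes[np.sign(obs_nes) == sign]
        num = (np.abs(null_same) >= abs(nes)).mean() if len(null_same) else 0.0
        den = (np.abs(obs_same) >= abs(nes)).mean() if len(obs_same) else 1.0
        qs.append(float(np.clip(num / den if den > 0 else 0.0, 0.0, 1.0)))
    table = pd.DataFrame(
        {
            "set": [r[0] for r in rows],
            "size": [r[1] for r in rows],
            "ES": [r[2] for r in rows],
            "NES": obs_nes,
            "p": [r[4] for r in rows],
            "q": qs,
            "leading_edge": [",".join(r[5]) for r in rows],
        }
    ).set_index("set")
    return GSEAResult(table=table, excluded=excluded)


def significant_sets(result: GSEAResult, fdr_max: float = 0.25, p_max: float = 0.05) -> pd.DataFrame:
    """Sets passing both thresholds (FDR < fdr_max and p < p_max),
    sign-agnostic."""
    t = result.table
    return t[(t["q"] < fdr_max) & (t["p"] < p_max)].copy()
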