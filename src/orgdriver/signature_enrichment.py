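"""Preranked gene-set enrichment with gene-set permutation FDR.

The enrichment score is the classic weighted Kolmogorov–Smirnov running-sum
extremum: walking the ranked list, set members increment the sum by
|metric|^p (normalized over members) and non-members decrement it by
1/(N - Nh). Null scores come from random same-size gene sets drawn from the
ranked universe; NES normalizes by the sign-matched mean |null ES|, and the
FDR is the standard NES-based ratio of null to observed tail fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WEIGHT_P = 1.0
DEFAULT_N_PERM = 10000


def rank_list(metric: pd.Series) -> pd.Series:
    """Strict ranking: stable sort by (metric descending, gene id ascending)."""
    if not np.isfinite(metric.to_numpy(dtype=float)).all():
        raise ValueError("ranking metric must be finite")
    if metric.index.duplicated().any():
        raise ValueError("genes must be unique")
    order = np.lexsort((metric.index.to_numpy(), -metric.to_numpy(dtype=float)))
    return metric.iloc[order]


@dataclass
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]


def enrichment_score(ranked: pd.Series, gene_set, weight_p: float = DEFAULT_WEIGHT_P) -> EnrichmentScore:
    """Weighted-KS enrichment score with running sum and leading edge.

    Requires a non-empty intersection strictly smaller than the ranked list.
    The leading edge contains the members up to the extremum (from the top
    for positive ES, from the bottom for negative ES).
    """
    genes = ranked.index.to_numpy()
    metric = ranked.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    n, nh = genes.size, int(in_set.sum())
    if nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if nh >= n:
        raise ValueError("gene set must be smaller than the ranked list")
    w = np.abs(metric) ** weight_p
    w_hit = np.where(in_set, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all member metrics zero: fall back to equal weights
        w_hit = in_set.astype(float)
        total = w_hit.sum()
    steps = w_hit / total - (~in_set) / (n - nh)
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = float(running[i_max]) if abs(running[i_max]) >= abs(running[i_min]) else float(running[i_min])
    if es >= 0:
        leading = list(genes[: i_max + 1][in_set[: i_max + 1]])
    else:
        leading = list(genes[i_min:][in_set[i_min:]])
    return EnrichmentScore(es=es, running_sum=running, leading_edge=leading)


def _es_from_hits(hits: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Extremum ES from sorted hit positions, vectorized over rows.

    ``hits``: (n_perm, k) sorted 0-based positions; ``weights``: matching
    |metric|^p values. The running sum is piecewise linear between hits, so
    its extrema sit just before/after hit positions.
    """
    k = hits.shape[1]
    miss = 1.0 / (n - k)
    w = weights.copy()
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        total[zero] = k
    cumw = np.cumsum(w, axis=1) / total
    i = np.arange(1, k + 1)
    s_after = cumw - (hits + 1 - i) * miss
    s_before = np.concatenate([np.zeros((hits.shape[0], 1)), cumw[:, :-1]], axis=1) - (hits - i + 1) * miss
    s_max = s_after.max(axis=1)
    s_min = s_before.min(axis=1)
    return np.where(np.abs(s_max) >= np.abs(s_min), s_max, s_min)


@dataclass
class GseaResult:
    table: pd.DataFrame  # set -> es, nes, p, q, size
    leading_edges: dict[str, list[str]]
    n_permutations: int


def gsea_permutation_fdr(
    ranked: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = DEFAULT_N_PERM,
    weight_p: float = DEFAULT_WEIGHT_P,
    seed: int = 0,
) -> GseaResult:
    """Enrichment with gene-set permutation null, NES, nominal p and FDR q.

    For each set, ``n_perm`` random same-size gene sets from the ranked
    universe define the null ES distribution. NES = ES divided by the mean
    |null ES| of matching sign; the nominal p is the add-one-corrected
    fraction of null |ES| >= |ES|; q is the pooled null-NES tail fraction
    over the observed-NES tail fraction, sign-resolved, monotonized and
    capped at 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = rank_list(ranked)
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = genes.size
    w_all = np.abs(ranked.to_numpy(dtype=float)) ** weight_p

    null_cache: dict[int, np.ndarray] = {}

    def null_es_for_size(k: int) -> np.ndarray:
        # the gene-set permutation null depends only on the set size; draw
        # random same-size sets in memory-bounded chunks
        if k not in null_cache:
            out = np.empty(n_perm)
            done = 0
            while done < n_perm:
                m = min(1024, n_perm - done)
                u = rng.random((m, n))
                hits = np.sort(np.argpartition(u, k, axis=1)[:, :k], axis=1)
                out[done : done + m] = _es_from_hits(hits, w_all[hits], n)
                done += m
            null_cache[k] = out
        return null_cache[k]

    universe = set(genes)
    names, es_obs, nes_obs, pvals, sizes = [], [], [], [], []
    null_nes_pool = []
    leading = {}
    for name, members in gene_sets.items():
        members = [g for g in set(members) if g in universe]
        if not members or len(members) >= n:
            continue
        k = len(members)
        score = enrichment_score(ranked, members, weight_p)
        null_es = null_es_for_size(k)
        pos_mean = np.abs(null_es[null_es >= 0]).mean() if (null_es >= 0).any() else np.abs(null_es).mean()
        neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.abs(null_es).mean()
        nes = score.es / (pos_mean if score.es >= 0 else neg_mean)
        null_nes = np.where(null_es >= 0, null_es / pos_mean, null_es / neg_mean)
        p = (1.0 + np.sum(np.abs(null_es) >= abs(score.es))) / (1.0 + n_perm)
        names.append(name)
        es_obs.append(score.es)
        nes_obs.append(nes)
        pvals.append(p)
        sizes.append(k)
        null_nes_pool.append(null_nes)
        leading[name] = score.leading_edge

    nes_arr = np.array(nes_obs)
    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    q = np.ones(len(names))
    for sign in (1, -1):
        sel = np.flatnonzero(nes_arr >= 0) if sign > 0 else np.flatnonzero(nes_arr < 0)
        if sel.size == 0:
            continue
        pool_side = pool[pool >= 0] if sign > 0 else pool[pool < 0]
        obs_side = nes_arr[sel]
        for idx, nes in zip(sel, obs_side):
            if pool_side.size == 0:
                q[idx] = 1.0
                continue
            if sign > 0:
                null_frac = np.mean(pool_side >= nes)
                obs_frac = np.mean(obs_side >= nes)
            else:
                null_frac = np.mean(pool_side <= nes)
                obs_frac = np.mean(obs_side <= nes)
            q[idx] = min(null_frac / max(obs_frac, 1.0 / max(obs_side.size, 1)), 1.0)
        # monotonize within the sign: q non-increasing in |NES| (running min
        # from the least extreme NES up)
        order = np.argsort(np.abs(obs_side))
        q_sorted = np.minimum.accumulate(q[sel][order])
        q_sel = np.empty_like(q_sorted)
        q_sel[order] = q_sorted
        q[sel] = q_sel
    table = pd.DataFrame(
        {"es": es_obs, "nes": nes_obs, "p": pvals, "q": q, "size": sizes}, index=pd.Index(names, name="gene_set")
    )
    return GseaResult(table=table, leading_edges=leading, n_permutations=n_perm)
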