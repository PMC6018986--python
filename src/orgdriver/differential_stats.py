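"""Differential-abundance machinery shared by all omics layers.

Replicate-presence filtering and downshifted-Gaussian detection-limit
imputation for intensity matrices, a moderated t-test with permutation-based
FDR (Perseus-style, statistic d = diff / (se + s0)), median-of-ratios
normalization with pseudocount-shrunken log2 fold changes for count
matrices, and condition-signature Pearson correlation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import SampleDesign

logger = logging.getLogger(__name__)

DEFAULT_S0 = 0.1  # moderation constant on log2 intensities
DEFAULT_IMPUTE_SHIFT = 1.8  # downshift, in observed-sd multiples
DEFAULT_IMPUTE_WIDTH = 0.3  # imputation sd, as a fraction of observed sd
DEFAULT_PRIOR_COUNT = 4.0  # fold-change shrinkage pseudocount


def presence_filter(matrix: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Keep features observed in every replicate of at least one condition."""
    keep = np.zeros(len(matrix), dtype=bool)
    for cond in design.conditions:
        cols = design.samples_of(cond)
        keep |= matrix[cols].notna().all(axis=1).to_numpy()
    return matrix.loc[keep]


def detection_limit_impute(
    matrix: pd.DataFrame,
    width: float = DEFAULT_IMPUTE_WIDTH,
    shift: float = DEFAULT_IMPUTE_SHIFT,
    seed: int = 0,
    log_input: bool = False,
) -> pd.DataFrame:
    """Impute missing intensities from a downshifted Gaussian, per sample.

    For each sample, missing log-intensities are drawn from
    Normal(mean_obs - shift * sd_obs, (width * sd_obs)^2), mimicking values
    below the detection limit. Intensities are log-transformed internally
    unless ``log_input`` says they already are.
    """
    rng = np.random.default_rng(seed)
    vals = matrix.to_numpy(dtype=float).copy()
    logged = vals if log_input else np.log10(vals, where=~np.isnan(vals), out=np.full_like(vals, np.nan))
    for j, col in enumerate(matrix.columns):
        x = logged[:, j]
        miss = np.isnan(x)
        if not miss.any():
            continue
        obs = x[~miss]
        if obs.size < 10:
            raise ValueError(f"sample {col!r} has fewer than 10 observed values; refusing to impute")
        mu = obs.mean() - shift * obs.std(ddof=1)
        sd = width * obs.std(ddof=1)
        draws = rng.normal(mu, sd, int(miss.sum()))
        logged[miss, j] = draws
    out = logged if log_input else 10 ** logged
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# permutation-FDR moderated t-test
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    """Per-feature log2 fold change, moderated statistic and permutation q."""

    table: pd.DataFrame  # columns log2fc, stat, q
    contrast: tuple[str, str]
    s0: float
    n_permutations: int


def _moderated_stat(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    """d = (meanA - meanB) / (pooled se + s0), rows are features."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return (ma - mb) / (se + s0)


def _distinct_permutations(na: int, nb: int, n_perm: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Label assignments (indices of group A) excluding the observed one.

    All distinct assignments are enumerated when there are fewer than
    ``n_perm``; otherwise assignments are sampled. With equal group sizes an
    assignment and its complement give mirror-image statistics (identical
    |d|), so only one member of each unordered partition is kept — without
    this the smallest attainable q would be 1/n_perm-bounded away from 0.
    """
    n = na + nb
    if na == nb:
        total = math.comb(n - 1, na - 1)
        if total - 1 <= n_perm:
            combos = [np.array((0, *c)) for c in itertools.combinations(range(1, n), na - 1)]
            observed = tuple(range(na))
            return [c for c in combos if tuple(c) != observed]
    else:
        total = math.comb(n, na)
        if total - 1 <= n_perm:
            combos = [np.array(c) for c in itertools.combinations(range(n), na)]
            observed = tuple(range(na))
            return [c for c in combos if tuple(c) != observed]
    return [np.sort(rng.permutation(n)[:na]) for _ in range(n_perm)]


def permutation_fdr_ttest(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    s0: float = DEFAULT_S0,
    n_perm: int = 10000,
    seed: int = 0,
    already_log: bool = True,
) -> DifferentialResult:
    """Moderated two-sample test with a label-permutation false discovery rate.

    q(feature) = (average permuted count of |d_perm| >= |d|) / (observed
    count of |d_obs| >= |d|), monotonized to be non-increasing in |d| and
    capped at 1. With few replicates, all distinct label assignments are
    used instead of random draws.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    rng = np.random.default_rng(seed)
    X = matrix[group_a + group_b].to_numpy(dtype=float)
    if not already_log:
        X = np.log2(X)
    na, nb = len(group_a), len(group_b)
    a, b = X[:, :na], X[:, na:]
    d_obs = _moderated_stat(a, b, s0)
    log2fc = a.mean(axis=1) - b.mean(axis=1)

    perms = _distinct_permutations(na, nb, n_perm, rng)
    abs_obs = np.abs(d_obs)
    order = np.argsort(abs_obs)
    sorted_abs = abs_obs[order]
    n_features = X.shape[0]
    # observed count of |d| >= threshold for each feature's own |d|
    obs_ge = n_features - np.searchsorted(sorted_abs, sorted_abs, side="left")
    null_counts = np.zeros(n_features)
    cols = np.arange(na + nb)
    for idx_a in perms:
        mask = np.zeros(na + nb, dtype=bool)
        mask[idx_a] = True
        d_p = _moderated_stat(X[:, cols[mask]], X[:, cols[~mask]], s0)
        abs_p = np.sort(np.abs(d_p))
        null_counts += n_features - np.searchsorted(abs_p, sorted_abs, side="left")
    mean_null = null_counts / max(len(perms), 1)
    q_sorted = np.minimum(mean_null / np.maximum(obs_ge, 1), 1.0)
    # monotonize: q non-increasing in |d| (running min over weaker features,
    # BH-style, so a more extreme statistic never reports a larger q)
    q_sorted = np.minimum.accumulate(q_sorted)
    q = np.empty(n_features)
    q[order] = q_sorted
    if not perms:
        q[:] = 1.0
    table = pd.DataFrame({"log2fc": log2fc, "stat": d_obs, "q": q}, index=matrix.index)
    return DifferentialResult(table=table, contrast=("A", "B"), s0=s0, n_permutations=len(perms))


# ---------------------------------------------------------------------------
# count matrices: normalization and shrunken fold changes
# ---------------------------------------------------------------------------


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Size factor = median across features of count / geometric-mean
    reference, over features with no zero count."""
    X = counts.to_numpy(dtype=float)
    nonzero = (X > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no feature has all-positive counts; cannot derive size factors")
    logX = np.log(X[nonzero])
    ref = logX.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logX - ref, axis=0))
    if (X.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts")
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass
class FoldChangeTable:
    table: pd.DataFrame  # log2fc, base_mean, stat, q, significant
    size_factors: pd.Series
    contrast: tuple[str, str]
    prior_count: float


def count_fold_changes(
    counts: pd.DataFrame,
    design: SampleDesign,
    contrast: tuple[str, str],
    prior_count: float = DEFAULT_PRIOR_COUNT,
    n_perm: int = 10000,
    q_cutoff: float = 0.05,
    s0: float = DEFAULT_S0,
    seed: int = 0,
) -> FoldChangeTable:
    """Normalized, noise-stabilized log2 fold changes for peak counts.

    Counts are scaled by median-of-ratios size factors; the fold change is
    log2((meanA + prior) / (meanB + prior)) so low-count noise is damped;
    significance comes from the permutation-FDR test on log2-normalized
    counts.
    """
    cond_a, cond_b = contrast
    sf = median_of_ratios_size_factors(counts)
    norm = counts / sf
    cols_a = design.samples_of(cond_a)
    cols_b = design.samples_of(cond_b)
    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    log2fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))
    log_norm = np.log2(norm + prior_count)
    diff = permutation_fdr_ttest(log_norm, cols_a, cols_b, s0=s0, n_perm=n_perm, seed=seed)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "base_mean": norm.mean(axis=1),
            "stat": diff.table["stat"],
            "q": diff.table["q"],
        },
        index=counts.index,
    )
    table["significant"] = table["q"] < q_cutoff
    return FoldChangeTable(table=table, size_factors=sf, contrast=contrast, prior_count=prior_count)


def signature_correlation(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    features: list[str],
    log_input: bool = False,
) -> pd.DataFrame:
    """Pearson r between every column pair across the two matrices, on log
    intensities restricted to a (significant) feature subset."""
    if len(features) < 3:
        raise ValueError("feature subset must have >= 3 members")
    A = matrix_a.loc[features].to_numpy(dtype=float)
    B = matrix_b.loc[features].to_numpy(dtype=float)
    if not log_input:
        A, B = np.log10(A), np.log10(B)
    out = np.full((matrix_a.shape[1], matrix_b.shape[1]), np.nan)
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            x, y = A[:, i], B[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            out[i, j] = np.corrcoef(x[ok], y[ok])[0, 1]
    return pd.DataFrame(out, index=matrix_a.columns, columns=matrix_b.columns)
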