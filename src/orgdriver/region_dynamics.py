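"""Genomic bookkeeping and the TAD-level coordinated-activity statistic.

Peak-set unions, fixed-width extension around peak centers, nearest-TSS
assignment with deterministic tie-breaks, TSS-proximal classification, and
the percentage-agreement statistic: per TAD, the share of member peaks whose
fold-change sign matches the sign of the TAD's mean fold change. Its null
distribution comes from shuffling fold changes across peaks (TAD membership
fixed), giving an empirical FDR and a significance cutoff.

All intervals are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_PEAKS = 20
DEFAULT_N_SHUFFLES = 100
DEFAULT_TSS_CUTOFF = 500


def _validate(intervals: pd.DataFrame) -> None:
    bad = (intervals["start"] < 0) | (intervals["start"] >= intervals["end"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"malformed interval at line {line}: require 0 <= start < end")


def peak_union(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals across the given sets.

    Output is sorted by (chrom, start); a ``sources`` column records which
    input sets contributed to each merged interval.
    """
    frames = []
    for i, df in enumerate(peak_sets):
        _validate(df)
        frames.append(df[["chrom", "start", "end"]].assign(_src=i))
    allp = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    )
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        cur_start = cur_end = None
        cur_src: set[int] = set()
        for r in grp.itertuples():
            if cur_start is None:
                cur_start, cur_end, cur_src = r.start, r.end, {r._4}
            elif r.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, r.end)
                cur_src.add(r._4)
            else:
                rows.append((chrom, cur_start, cur_end, ",".join(map(str, sorted(cur_src)))))
                cur_start, cur_end, cur_src = r.start, r.end, {r._4}
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, ",".join(map(str, sorted(cur_src)))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sources"])


def extend_to_width(
    intervals: pd.DataFrame, width: int = 1000, chrom_sizes: dict[str, int] | None = None
) -> pd.DataFrame:
    """Replace each interval by [center - w/2, center + w/2), clamped to the
    chromosome; center = floor((start + end) / 2)."""
    if width <= 0:
        raise ValueError("width must be > 0")
    out = intervals.copy()
    center = (out["start"] + out["end"]) // 2
    out["start"] = (center - width // 2).clip(lower=0)
    out["end"] = center + width - width // 2
    if chrom_sizes is not None:
        limits = out["chrom"].map(chrom_sizes)
        out["end"] = np.minimum(out["end"], limits)
    return out


def nearest_tss(intervals: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Assign each interval the gene whose TSS is closest to its midpoint.

    ``tss`` has columns chrom/tss (and its index is the gene id). Ties break
    to the smaller TSS coordinate, then the lexicographically smaller gene
    id. Intervals on chromosomes with no TSS get a missing assignment.
    Returns a frame indexed like ``intervals`` with gene/distance columns.
    """
    genes = []
    dists = []
    by_chrom = {}
    for chrom, grp in tss.groupby("chrom"):
        # sort by (coordinate, gene id) so ties resolve deterministically
        g = grp.iloc[np.lexsort((grp.index.to_numpy(), grp["tss"].to_numpy()))]
        by_chrom[chrom] = (g["tss"].to_numpy(), g.index.to_numpy())
    for r in intervals.itertuples():
        mid = (r.start + r.end) // 2
        if r.chrom not in by_chrom:
            logger.info("no TSS on %s; assignment missing", r.chrom)
            genes.append(None)
            dists.append(np.nan)
            continue
        pos, ids = by_chrom[r.chrom]
        k = np.searchsorted(pos, mid)
        best_idx, best_dist = None, None
        for cand in (k - 1, k):
            if 0 <= cand < pos.size:
                d = abs(int(pos[cand]) - mid)
                if best_dist is None or d < best_dist:
                    best_idx, best_dist = cand, d
                # on equal distance the earlier candidate (smaller coordinate) wins
        # genes sharing the winning coordinate: take the first occurrence,
        # which the (coordinate, id) sort makes the smallest gene id
        best_idx = int(np.searchsorted(pos, pos[best_idx], side="left"))
        genes.append(ids[best_idx])
        dists.append(best_dist)
    return pd.DataFrame({"gene": genes, "distance": dists}, index=intervals.index)


def classify_promoter_proximal(
    intervals: pd.DataFrame, tss: pd.DataFrame, cutoff: int = DEFAULT_TSS_CUTOFF
) -> pd.Series:
    """Label 'TSS-proximal' iff the nearest-TSS distance is strictly below
    ``cutoff`` base pairs, else 'distal'."""
    assign = nearest_tss(intervals, tss)
    labels = np.where(assign["distance"] < cutoff, "TSS-proximal", "distal")
    return pd.Series(labels, index=intervals.index, name="location")


# ---------------------------------------------------------------------------
# TAD percentage agreement
# ---------------------------------------------------------------------------


def assign_peaks_to_tads(peaks: pd.DataFrame, tads: pd.DataFrame) -> pd.Series:
    """TAD containing each peak's midpoint (NaN when none). TADs must not
    overlap within a chromosome."""
    out = pd.Series(index=peaks.index, dtype=object)
    for chrom, grp in tads.groupby("chrom"):
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping TADs on {chrom}")
        sel = peaks["chrom"] == chrom
        mids = ((peaks.loc[sel, "start"] + peaks.loc[sel, "end"]) // 2).to_numpy()
        k = np.searchsorted(starts, mids, side="right") - 1
        valid = (k >= 0) & (mids < ends[np.clip(k, 0, len(ends) - 1)])
        names = g["name"].to_numpy()
        vals = np.where(valid, names[np.clip(k, 0, len(names) - 1)], None)
        out.loc[sel] = vals
    return out


def _agreement(fc: np.ndarray, groups: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-TAD (n_peaks, mean FC, % agreement); zero-FC peaks
    count as disagreeing."""
    counts = np.bincount(groups, minlength=n_groups)
    sums = np.bincount(groups, weights=fc, minlength=n_groups)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    sign_match = np.sign(fc) == np.sign(means[groups])
    nonzero = np.sign(fc) != 0
    agree = np.bincount(groups, weights=(sign_match & nonzero).astype(float), minlength=n_groups)
    with np.errstate(invalid="ignore"):
        pct = 100.0 * agree / counts
    return counts, means, pct


def tad_agreement(
    peak_fc: pd.Series,
    peak_tad: pd.Series,
    min_peaks: int = DEFAULT_MIN_PEAKS,
) -> pd.DataFrame:
    """Percentage agreement per TAD.

    ``peak_fc`` is the per-peak log2 fold change and ``peak_tad`` the TAD
    assignment (same index). Only TADs with >= ``min_peaks`` peaks are
    reported; TADs whose mean fold change is exactly zero are skipped.
    Columns: n_peaks, mean_log2fc, agreement (0-100), direction.
    """
    ok = peak_tad.notna()
    fc = peak_fc.loc[ok.index[ok]].to_numpy(dtype=float)
    tad_codes, tad_names = pd.factorize(peak_tad[ok])
    counts, means, pct = _agreement(fc, tad_codes, len(tad_names))
    table = pd.DataFrame(
        {"n_peaks": counts, "mean_log2fc": means, "agreement": pct}, index=tad_names
    )
    table = table[table["n_peaks"] >= min_peaks]
    zero = table["mean_log2fc"] == 0
    if zero.any():
        logger.info("%d TADs skipped: mean fold change exactly 0", int(zero.sum()))
        table = table[~zero]
    table["direction"] = np.where(table["mean_log2fc"] > 0, "activated", "repressed")
    return table


def tad_empirical_fdr(
    table: pd.DataFrame,
    peak_fc: pd.Series,
    peak_tad: pd.Series,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    alpha: float = 0.05,
    min_peaks: int = DEFAULT_MIN_PEAKS,
) -> tuple[pd.DataFrame, float | None]:
    """Empirical FDR for the agreement statistic from genome-wide shuffles.

    Fold changes are permuted across all peaks (TAD membership fixed) and
    agreements recomputed; FDR(t) = mean over shuffles of the null TAD count
    at agreement >= t, divided by the observed count at >= t. The cutoff is
    the smallest observed agreement with FDR <= alpha; per-TAD FDRs are
    monotonized (non-increasing in agreement) and capped at 1. The shuffle
    null inherits the small-sample bias of the statistic (the reference sign
    is estimated from the same peaks), so the FDR stays calibrated.
    """
    if n_shuffles < 10:
        raise ValueError("n_shuffles must be >= 10")
    rng = np.random.default_rng(seed)
    ok = peak_tad.notna()
    fc = peak_fc.loc[ok.index[ok]].to_numpy(dtype=float)
    tad_codes, tad_names = pd.factorize(peak_tad[ok])
    n_tads = len(tad_names)
    keep = np.isin(tad_names, table.index)

    obs = table["agreement"].to_numpy(dtype=float)
    obs_sorted = np.sort(obs)
    null_ge = np.zeros_like(obs)
    for _ in range(n_shuffles):
        perm = rng.permutation(fc)
        counts, means, pct = _agreement(perm, tad_codes, n_tads)
        pct = pct[keep & (counts >= min_peaks) & (means != 0)]
        # count of null TADs with agreement >= each observed threshold
        null_sorted = np.sort(pct)
        null_ge += null_sorted.size - np.searchsorted(null_sorted, obs, side="left")
    mean_null = null_ge / n_shuffles
    obs_ge = obs_sorted.size - np.searchsorted(obs_sorted, obs, side="left")
    fdr = np.minimum(mean_null / np.maximum(obs_ge, 1), 1.0)
    # monotonize: FDR non-increasing as the agreement threshold rises
    # (running min from the lowest agreement up, BH-style)
    order = np.argsort(obs)
    fdr_sorted = np.minimum.accumulate(fdr[order])
    fdr_mono = np.empty_like(fdr)
    fdr_mono[order] = fdr_sorted
    out = table.copy()
    out["fdr"] = fdr_mono
    sig_levels = np.sort(obs[fdr_mono <= alpha])
    cutoff = float(sig_levels[0]) if sig_levels.size else None
    out["significant"] = fdr_mono <= alpha if cutoff is not None else False
    return out, cutoff
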