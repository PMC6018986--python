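"""Spike-in-anchored absolute quantification and protein-per-mRNA statistics.

Proteins: a two-stage calibration. Stage 1 regresses log10 known spike-in
amount on log10 iBAQ intensity in the unfractionated sample; stage 2 maps
the (deeper) fractionated intensities onto stage-1 absolute abundances via a
second log-log regression on shared proteins. mRNAs: a single log-log
regression of ERCC input amounts on counts. All calibrations are fitted per
sample, which makes copy numbers invariant to rescaling any one sample's
intensities.

Ratios: protein copies per mRNA molecule, taken as the median over all
replicate-pair ratios within a condition; a Fisher-z t-test compares
within- vs between-condition ratio-vector correlations (a global
translation/degradation difference test), and a restricted-df Welch test
compares per-feature ratios between conditions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_data import SampleDesign, SpikeInPanel

logger = logging.getLogger(__name__)

MIN_SPIKEINS = 5
MIN_SHARED_FEATURES = 50
FISHER_Z_CLIP = np.arctanh(1.0 - 1e-12)


@dataclass
class SpikeinFit:
    """Per-sample affine maps log10(intensity) -> log10(amount)."""

    params: pd.DataFrame  # sample -> slope, intercept, r2, n, ok

    def apply(self, intensities: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for s in intensities.columns:
            p = self.params.loc[s]
            logi = np.log10(intensities[s].to_numpy(dtype=float))
            out[s] = 10 ** (p["slope"] * logi + p["intercept"])
        return pd.DataFrame(out, index=intensities.index)


@dataclass
class CopyNumberTable:
    """Absolute molecules-per-cell estimates with calibration provenance."""

    values: pd.DataFrame  # feature x sample, NaN where undefined
    calibration: dict = field(default_factory=dict)
    provenance: str = ""


def fit_spikein_regression(intensities: pd.DataFrame, panel: SpikeInPanel) -> SpikeinFit:
    """OLS of log10 known amount on log10 intensity, per sample, over the
    detected spike-ins. Refuses with <5 detected spike-ins; a non-positive
    slope is flagged as a calibration failure."""
    amounts = panel.amounts
    rows = {}
    for s in intensities.columns:
        obs = intensities.loc[intensities.index.intersection(amounts.index), s].dropna()
        obs = obs[obs > 0]
        if len(obs) < MIN_SPIKEINS:
            raise ValueError(f"sample {s!r}: only {len(obs)} spike-ins detected (need >= {MIN_SPIKEINS})")
        amt = amounts.loc[obs.index]
        if np.log10(amt.max() / amt.min()) < 2:
            raise ValueError(f"sample {s!r}: detected spike-ins span < 2 orders of magnitude")
        res = stats.linregress(np.log10(obs.to_numpy()), np.log10(amt.to_numpy()))
        ok = res.slope > 0
        if not ok:
            logger.warning("sample %s: calibration failure (slope %.3f <= 0)", s, res.slope)
        rows[s] = {
            "slope": res.slope,
            "intercept": res.intercept,
            "r2": res.rvalue**2,
            "n": len(obs),
            "ok": ok,
        }
    params = pd.DataFrame.from_dict(rows, orient="index")
    params = params.astype({"slope": float, "intercept": float, "r2": float, "n": int, "ok": bool})
    return SpikeinFit(params=params)


def absolute_quant_two_stage(
    unfractionated: pd.DataFrame,
    fractionated: pd.DataFrame,
    panel: SpikeInPanel,
) -> CopyNumberTable:
    """Protein copy numbers from the two-stage spike-in calibration.

    Because the stage-2 map is fitted per sample on the log-log scale, any
    multiplicative rescaling of a sample is absorbed by its intercept.
    Stage-2 R^2 below 0.5 is logged as a warning but the result is returned.
    """
    spike_ids = [i for i in panel.ids if i in unfractionated.index]
    stage1_fit = fit_spikein_regression(unfractionated.loc[spike_ids], panel)
    feature_rows = unfractionated.index.difference(panel.ids)
    stage1_abund = stage1_fit.apply(unfractionated.loc[feature_rows])

    frac_features = fractionated.index.difference(panel.ids)
    out = {}
    stage2_rows = {}
    for s in fractionated.columns:
        shared = stage1_abund.index.intersection(frac_features)
        x = np.log10(fractionated.loc[shared, s].to_numpy(dtype=float))
        y = np.log10(stage1_abund.loc[shared, s].to_numpy(dtype=float))
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < MIN_SHARED_FEATURES:
            raise ValueError(
                f"sample {s!r}: only {int(ok.sum())} shared features between stages (need >= {MIN_SHARED_FEATURES})"
            )
        res = stats.linregress(x[ok], y[ok])
        r2 = res.rvalue**2
        if r2 < 0.5:
            logger.warning("sample %s: stage-2 R^2 %.2f < 0.5", s, r2)
        logi = np.log10(fractionated.loc[frac_features, s].to_numpy(dtype=float))
        out[s] = 10 ** (res.slope * logi + res.intercept)
        stage2_rows[s] = {"slope": res.slope, "intercept": res.intercept, "r2": r2, "n": int(ok.sum())}
    values = pd.DataFrame(out, index=frac_features)
    return CopyNumberTable(
        values=values,
        calibration={
            "stage1": stage1_fit.params.to_dict(orient="index"),
            "stage2": pd.DataFrame(stage2_rows).T.to_dict(orient="index"),
        },
        provenance="two-stage spike-in regression",
    )


def mrna_absolute_quant(counts: pd.DataFrame, ercc_panel: SpikeInPanel) -> CopyNumberTable:
    """mRNA copies from a single log-log regression of counts on ERCC input.

    Features with zero counts in a sample get an undefined (NaN) copy
    number, not zero."""
    spike_rows = counts.loc[counts.index.intersection(ercc_panel.ids)]
    fit = fit_spikein_regression(spike_rows.where(spike_rows > 0), ercc_panel)
    features = counts.index.difference(ercc_panel.ids)
    feat = counts.loc[features].where(counts.loc[features] > 0)
    values = fit.apply(feat)
    return CopyNumberTable(
        values=values,
        calibration={"stage1": fit.params.to_dict(orient="index")},
        provenance="ERCC single-stage regression",
    )


# ---------------------------------------------------------------------------
# protein-per-mRNA ratios
# ---------------------------------------------------------------------------


def protein_per_mrna(
    protein: CopyNumberTable,
    mrna: CopyNumberTable,
    design: SampleDesign,
    condition: str,
) -> pd.DataFrame:
    """Median over all replicate pairs (i, j) of protein_i / mrna_j, per
    feature. Features missing in either layer get no entry."""
    p_cols = [c for c in design.samples_of(condition) if c in protein.values.columns]
    m_cols = [c for c in design.samples_of(condition) if c in mrna.values.columns]
    if len(p_cols) < 2 or len(m_cols) < 2:
        raise ValueError("need >= 2 replicates in each layer for the condition")
    common = protein.values.index.intersection(mrna.values.index)
    P = protein.values.loc[common, p_cols].to_numpy(dtype=float)
    M = mrna.values.loc[common, m_cols].to_numpy(dtype=float)
    ratios = P[:, :, None] / M[:, None, :]  # feature x protein-rep x mrna-rep
    flat = ratios.reshape(len(common), -1)
    n_pairs = np.isfinite(flat).sum(axis=1)
    med = np.full(len(common), np.nan)
    any_pair = n_pairs > 0
    if any_pair.any():
        med[any_pair] = np.nanmedian(flat[any_pair], axis=1)
    out = pd.DataFrame({"ratio": med, "n_pairs": n_pairs}, index=common)
    return out[(out["n_pairs"] > 0) & np.isfinite(out["ratio"])]


def replicate_ratio_matrix(
    protein: CopyNumberTable,
    mrna: CopyNumberTable,
    design: SampleDesign,
    condition: str,
) -> pd.DataFrame:
    """Matched-replicate log10 protein/mRNA ratio vectors (feature x replicate)."""
    cols = design.samples_of(condition)
    common = protein.values.index.intersection(mrna.values.index)
    out = {}
    for c in cols:
        out[c] = np.log10(protein.values.loc[common, c] / mrna.values.loc[common, c])
    df = pd.DataFrame(out, index=common)
    return df.dropna()


def _pairwise_log_ratios(
    protein: CopyNumberTable, mrna: CopyNumberTable, design: SampleDesign, condition: str
) -> pd.DataFrame:
    """All replicate-pair log10 ratios (feature x nP*nM pairs), NaN-free rows only."""
    p_cols = design.samples_of(condition)
    m_cols = design.samples_of(condition)
    common = protein.values.index.intersection(mrna.values.index)
    cols = {}
    for pc, mc in itertools.product(p_cols, m_cols):
        cols[f"{pc}/{mc}"] = np.log10(protein.values.loc[common, pc] / mrna.values.loc[common, mc])
    return pd.DataFrame(cols, index=common)


def global_translation_test(ratios_a: pd.DataFrame, ratios_b: pd.DataFrame) -> float:
    """t-test on Fisher-transformed Pearson correlations of replicate
    log-ratio vectors: within-condition pairs vs between-condition pairs.

    A significant p indicates global translation/degradation differences
    between the two conditions beyond replicate noise. Correlations of
    exactly +/-1 are clipped before the atanh transform.
    """
    common = ratios_a.index.intersection(ratios_b.index)
    A = ratios_a.loc[common].to_numpy(dtype=float)
    B = ratios_b.loc[common].to_numpy(dtype=float)

    def corr(x, y):
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= 1.0 - 1e-12:
            logger.warning("correlation at +/-1 clipped before Fisher transform")
            r = np.sign(r) * (1.0 - 1e-12)
        return np.arctanh(r)

    within = [corr(A[:, i], A[:, j]) for i, j in itertools.combinations(range(A.shape[1]), 2)]
    within += [corr(B[:, i], B[:, j]) for i, j in itertools.combinations(range(B.shape[1]), 2)]
    between = [corr(A[:, i], B[:, j]) for i in range(A.shape[1]) for j in range(B.shape[1])]
    if len(within) < 2 or len(between) < 2:
        raise ValueError("need >= 2 within-group and >= 2 between-group correlations")
    return float(stats.ttest_ind(within, between).pvalue)


def ratio_change_test(
    protein: CopyNumberTable,
    mrna: CopyNumberTable,
    design: SampleDesign,
    condition_a: str,
    condition_b: str,
    df_override: int | None = None,
) -> pd.DataFrame:
    """Per-feature Welch test on log pairwise ratios with restricted df.

    The replicate pairs within a condition are statistically dependent (each
    replicate enters several pairs), so the degrees of freedom are set to
    (n_repA - 1) + (n_repB - 1) — the number of independent biological
    replicates — rather than the pair count. Columns: log2_ratio_fc, stat,
    p, q (Benjamini-Hochberg). Features with zero variance in both groups
    are skipped (NaN statistic, excluded from the FDR).
    """
    ra = _pairwise_log_ratios(protein, mrna, design, condition_a)
    rb = _pairwise_log_ratios(protein, mrna, design, condition_b)

    def _per_condition(R: pd.DataFrame):
        # observed replicate counts per layer (a missing replicate voids its pairs)
        nrep = design.replicates_per_condition
        vals = R.to_numpy(dtype=float).reshape(len(R), nrep, nrep)
        n_p = np.isfinite(vals).any(axis=2).sum(axis=1)
        n_m = np.isfinite(vals).any(axis=1).sum(axis=1)
        flat = vals.reshape(len(R), -1)
        m = np.full(len(R), np.nan)
        v = np.full(len(R), np.nan)
        enough = np.isfinite(flat).sum(axis=1) >= 2
        if enough.any():
            m[enough] = np.nanmean(flat[enough], axis=1)
            v[enough] = np.nanvar(flat[enough], axis=1, ddof=1)
        return m, v, np.minimum(n_p, n_m)

    common = ra.index.intersection(rb.index)
    ma, va, neff_a = _per_condition(ra.loc[common])
    mb, vb, neff_b = _per_condition(rb.loc[common])
    usable = (neff_a >= 2) & (neff_b >= 2)
    common = common[usable]
    ma, va, neff_a = ma[usable], va[usable], neff_a[usable]
    mb, vb, neff_b = mb[usable], vb[usable], neff_b[usable]
    # the pairwise ratios are dependent: their sample variance estimates
    # sigma_P^2 + sigma_M^2, and the variance of the mean ratio is that
    # divided by the number of independent biological replicates (the
    # smaller observed layer count, conservatively), not by the pair count
    se = np.sqrt(va / neff_a + vb / neff_b)
    degenerate = (va == 0) & (vb == 0)
    if degenerate.any():
        logger.info("%d features skipped: zero within-group variance in both groups", int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (ma - mb) / se, 0.0)
    t = np.where(degenerate, np.nan, t)
    # equal ratio sets -> statistic exactly 0, p exactly 1
    t = np.where((se > 0) & (ma == mb), 0.0, t)
    df = df_override if df_override is not None else (design.replicates_per_condition - 1) * 2
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    log2fc = (ma - mb) / np.log10(2.0)  # ratios are log10; convert the shift to log2
    return pd.DataFrame(
        {"log2_ratio_fc": log2fc, "stat": t, "p": p, "q": q, "df": float(df)}, index=common
    )


def ratio_significance_filter(
    test_a_vs_ref: pd.DataFrame,
    test_b_vs_ref: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    fold_cutoff: float = 3.0,
) -> pd.Index:
    """Features with FDR < cutoff AND |ratio fold change| > cutoff in BOTH
    comparisons against the reference condition, with consistent direction."""
    common = test_a_vs_ref.index.intersection(test_b_vs_ref.index)
    a = test_a_vs_ref.loc[common]
    b = test_b_vs_ref.loc[common]
    lfc = np.log2(fold_cutoff)
    flag = (
        (a["q"] < fdr_cutoff)
        & (b["q"] < fdr_cutoff)
        & (a["log2_ratio_fc"].abs() > lfc)
        & (b["log2_ratio_fc"].abs() > lfc)
        & (np.sign(a["log2_ratio_fc"]) == np.sign(b["log2_ratio_fc"]))
    )
    return common[flag.to_numpy(dtype=bool)]
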