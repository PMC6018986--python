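"""Motif-driver selection: which TF motifs explain epigenome dynamics.

The inference chain: restrict a PWM database to motifs whose linked TFs are
differentially expressed at the protein level (FDR < 0.01); score every
candidate motif under the significantly changing peaks (best-match log-odds,
both strands); pre-select predictors with 10-fold cross-validated LASSO;
then iteratively fit random-forest regressions of the (residual) fold change
on the remaining motif scores, each round keeping the motif with the highest
out-of-bag permutation importance (%IncMSE), subtracting the variance a
single-motif forest explains, and stopping once the best single motif can no
longer predict any residual variance (out-of-bag R^2 <= 0). The whole
procedure is repeated with independent seeds and only motifs selected every
time are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
    _BASE_INDEX[_b + 32] = _i  # lowercase


@dataclass(frozen=True)
class PWM:
    """Position weight matrix of base probabilities (L x 4, columns ACGT)."""

    id: str
    matrix: np.ndarray
    tfs: tuple[str, ...] = ()

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if mat.shape[0] < 4:
            raise ValueError("PWM must be at least 4 positions long")
        if (mat < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, background: np.ndarray | None = None, pseudocount: float = 1e-3) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        p = (self.matrix + pseudocount) / (1.0 + 4.0 * pseudocount)
        return np.log2(p / bg)

    def consensus_score(self, **kw) -> float:
        """Log-odds score of the consensus sequence (the maximum attainable)."""
        return float(self.log_odds(**kw).max(axis=1).sum())


def encode_sequence(seq: str) -> np.ndarray:
    codes = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def scan_best_match(
    sequence: str | np.ndarray,
    pwm: PWM,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> float:
    """Best-match log-odds score over all offsets and both strands.

    Returns NaN when the sequence is shorter than the motif.
    """
    codes = sequence if isinstance(sequence, np.ndarray) else encode_sequence(sequence)
    L = pwm.length
    if codes.size < L:
        return float("nan")
    lo = pwm.log_odds(background, pseudocount)
    # scoring the reverse strand == scanning with the reverse-complement PWM
    lo_rc = lo[::-1, ::-1]
    windows = sliding_window_view(codes, L)
    pos = np.arange(L)
    fwd = lo[pos, windows].sum(axis=1)
    rev = lo_rc[pos, windows].sum(axis=1)
    return float(max(fwd.max(), rev.max()))


@dataclass
class MotifScoreMatrix:
    """Per-peak best-match scores: raw log-odds and per-motif min-max normalized."""

    raw: pd.DataFrame  # peaks x motifs
    normalized: pd.DataFrame


def score_peaks(
    sequences: Sequence[str],
    pwms: Sequence[PWM],
    peak_ids: Sequence[str] | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = 1e-3,
) -> MotifScoreMatrix:
    """Best-match score of every PWM under every peak sequence (vectorized)."""
    ids = list(peak_ids) if peak_ids is not None else [f"peak{i}" for i in range(len(sequences))]
    codes = [encode_sequence(s) for s in sequences]
    lens = np.array([c.size for c in codes])
    raw = np.full((len(sequences), len(pwms)), np.nan)
    by_len: dict[int, np.ndarray] = {}
    for ln in np.unique(lens):
        by_len[int(ln)] = np.flatnonzero(lens == ln)
    blocks = {ln: np.stack([codes[i] for i in idx]) for ln, idx in by_len.items()}
    for mi, pwm in enumerate(pwms):
        L = pwm.length
        lo = pwm.log_odds(background, pseudocount).astype(np.float32)
        lo_rc = lo[::-1, ::-1]
        for ln, idx in by_len.items():
            if ln < L:
                continue
            block = blocks[ln]  # (n, ln) int8
            n_off = ln - L + 1
            acc_f = np.zeros((len(idx), n_off), dtype=np.float32)
            acc_r = np.zeros_like(acc_f)
            for j in range(L):
                col = block[:, j : j + n_off]
                acc_f += lo[j].take(col)
                acc_r += lo_rc[j].take(col)
            raw[idx, mi] = np.maximum(acc_f.max(axis=1), acc_r.max(axis=1))
    raw_df = pd.DataFrame(raw, index=ids, columns=[p.id for p in pwms])
    lo_, hi = raw_df.min(axis=0), raw_df.max(axis=0)
    span = (hi - lo_).replace(0.0, np.nan)
    norm = ((raw_df - lo_) / span).fillna(0.0)
    return MotifScoreMatrix(raw=raw_df, normalized=norm)


# ---------------------------------------------------------------------------
# candidate filtering and labeling
# ---------------------------------------------------------------------------


def filter_motifs_by_tf_dynamics(
    motif_ids: Iterable[str],
    tf_map: pd.DataFrame,
    protein_diff: pd.DataFrame,
    fdr_cutoff: float = 0.01,
) -> list[str]:
    """Keep motifs with at least one linked TF at protein q < fdr_cutoff (strict).

    ``tf_map`` has columns motif/tf; ``protein_diff`` is indexed by TF with a
    ``q`` column. Motifs with no scored link are dropped.
    """
    q = protein_diff["q"]
    keep = []
    for m in motif_ids:
        links = tf_map.loc[tf_map["motif"] == m, "tf"]
        scored = q.reindex(links).dropna()
        if not scored.empty and (scored < fdr_cutoff).any():
            keep.append(m)
    return keep


def label_tf(motif_id: str, tf_map: pd.DataFrame, protein_diff: pd.DataFrame) -> str | None:
    """The linked TF with the most significant protein change.

    Ties on q go to the larger |log2fc|, then lexicographic TF id.
    """
    links = tf_map.loc[tf_map["motif"] == motif_id, "tf"]
    sub = protein_diff.reindex(links).dropna(subset=["q"])
    if sub.empty:
        return None
    sub = sub.assign(_absfc=sub["log2fc"].abs())
    sub = sub.sort_values(["q", "_absfc"], ascending=[True, False], kind="mergesort")
    best_q = sub["q"].iloc[0]
    best_fc = sub["_absfc"].iloc[0]
    tied = sub[(sub["q"] == best_q) & (sub["_absfc"] == best_fc)]
    return sorted(tied.index)[0]


def motif_fc_correlation(scores: pd.Series, response: pd.Series) -> float:
    """Pearson r of normalized best score vs log2FC; NaN for constant input."""
    x = scores.to_numpy(dtype=float)
    y = response.to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# LASSO pre-selection
# ---------------------------------------------------------------------------


def lasso_preselect(
    scores: pd.DataFrame,
    response: pd.Series,
    folds: int = 10,
    seed: int = 0,
) -> list[str]:
    """Motifs with nonzero coefficient in an L1 path at the minimum-CV-error penalty."""
    if len(scores) < folds * 3:
        raise ValueError("need at least 3 x folds observations")
    y = response.loc[scores.index].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return []
    X = scores.to_numpy(dtype=float)
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.any():
        return []
    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=100, max_iter=10000, random_state=seed)
    model.fit(Xs, y)
    cols = scores.columns[usable]
    return [c for c, b in zip(cols, model.coef_) if b != 0.0]


# ---------------------------------------------------------------------------
# iterative random-forest residual-variance selection
# ---------------------------------------------------------------------------


def _bootstrap_oob_masks(forest: RandomForestRegressor, n: int) -> list[np.ndarray]:
    """Out-of-bag sample masks per tree (reproduces the forest's bootstrap)."""
    masks = []
    for tree in forest.estimators_:
        rs = np.random.RandomState(tree.random_state)
        sampled = rs.randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        masks.append(mask)
    return masks


def oob_permutation_importance(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """R-randomForest-style %IncMSE: per tree, the relative increase in
    out-of-bag MSE when one predictor's OOB values are permuted; returns
    (mean, sd) over trees, in percent."""
    rng = np.random.default_rng(seed)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    n, p = X32.shape
    masks = _bootstrap_oob_masks(forest, n)
    inc = np.zeros((len(forest.estimators_), p))
    for t, (tree, mask) in enumerate(zip(forest.estimators_, masks)):
        if not mask.any():
            continue
        Xo = X32[mask]
        yo = y[mask]
        base = np.mean((tree.predict(Xo, check_input=False) - yo) ** 2)
        if base == 0:
            base = np.finfo(float).tiny
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(Xo.shape[0]), j]
            err = np.mean((tree.predict(Xp, check_input=False) - yo) ** 2)
            inc[t, j] = (err - base) / base
    return 100.0 * inc.mean(axis=0), 100.0 * inc.std(axis=0)


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int,
                max_features, oob: bool) -> RandomForestRegressor:
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        min_samples_leaf=5,
        bootstrap=True,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


@dataclass
class SelectionResult:
    """Ordered driver motifs with diagnostics and cross-repeat stability."""

    table: pd.DataFrame  # motif, order, pct_inc_mse, sd_inc_mse, single_r2, stability
    final: list[str] = field(default_factory=list)
    repeats: int = 1


STOPPING_R2 = 0.01  # a motif must explain >1% of residual variance out-of-bag


def iterative_rf_select(
    scores: pd.DataFrame,
    response: pd.Series,
    n_trees: int = 5000,
    seed: int = 0,
    max_features: float = 1.0 / 3.0,
    stopping_r2: float = STOPPING_R2,
) -> SelectionResult:
    """One repeat of the residual-variance selection loop.

    Each round fits a forest of the current residual on the remaining motif
    scores, takes the motif with the highest OOB-permutation %IncMSE, and
    checks whether a single-predictor forest on that motif alone still
    explains residual variance out-of-bag. If yes, the motif is recorded,
    its single-forest OOB predictions are subtracted from the residual and
    it is removed from the matrix; if not, the loop stops without selecting
    it. "Explains residual variance" means OOB R^2 above ``stopping_r2``
    (default 1%): demanding any positive value would admit predictors whose
    contribution is within the sequence-crosstalk floor of best-match
    scoring, where inserting one motif's site perturbs every other motif's
    maximum by a sliver.
    """
    remaining = list(scores.columns)
    residual = response.loc[scores.index].to_numpy(dtype=float).copy()
    rows = []
    rng = np.random.default_rng(seed)
    order = 0
    while len(remaining) >= 2:
        X = scores[remaining].to_numpy(dtype=float)
        forest_seed = int(rng.integers(2**31))
        forest = _fit_forest(X, residual, n_trees, forest_seed, max_features, oob=False)
        imp, sd = oob_permutation_importance(forest, X, residual, seed=int(rng.integers(2**31)))
        best = int(np.argmax(imp))
        motif = remaining[best]
        x_single = scores[[motif]].to_numpy(dtype=float)
        single = _fit_forest(x_single, residual, n_trees, int(rng.integers(2**31)), 1.0, oob=True)
        r2 = float(single.oob_score_)
        if r2 <= stopping_r2:
            break
        order += 1
        rows.append(
            {
                "motif": motif,
                "order": order,
                "pct_inc_mse": float(imp[best]),
                "sd_inc_mse": float(sd[best]),
                "single_r2": r2,
            }
        )
        pred = np.asarray(single.oob_prediction_, dtype=float)
        pred[~np.isfinite(pred)] = residual.mean()
        residual = residual - pred
        remaining.remove(motif)
    table = pd.DataFrame(rows, columns=["motif", "order", "pct_inc_mse", "sd_inc_mse", "single_r2"])
    table["stability"] = 1
    return SelectionResult(table=table, final=list(table["motif"]), repeats=1)


def stability_select(
    scores: pd.DataFrame,
    response: pd.Series,
    repeats: int = 5,
    seed: int = 0,
    n_trees: int = 5000,
    folds: int = 10,
    use_lasso: bool = True,
) -> SelectionResult:
    """LASSO + iterative forest selection repeated with independent seeds;
    only motifs selected in every repeat make the final set."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(repeats)]
    per_repeat: list[pd.DataFrame] = []
    for r, rs in enumerate(child_seeds):
        if use_lasso:
            candidates = lasso_preselect(scores, response, folds=folds, seed=rs)
        else:
            candidates = list(scores.columns)
        if len(candidates) == 0:
            per_repeat.append(pd.DataFrame(columns=["motif", "order", "pct_inc_mse", "sd_inc_mse", "single_r2"]))
            continue
        if len(candidates) == 1:
            # degenerate: a single candidate is kept if it alone predicts variance
            sub = scores[candidates]
            single = _fit_forest(sub.to_numpy(dtype=float), response.loc[sub.index].to_numpy(dtype=float),
                                 n_trees, rs, 1.0, oob=True)
            if single.oob_score_ > STOPPING_R2:
                per_repeat.append(pd.DataFrame([{"motif": candidates[0], "order": 1,
                                                 "pct_inc_mse": np.nan, "sd_inc_mse": np.nan,
                                                 "single_r2": float(single.oob_score_)}]))
            else:
                per_repeat.append(pd.DataFrame(columns=["motif", "order", "pct_inc_mse", "sd_inc_mse", "single_r2"]))
            continue
        res = iterative_rf_select(scores[candidates], response, n_trees=n_trees, seed=rs)
        per_repeat.append(res.table)
    counts: dict[str, int] = {}
    for tab in per_repeat:
        for m in tab["motif"]:
            counts[m] = counts.get(m, 0) + 1
    all_rows = pd.concat([t for t in per_repeat if len(t)], ignore_index=True) if counts else pd.DataFrame(
        columns=["motif", "order", "pct_inc_mse", "sd_inc_mse", "single_r2"])
    if counts:
        agg = all_rows.groupby("motif").agg(
            order=("order", "mean"),
            pct_inc_mse=("pct_inc_mse", "mean"),
            sd_inc_mse=("sd_inc_mse", "mean"),
            single_r2=("single_r2", "mean"),
        )
        agg["stability"] = pd.Series(counts)
        agg = agg.sort_values(["stability", "order"], ascending=[False, True]).reset_index()
    else:
        agg = pd.DataFrame(columns=["motif", "order", "pct_inc_mse", "sd_inc_mse", "single_r2", "stability"])
    final = list(agg.loc[agg["stability"] == repeats, "motif"]) if len(agg) else []
    return SelectionResult(table=agg, final=final, repeats=repeats)


# ---------------------------------------------------------------------------
# promoter scan
# ---------------------------------------------------------------------------


def promoter_motif_fraction(
    genes: Sequence[str],
    gene_table: pd.DataFrame,
    genome_chromosomes: dict[str, str],
    pwm: PWM,
    score_threshold: float,
    window: int = 500,
) -> float:
    """Fraction of genes whose promoter window ([TSS - w/2, TSS + w/2))
    best-match score reaches ``score_threshold``."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    half = window // 2
    n_hit = 0
    for g in genes:
        row = gene_table.loc[g]
        seq = genome_chromosomes[row["chrom"]]
        start = max(int(row["tss"]) - half, 0)
        end = min(int(row["tss"]) + half, len(seq))
        score = scan_best_match(seq[start:end], pwm)
        if np.isfinite(score) and score >= score_threshold:
            n_hit += 1
    return n_hit / len(genes)


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------


def peak_sequences(peaks: pd.DataFrame, chromosomes: dict[str, str]) -> list[str]:
    return [chromosomes[r.chrom][int(r.start): int(r.end)] for r in peaks.itertuples()]


def select_drivers(
    scores: MotifScoreMatrix,
    fold_changes: pd.DataFrame,
    tf_map: pd.DataFrame,
    protein_diff: pd.DataFrame,
    significant_only: bool = True,
    fdr_cutoff: float = 0.01,
    repeats: int = 5,
    n_trees: int = 5000,
    seed: int = 0,
) -> SelectionResult:
    """Full selection on a scored peak set: TF-dynamics filter -> restriction
    to significant peaks -> stability selection -> TF labels + correlations."""
    candidates = filter_motifs_by_tf_dynamics(scores.normalized.columns, tf_map, protein_diff, fdr_cutoff)
    fc = fold_changes
    if significant_only and "significant" in fc.columns:
        fc = fc[fc["significant"]]
    common = fc.index.intersection(scores.normalized.index)
    X = scores.normalized.loc[common, candidates]
    y = fc.loc[common, "log2fc"]
    if len(candidates) == 0 or len(common) < 30:
        return SelectionResult(
            table=pd.DataFrame(columns=["motif", "order", "pct_inc_mse", "sd_inc_mse",
                                        "single_r2", "stability", "correlation", "tf"]),
            final=[], repeats=repeats,
        )
    result = stability_select(X, y, repeats=repeats, seed=seed, n_trees=n_trees)
    tab = result.table
    tab["correlation"] = [motif_fc_correlation(X[m], y) for m in tab["motif"]]
    tab["tf"] = [label_tf(m, tf_map, protein_diff) for m in tab["motif"]]
    return SelectionResult(table=tab, final=result.final, repeats=repeats)
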