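"""PWM scanning, candidate filtering, LASSO + iterative forest selection."""

import numpy as np
import pandas as pd
import pytest

from orgdriver import motif_driver_selection as mds

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP[c] for c in reversed(s))


def brute_force_best_match(seq, pwm, pseudocount=1e-3):
    """Exhaustive two-strand enumeration oracle, scalar arithmetic only."""
    lo = np.log2((pwm.matrix + pseudocount) / (1 + 4 * pseudocount) / 0.25)
    best = -np.inf
    for strand_seq in (seq, revcomp(seq)):
        codes = ["ACGT".index(c) for c in strand_seq]
        for off in range(len(seq) - pwm.length + 1):
            s = sum(lo[j, codes[off + j]] for j in range(pwm.length))
            best = max(best, s)
    return best


def random_pwm(rng, length=None):
    L = length or int(rng.integers(4, 12))
    mat = rng.dirichlet(np.ones(4), size=L)
    return mds.PWM(id="m", matrix=mat)


class TestPwmType:
    def test_row_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            mds.PWM(id="x", matrix=np.full((6, 4), 0.3))

    def test_min_length(self):
        with pytest.raises(ValueError):
            mds.PWM(id="x", matrix=np.full((3, 4), 0.25))


class TestScanBestMatch:
    def test_uniform_pwm_scores_zero(self, rng):
        pwm = mds.PWM(id="u", matrix=np.full((8, 4), 0.25))
        seq = "".join(rng.choice(list("ACGT"), 50))
        score = mds.scan_best_match(seq, pwm, pseudocount=0.0)
        np.testing.assert_allclose(score, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        """200 random (sequence, PWM) pairs vs exhaustive enumeration."""
        for _ in range(200):
            pwm = random_pwm(rng)
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(pwm.length, 40))))
            np.testing.assert_allclose(
                mds.scan_best_match(seq, pwm), brute_force_best_match(seq, pwm), atol=1e-9)

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng)
            seq = "".join(rng.choice(list("ACGT"), 60))
            np.testing.assert_allclose(
                mds.scan_best_match(seq, pwm), mds.scan_best_match(revcomp(seq), pwm), atol=1e-9)

    def test_short_sequence_is_missing(self):
        pwm = mds.PWM(id="u", matrix=np.full((8, 4), 0.25))
        assert np.isnan(mds.scan_best_match("ACG", pwm))

    def test_adding_consensus_site_never_decreases_score(self, rng):
        for _ in range(20):
            pwm = random_pwm(rng)
            consensus = "".join("ACGT"[i] for i in pwm.matrix.argmax(axis=1))
            seq = "".join(rng.choice(list("ACGT"), 40))
            assert mds.scan_best_match(seq + consensus, pwm) >= mds.scan_best_match(seq, pwm) - 1e-9
            np.testing.assert_allclose(
                mds.scan_best_match(seq + consensus, pwm), pwm.consensus_score(), atol=1e-9)

    def test_batch_scanner_agrees_with_scalar(self, rng):
        pwms = [random_pwm(rng) for _ in range(4)]
        seqs = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(30)]
        batch = mds.score_peaks(seqs, pwms)
        for i in (0, 7, 29):
            for j, pwm in enumerate(pwms):
                np.testing.assert_allclose(batch.raw.iloc[i, j], mds.scan_best_match(seqs[i], pwm), atol=1e-4)
        assert ((batch.normalized >= 0) & (batch.normalized <= 1)).all().all()


class TestCandidateFiltering:
    def _diff(self, qs, fcs=None):
        fcs = fcs if fcs is not None else [1.0] * len(qs)
        return pd.DataFrame({"q": qs, "log2fc": fcs}, index=[f"TF{i}" for i in range(len(qs))])

    def test_strict_fdr_cutoff(self):
        tf_map = pd.DataFrame({"motif": ["m0", "m1", "m2"], "tf": ["TF0", "TF1", "TF2"]})
        diff = self._diff([0.005, 0.01, 0.5])
        assert mds.filter_motifs_by_tf_dynamics(["m0", "m1", "m2"], tf_map, diff) == ["m0"]

    def test_any_significant_link_keeps_motif(self):
        tf_map = pd.DataFrame({"motif": ["m0", "m0"], "tf": ["TF0", "TF1"]})
        diff = self._diff([0.5, 0.002])
        assert mds.filter_motifs_by_tf_dynamics(["m0"], tf_map, diff) == ["m0"]

    def test_unlinked_motif_dropped(self):
        tf_map = pd.DataFrame({"motif": ["m0"], "tf": ["TFX"]})
        diff = self._diff([0.001])
        assert mds.filter_motifs_by_tf_dynamics(["m0"], tf_map, diff) == []

    def test_label_tf_most_significant(self):
        tf_map = pd.DataFrame({"motif": ["m0", "m0"], "tf": ["TF0", "TF1"]})
        diff = self._diff([0.2, 1e-6])
        assert mds.label_tf("m0", tf_map, diff) == "TF1"

    def test_label_tf_tie_breaks_on_abs_fold_change(self):
        tf_map = pd.DataFrame({"motif": ["m0", "m0"], "tf": ["TF0", "TF1"]})
        diff = self._diff([0.01, 0.01], fcs=[1.0, 3.0])
        assert mds.label_tf("m0", tf_map, diff) == "TF1"


class TestLassoPreselect:
    def test_planted_linear_signal_recovered(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(0, 1, (n, 21)), columns=[f"m{i}" for i in range(21)])
        y = pd.Series(2.0 * X["m0"].to_numpy(), index=X.index)
        assert mds.lasso_preselect(X, y, seed=0) == ["m0"]

    def test_constant_response_empty(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (100, 5)), columns=list("abcde"))
        y = pd.Series(np.ones(100), index=X.index)
        assert mds.lasso_preselect(X, y, seed=0) == []

    def test_orthonormal_design_soft_threshold(self, rng):
        """On an orthonormal design the LASSO solution is soft-thresholded OLS."""
        from scipy.stats import ortho_group
        from sklearn.linear_model import Lasso

        n, p = 64, 8
        Q = ortho_group.rvs(n, random_state=1)[:, :p] * np.sqrt(n)  # columns: mean~0, norm sqrt(n)
        beta = np.array([3.0, -2.0, 1.0, 0.5, 0.0, 0.0, 0.0, 0.0])
        y = Q @ beta
        alpha = 0.8
        model = Lasso(alpha=alpha, fit_intercept=False).fit(Q, y)
        ols = Q.T @ y / n
        soft = np.sign(ols) * np.maximum(np.abs(ols) - alpha, 0.0)
        np.testing.assert_allclose(model.coef_, soft, atol=1e-6)

    def test_too_few_observations_rejected(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (20, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(0, 1, 20), index=X.index)
        with pytest.raises(ValueError):
            mds.lasso_preselect(X, y, folds=10, seed=0)


class TestIterativeForest:
    def test_dominant_motif_selected_first(self, rng):
        n = 400
        X = pd.DataFrame(rng.random((n, 5)), columns=[f"m{i}" for i in range(5)])
        y = pd.Series(np.sin(3 * X["m2"].to_numpy()) + 2 * X["m2"].to_numpy(), index=X.index)
        res = mds.iterative_rf_select(X, y, n_trees=200, seed=0)
        assert len(res.final) >= 1 and res.final[0] == "m2"
        assert res.table.loc[0, "pct_inc_mse"] == res.table["pct_inc_mse"].max()

    def test_pure_noise_selects_nothing_most_of_the_time(self, rng):
        empty = 0
        for k in range(10):
            X = pd.DataFrame(rng.random((300, 8)), columns=[f"m{i}" for i in range(8)])
            y = pd.Series(rng.normal(0, 1, 300), index=X.index)
            res = mds.iterative_rf_select(X, y, n_trees=150, seed=k)
            empty += (len(res.final) == 0)
        assert empty >= 9

    def test_stability_intersection_rule(self, rng, monkeypatch):
        """A motif selected in 4/5 repeats is reported but not in the final set."""
        calls = {"n": 0}
        real = mds.iterative_rf_select

        def fake(scores, response, n_trees=5000, seed=0, max_features=1.0 / 3.0):
            calls["n"] += 1
            motifs = ["mA"] if calls["n"] == 1 else ["mA", "mB"]
            tab = pd.DataFrame({"motif": motifs, "order": range(1, len(motifs) + 1),
                                "pct_inc_mse": 1.0, "sd_inc_mse": 0.1, "single_r2": 0.5})
            tab["stability"] = 1
            return mds.SelectionResult(table=tab, final=motifs, repeats=1)

        monkeypatch.setattr(mds, "iterative_rf_select", fake)
        X = pd.DataFrame(np.random.default_rng(0).random((60, 2)), columns=["mA", "mB"])
        y = pd.Series(np.random.default_rng(1).normal(0, 1, 60), index=X.index)
        res = mds.stability_select(X, y, repeats=5, seed=0, use_lasso=False, n_trees=10)
        monkeypatch.setattr(mds, "iterative_rf_select", real)
        assert res.final == ["mA"]
        row = res.table.set_index("motif").loc["mB"]
        assert row["stability"] == 4

    def test_duplicated_decoy_cannot_displace_driver(self):
        """Duplicating a decoy score column neither changes the driver
        selection nor lets the twin columns both enter the final set."""
        import orgdriver as od

        design = od.SampleDesign(seed=61)
        land = od.simulate_regulatory_landscape(design, seed=61, n_peaks=1000, n_motifs=10)
        fc = od.count_fold_changes(land.counts, design, ("EN", "ENR"), seed=62)
        seqs = mds.peak_sequences(land.peaks, land.genome.chromosomes)
        scores = mds.score_peaks(seqs, land.motifs, peak_ids=list(land.peaks["name"]))
        X = scores.normalized.loc[fc.table[fc.table["significant"]].index]
        y = fc.table.loc[X.index, "log2fc"]
        X2 = X.copy()
        X2["motif002_twin"] = X2["motif002"]
        base = mds.stability_select(X, y, repeats=3, seed=5, n_trees=200)
        dup = mds.stability_select(X2, y, repeats=3, seed=5, n_trees=200)
        driver = land.truth.driver_motif_id
        assert driver in base.final and driver in dup.final
        assert not {"motif002", "motif002_twin"} <= set(dup.final)

    def test_single_repeat_equals_single_run(self, rng):
        X = pd.DataFrame(rng.random((200, 4)), columns=[f"m{i}" for i in range(4)])
        y = pd.Series(3 * X["m1"].to_numpy() + rng.normal(0, 0.2, 200), index=X.index)
        res = mds.stability_select(X, y, repeats=1, seed=0, use_lasso=False, n_trees=150)
        assert res.final == ["m1"] or res.final[:1] == ["m1"]


class TestMotifCorrelationAndPromoters:
    def test_constant_score_column_undefined(self):
        s = pd.Series(np.ones(10))
        y = pd.Series(np.arange(10.0))
        assert np.isnan(mds.motif_fc_correlation(s, y))

    def test_extreme_thresholds(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
        genes = pd.DataFrame({"chrom": ["chr1"] * 5, "tss": [500, 1500, 2500, 3500, 4500]},
                             index=[f"g{i}" for i in range(5)])
        pwm = random_pwm(rng, length=8)
        assert mds.promoter_motif_fraction(list(genes.index), genes, genome, pwm, -1e9) == 1.0
        assert mds.promoter_motif_fraction(list(genes.index), genes, genome, pwm, 1e9) == 0.0
        with pytest.raises(ValueError):
            mds.promoter_motif_fraction([], genes, genome, pwm, 0.0)

    def test_planted_promoter_fraction_recovered(self):
        """Motif planted in 60% of 'up' gene promoters is recovered by the
        threshold scan at consensus score - 2 bits."""
        import orgdriver as od

        land = od.simulate_regulatory_landscape(
            od.SampleDesign(seed=17), seed=17, n_peaks=200, n_motifs=3, n_tads=20,
            n_genes=300, frac_promoter_motif=0.6)
        driver = land.motifs[0]
        frac = mds.promoter_motif_fraction(
            land.truth.up_genes, land.genes, land.genome.chromosomes, driver,
            driver.consensus_score() - 2.0)
        assert abs(frac - 0.6) <= 0.05
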