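"""Spike-in calibration, copy-number recovery and ratio statistics."""

import numpy as np
import pandas as pd
import pytest

import orgdriver as od
from orgdriver import abundance_quant as aq


def _panel(pairs):
    return od.SpikeInPanel(tuple(pairs))


def _ten_level_panel(lo=1.0, hi=1e4):
    amounts = np.logspace(np.log10(lo), np.log10(hi), 10)
    return _panel([(f"s{i}", float(a)) for i, a in enumerate(amounts)])


class TestSpikeinRegression:
    def test_identity_gain(self):
        """amount == intensity -> slope 1, intercept 0, R^2 1."""
        panel = _ten_level_panel()
        mat = pd.DataFrame({"x_1": panel.amounts})
        fit = aq.fit_spikein_regression(mat, panel)
        p = fit.params.loc["x_1"]
        np.testing.assert_allclose([p.slope, p.intercept, p.r2], [1.0, 0.0, 1.0], atol=1e-12)

    def test_two_point_hand_solution(self):
        """(10, 1) and (1000, 100): slope 1, intercept -1 on log10 scale."""
        amounts = np.concatenate([np.full(4, 1.0), np.full(4, 100.0)])
        panel = _panel([(f"s{i}", float(a)) for i, a in enumerate(amounts)] +
                       [(f"pad{i}", float(10 ** (3 + i))) for i in range(7)])
        mat = pd.DataFrame({"x_1": pd.Series({f"s{i}": 10.0 if i < 4 else 1000.0 for i in range(8)})})
        fit = aq.fit_spikein_regression(mat, panel)
        p = fit.params.loc["x_1"]
        np.testing.assert_allclose([p.slope, p.intercept], [1.0, -1.0], atol=1e-12)

    def test_noiseless_gain_recovery(self):
        panel = _ten_level_panel()
        mat = pd.DataFrame({"x_1": 50.0 * panel.amounts})
        fit = aq.fit_spikein_regression(mat, panel)
        rec = fit.apply(mat)
        np.testing.assert_allclose(rec["x_1"], panel.amounts, rtol=1e-9)

    def test_too_few_spikeins_refused(self):
        panel = _ten_level_panel()
        mat = pd.DataFrame({"x_1": panel.amounts})
        mat.iloc[:6] = np.nan
        with pytest.raises(ValueError, match="spike-ins detected"):
            aq.fit_spikein_regression(mat, panel)

    def test_negative_slope_flagged(self):
        panel = _ten_level_panel()
        mat = pd.DataFrame({"x_1": panel.amounts.iloc[::-1].to_numpy()}, index=panel.ids)
        fit = aq.fit_spikein_regression(mat, panel)
        assert not fit.params.loc["x_1", "ok"]


class TestTwoStageQuant:
    def test_fractionated_equals_unfractionated_is_identity(self, noiseless_study):
        st = noiseless_study
        cn = aq.absolute_quant_two_stage(st.protein_unfractionated, st.protein_unfractionated, st.protein_panel)
        feats = st.truth.true_protein_copies.index
        stage1 = aq.fit_spikein_regression(
            st.protein_unfractionated.loc[st.protein_panel.ids], st.protein_panel
        ).apply(st.protein_unfractionated.loc[feats])
        pd.testing.assert_frame_equal(cn.values.loc[feats], stage1, check_like=True)

    def test_scale_absorbed_by_intercept(self, noiseless_study):
        """3x all fractionated intensities -> identical copy numbers."""
        st = noiseless_study
        a = aq.absolute_quant_two_stage(st.protein_unfractionated, st.protein_fractionated, st.protein_panel)
        b = aq.absolute_quant_two_stage(st.protein_unfractionated, 3.0 * st.protein_fractionated, st.protein_panel)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_noiseless_exact_recovery(self, noiseless_study):
        st = noiseless_study
        cn = aq.absolute_quant_two_stage(st.protein_unfractionated, st.protein_fractionated, st.protein_panel)
        for s in cn.values.columns:
            c = st.design.condition_of(s)
            np.testing.assert_allclose(cn.values[s], st.truth.true_protein_copies[c], rtol=1e-9)

    def test_per_sample_affine_invariance(self, noisy_study):
        """Rescaling one sample's intensities leaves its copy numbers unchanged."""
        st = noisy_study
        a = aq.absolute_quant_two_stage(st.protein_unfractionated, st.protein_fractionated, st.protein_panel)
        unfrac = st.protein_unfractionated.copy()
        frac = st.protein_fractionated.copy()
        unfrac["CV_1"] *= 7.0
        frac["CV_1"] *= 0.11
        b = aq.absolute_quant_two_stage(unfrac, frac, st.protein_panel)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestMrnaQuant:
    def test_noiseless_proportional_recovery(self):
        st = od.simulate_expression(od.SampleDesign(seed=21), n_features=200, noise_cv=0.0, missing_rate=0.0)
        cn = aq.mrna_absolute_quant(st.counts, st.ercc_panel)
        for s in cn.values.columns:
            c = st.design.condition_of(s)
            np.testing.assert_allclose(cn.values[s], st.truth.true_mrna_copies[c], rtol=1e-9)

    def test_zero_counts_give_missing_not_zero(self, noisy_study):
        st = noisy_study
        counts = st.counts.copy()
        g = st.truth.true_mrna_copies.index[0]
        counts.loc[g, "CV_1"] = 0.0
        cn = aq.mrna_absolute_quant(counts, st.ercc_panel)
        assert np.isnan(cn.values.loc[g, "CV_1"])

    def test_noisy_median_relative_error_below_25pct(self, noisy_study):
        st = noisy_study
        cn = aq.mrna_absolute_quant(st.counts, st.ercc_panel)
        errs = []
        for s in cn.values.columns:
            truth = st.truth.true_mrna_copies[st.design.condition_of(s)]
            errs.append(np.nanmedian(np.abs(cn.values[s] / truth - 1.0)))
        assert max(errs) < 0.25


def _cn(df):
    return aq.CopyNumberTable(values=df)


class TestProteinPerMrna:
    def test_constant_replicates(self, design):
        prot = _cn(pd.DataFrame(100.0, index=["g1"], columns=design.samples))
        mrna = _cn(pd.DataFrame(10.0, index=["g1"], columns=design.samples))
        out = aq.protein_per_mrna(prot, mrna, design, "CV")
        assert out.loc["g1", "ratio"] == 10.0
        assert out.loc["g1", "n_pairs"] == 9

    def test_enumerated_four_pairs(self):
        """protein (90,110), mRNA (9,11): pairwise {10, 90/11, 110/9, 10} -> median 10."""
        design = od.SampleDesign(conditions=("A", "B"), replicates_per_condition=2)
        cols = design.samples
        prot = _cn(pd.DataFrame([[90.0, 110.0, 1, 1]], index=["g"], columns=cols))
        mrna = _cn(pd.DataFrame([[9.0, 11.0, 1, 1]], index=["g"], columns=cols))
        out = aq.protein_per_mrna(prot, mrna, design, "A")
        np.testing.assert_allclose(out.loc["g", "ratio"], 10.0)

    def test_replicate_order_invariance(self, design, rng):
        vals = rng.lognormal(4, 1, (20, 9))
        prot = _cn(pd.DataFrame(vals, columns=design.samples))
        mrna = _cn(pd.DataFrame(rng.lognormal(1, 1, (20, 9)), index=prot.values.index, columns=design.samples))
        a = aq.protein_per_mrna(prot, mrna, design, "ENR")
        shuffled = ["ENR_3", "ENR_1", "ENR_2"]
        prot2 = _cn(prot.values.rename(columns=dict(zip(design.samples_of("ENR"), shuffled))))
        b = aq.protein_per_mrna(prot2, mrna, design, "ENR")
        np.testing.assert_allclose(a["ratio"], b["ratio"])

    def test_ratio_symmetry_on_swap(self, design):
        """Swapping layers gives the reciprocal of the median reciprocal pair."""
        cols = design.samples
        prot = _cn(pd.DataFrame([[90.0, 110.0, 100.0] + [1.0] * 6], index=["g"], columns=cols))
        mrna = _cn(pd.DataFrame([[9.0, 11.0, 10.0] + [1.0] * 6], index=["g"], columns=cols))
        fwd = aq.protein_per_mrna(prot, mrna, design, "CV").loc["g", "ratio"]
        # reciprocal-pair median computed by direct enumeration
        p = np.array([90.0, 110.0, 100.0]); m = np.array([9.0, 11.0, 10.0])
        rec = np.median((m[:, None] / p[None, :]).ravel())
        swapped = aq.protein_per_mrna(mrna, prot, design, "CV").loc["g", "ratio"]
        np.testing.assert_allclose(swapped, rec)
        assert fwd > 0 and swapped > 0


class TestGlobalTranslationTest:
    def test_fisher_z_values(self):
        np.testing.assert_allclose(np.arctanh(0.0), 0.0)
        np.testing.assert_allclose(np.arctanh(0.5), 0.5493061443340549)

    def test_perfect_correlation_clipped_not_fatal(self, rng):
        base = rng.normal(0, 1, 50)
        A = pd.DataFrame({"a1": base, "a2": base, "a3": base})  # r == 1 within
        B = pd.DataFrame({"b1": base + rng.normal(0, 0.5, 50),
                          "b2": base + rng.normal(0, 0.5, 50),
                          "b3": base + rng.normal(0, 0.5, 50)})
        p = aq.global_translation_test(A, B)
        assert 0.0 <= p <= 1.0

    def test_type_one_error_held(self, rng):
        """Null simulation: A and B from one distribution -> p<0.05 rarely."""
        hits = 0
        n_runs = 200
        for _ in range(n_runs):
            base = rng.normal(0, 1, 200)
            A = pd.DataFrame({f"a{i}": base + rng.normal(0, 0.4, 200) for i in range(3)})
            B = pd.DataFrame({f"b{i}": base + rng.normal(0, 0.4, 200) for i in range(3)})
            hits += aq.global_translation_test(A, B) < 0.05
        assert hits / n_runs <= 0.07


class TestRatioChangeTest:
    def test_identical_groups_give_zero_stat_unit_p(self, design):
        vals = np.tile(np.array([[100.0, 120.0, 90.0]]), (5, 3))
        prot = _cn(pd.DataFrame(vals, columns=design.samples))
        mrna = _cn(pd.DataFrame(10.0, index=prot.values.index, columns=design.samples))
        out = aq.ratio_change_test(prot, mrna, design, "CV", "EN")
        np.testing.assert_allclose(out["stat"], 0.0)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_df_is_replicates_not_pairs(self, noisy_study):
        st = noisy_study
        prot = aq.absolute_quant_two_stage(st.protein_unfractionated, st.protein_fractionated, st.protein_panel)
        mrna = aq.mrna_absolute_quant(st.counts, st.ercc_panel)
        out = aq.ratio_change_test(prot, mrna, st.design, "CV", "EN")
        assert (out["df"] == 4.0).all()

    def test_zero_variance_feature_skipped(self, design):
        prot = _cn(pd.DataFrame(100.0, index=["g1", "g2"], columns=design.samples))
        mrna_vals = pd.DataFrame(10.0, index=["g1", "g2"], columns=design.samples)
        mrna_vals.loc["g2"] = [10, 11, 12, 10, 11, 12, 13, 14, 15]
        out = aq.ratio_change_test(_cn(prot.values), _cn(mrna_vals), design, "CV", "EN")
        assert np.isnan(out.loc["g1", "stat"])  # zero variance in both groups
        assert np.isfinite(out.loc["g2", "stat"])

    def test_null_type_one_error(self):
        """No planted shifts: fraction with p<0.05 near nominal."""
        st = od.simulate_expression(od.SampleDesign(seed=31), n_features=1000,
                                    missing_rate=0.0, frac_ratio_shift=0.0, frac_de=0.0)
        prot = aq.absolute_quant_two_stage(st.protein_unfractionated, st.protein_fractionated, st.protein_panel)
        mrna = aq.mrna_absolute_quant(st.counts, st.ercc_panel)
        out = aq.ratio_change_test(prot, mrna, st.design, "CV", "EN")
        assert 0.03 <= (out["p"] < 0.05).mean() <= 0.07


class TestRatioSignificanceFilter:
    def _mk(self, fc, q):
        return pd.DataFrame({"log2_ratio_fc": fc, "q": q, "stat": 0.0, "p": q},
                            index=[f"g{i}" for i in range(len(fc))])

    def test_fails_one_arm_not_flagged(self):
        a = self._mk([np.log2(4)], [0.01])
        b = self._mk([np.log2(2)], [0.01])
        assert len(aq.ratio_significance_filter(a, b)) == 0

    def test_passes_both_arms_flagged(self):
        a = self._mk([np.log2(5)], [0.01])
        b = self._mk([np.log2(4)], [0.02])
        assert list(aq.ratio_significance_filter(a, b)) == ["g0"]

    def test_opposite_directions_not_flagged(self):
        a = self._mk([np.log2(5)], [0.01])
        b = self._mk([-np.log2(5)], [0.01])
        assert len(aq.ratio_significance_filter(a, b)) == 0
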