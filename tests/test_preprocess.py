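"""Preprocessing contracts: I/O round trips, filter rules, imputation, normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from myosignal import synth
from myosignal.preprocess import (
    FilterRule,
    QuantMatrix,
    correct_batch,
    filter_features,
    impute_condition_specific,
    impute_random_tail,
    proteome_correct,
    read_quant_matrix,
    ruv_normalize,
    select_stable_features,
    to_ratios,
    write_quant_matrix,
)

from conftest import random_quant


def design_2x4():
    return synth.make_design(["t0", "t1"], 4, n_batches=2)


class TestIO:
    def test_round_trip(self, tmp_path, toy_design):
        m = random_quant(toy_design, n_features=5, seed=1, missing=0.1)
        write_quant_matrix(m, tmp_path / "m.tsv", tmp_path / "d.tsv")
        back = read_quant_matrix(tmp_path / "m.tsv", tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(back.values, m.values)
        assert back.n_missing() == m.n_missing()

    def test_single_empty_cell(self, tmp_path, toy_design):
        m = random_quant(toy_design, n_features=3, seed=2)
        m.values.iloc[1, 2] = np.nan
        write_quant_matrix(m, tmp_path / "m.tsv", tmp_path / "d.tsv")
        back = read_quant_matrix(tmp_path / "m.tsv", tmp_path / "d.tsv")
        assert back.n_missing() == 1
        assert np.isnan(back.values.iloc[1, 2])

    def test_malformed_cell_names_row_and_column(self, tmp_path, toy_design):
        m = random_quant(toy_design, n_features=3, seed=3)
        write_quant_matrix(m, tmp_path / "m.tsv", tmp_path / "d.tsv")
        text = (tmp_path / "m.tsv").read_text().splitlines()
        cells = text[1].split("\t")
        cells[2] = "not_a_number"
        text[1] = "\t".join(cells)
        (tmp_path / "m.tsv").write_text("\n".join(text) + "\n")
        with pytest.raises(ValueError, match="f000"):
            read_quant_matrix(tmp_path / "m.tsv", tmp_path / "d.tsv")

    def test_design_mismatch_lists_unmatched(self, toy_design):
        values = pd.DataFrame(
            np.ones((2, 3)), index=["a", "b"], columns=["s1", "s2", "s3"]
        )
        with pytest.raises(ValueError, match="s1"):
            QuantMatrix(values=values, design=toy_design)


class TestFilterFeatures:
    def _matrix(self, pattern, design):
        """pattern: dict feature -> set of observed sample positions."""
        vals = pd.DataFrame(
            np.nan, index=list(pattern), columns=design.index, dtype=float
        )
        for feat, positions in pattern.items():
            for pos in positions:
                vals.iloc[list(pattern).index(feat), pos] = 20.0
        return QuantMatrix(values=vals, design=design)

    def test_phospho_rule_total_threshold(self, toy_design):
        # 3 of 4 replicates at one time point, nothing else: fails total >= 4
        m = self._matrix({"s1": {0, 1, 2}}, toy_design)
        out = filter_features(m, FilterRule.phospho_timecourse())
        assert list(out.features) == []

    def test_phospho_rule_retained_with_extra_value(self, toy_design):
        # same site plus one extra quantified value elsewhere: retained
        m = self._matrix({"s1": {0, 1, 2, 5}}, toy_design)
        out = filter_features(m, FilterRule.phospho_timecourse())
        assert list(out.features) == ["s1"]

    def test_proteome_adjacency(self):
        design = synth.make_design(["t1", "t2", "t3"], 4)
        rule = FilterRule.proteome_timecourse()
        # 2/4 at t1 and t3 only: not adjacent -> dropped
        gap = self._matrix({"p": {0, 1, 8, 9}}, design)
        assert list(filter_features(gap, rule).features) == []
        # 2/4 at t1 and t2: adjacent -> retained
        adj = self._matrix({"p": {0, 1, 4, 5}}, design)
        assert list(filter_features(adj, rule).features) == ["p"]

    def test_min_reps_above_replicates_rejected(self, toy_design):
        m = random_quant(toy_design, n_features=2)
        with pytest.raises(ValueError, match="replicate"):
            filter_features(m, FilterRule(0, 5, 1, False))

    @given(
        total=st.integers(0, 6),
        reps=st.integers(1, 4),
        conds=st.integers(1, 3),
        seed=st.integers(0, 30),
    )
    def test_filter_monotone_in_thresholds(self, total, reps, conds, seed):
        """Relaxing any threshold never removes a retained feature."""
        design = synth.make_design(["t0", "t1", "t2"], 4)
        m = random_quant(design, n_features=12, seed=seed, missing=0.5)
        strict = filter_features(m, FilterRule(total, reps, conds, False))
        for rule in (
            FilterRule(max(total - 1, 0), reps, conds, False),
            FilterRule(total, max(reps - 1, 1), conds, False),
            FilterRule(total, reps, max(conds - 1, 1), False),
        ):
            relaxed = filter_features(m, rule)
            assert set(strict.features) <= set(relaxed.features)


class TestConditionSpecificImputation:
    def test_degenerate_variance_gives_exact_mean(self):
        design = design_2x4()
        vals = pd.DataFrame(
            [[6.0, 6.0, 6.0, np.nan, 1.0, 1.0, 1.0, 1.0]],
            index=["f"], columns=design.index,
        )
        m = QuantMatrix(values=vals, design=design)
        out = impute_condition_specific(m, seed=0)
        assert out.values.iloc[0, 3] == pytest.approx(6.0)

    def test_below_threshold_left_missing(self):
        design = design_2x4()
        vals = pd.DataFrame(
            [[6.0, 7.0, np.nan, np.nan, 1.0, 1.0, 1.0, 1.0]],
            index=["f"], columns=design.index,
        )
        m = QuantMatrix(values=vals, design=design)
        out = impute_condition_specific(m, seed=0)
        assert out.values.iloc[0, 2:4].isna().all()

    def test_draw_distribution_matches_observed_moments(self):
        # 1000 features each with observed {5, 6, 7}: draws are iid N(6, 1)
        design = design_2x4()
        row = [5.0, 6.0, 7.0, np.nan, 1.0, 1.0, 1.0, 1.0]
        vals = pd.DataFrame(
            [row] * 1000, index=[f"f{i}" for i in range(1000)], columns=design.index
        )
        m = QuantMatrix(values=vals, design=design)
        out = impute_condition_specific(m, seed=1)
        draws = out.values.iloc[:, 3]
        assert abs(draws.mean() - 6.0) < 0.1

    def test_observed_cells_untouched(self):
        design = design_2x4()
        m = random_quant(design, n_features=30, seed=4, missing=0.3)
        before = m.values.copy()
        out = impute_condition_specific(m, seed=0)
        obs = before.notna()
        assert out.values[obs].equals(before[obs])


class TestRandomTailImputation:
    def test_no_missing_is_identity(self, toy_design):
        m = random_quant(toy_design, n_features=10, seed=5)
        out = impute_random_tail(m, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_degenerate_width_hits_sample_mean(self, toy_design):
        m = random_quant(toy_design, n_features=50, seed=6, missing=0.2)
        out = impute_random_tail(m, shift=0.0, width=1e-9, seed=0)
        for col in m.samples:
            miss = m.values[col].isna()
            if miss.any():
                mu = m.values[col].dropna().mean()
                assert np.allclose(out.values.loc[miss, col], mu, atol=1e-6)

    def test_downshift_moments_at_scale(self):
        # one sample, 500 observed + 10,000 missing cells
        design = synth.make_design(["t0"], 1)
        rng = np.random.default_rng(0)
        obs = rng.normal(20, 2, size=500)
        vals = pd.DataFrame(
            np.concatenate([obs, np.full(10_000, np.nan)])[:, None],
            index=[f"f{i}" for i in range(10_500)],
            columns=design.index,
        )
        m = QuantMatrix(values=vals, design=design)
        out = impute_random_tail(m, seed=3)
        mu, sd = obs.mean(), obs.std(ddof=1)
        imputed = out.values.iloc[500:, 0]
        assert abs(imputed.mean() - (mu - 1.8 * sd)) < 0.05 * sd

    def test_underdetermined_sample_rejected(self):
        design = synth.make_design(["t0"], 1)
        vals = pd.DataFrame(
            [[20.0], [np.nan]], index=["a", "b"], columns=design.index
        )
        m = QuantMatrix(values=vals, design=design)
        with pytest.raises(ValueError, match="sd undefined"):
            impute_random_tail(m)


class TestRatiosAndBatch:
    def test_ratio_arithmetic_and_reference_zeroing(self):
        design = design_2x4()
        rng = np.random.default_rng(1)
        m = random_quant(design, n_features=8, seed=1)
        m.values.iloc[0] = 10.0  # constant feature
        out = to_ratios(m, "t0")
        assert np.allclose(out.values.iloc[0], 0.0)
        # reference columns mean zero per batch, by construction
        for batch in out.batches:
            cols = out.samples_of("t0", batch=batch)
            assert np.allclose(out.values[cols].mean(axis=1), 0.0, atol=1e-12)

    def test_simple_shift(self):
        design = synth.make_design(["t0", "t1"], 1)
        vals = pd.DataFrame([[10.0, 12.0]], index=["f"], columns=design.index)
        out = to_ratios(QuantMatrix(values=vals, design=design), "t0")
        assert out.values.loc["f", "t1_r1"] == pytest.approx(2.0)

    def test_center_removes_planted_batch_shift(self):
        design = design_2x4()
        m = random_quant(design, n_features=10, seed=2)
        b2 = [s for s in design.index if design.at[s, "batch"] == "b2"]
        m.values[b2] += 3.0
        out = correct_batch(m, method="center")
        for feat in out.features:
            m1 = out.values.loc[feat, [s for s in design.index if s not in b2]].mean()
            m2 = out.values.loc[feat, b2].mean()
            assert m1 == pytest.approx(m2, abs=1e-10)

    def test_eb_location_shrinks_between_raw_and_centered(self):
        design = design_2x4()
        m = random_quant(design, n_features=40, seed=3)
        eb = correct_batch(m, method="eb_location")
        centered = correct_batch(m, method="center")
        raw, ebv, cv = (x.values.to_numpy() for x in (m, eb, centered))
        moved = np.abs(raw - cv) > 1e-9
        inside = ((ebv >= np.minimum(raw, cv) - 1e-9) & (ebv <= np.maximum(raw, cv) + 1e-9))
        assert inside[moved].all()

    def test_batch_f_statistic_reduced_on_noisy_batches(self):
        design = design_2x4()
        models = synth.make_kinase_models(2, conditions=["t0", "t1"], seed=0)
        qm, _, _ = synth.simulate_phospho(
            models, 20, 100, design, batch_sd=1.0,
            mnar_quantile=0.0, mcar_rate=0.0, seed=1,
        )
        out = correct_batch(qm, method="center")

        def batch_f(m):
            from scipy import stats as sps
            b1 = [s for s in design.index if design.at[s, "batch"] == "b1"]
            b2 = [s for s in design.index if design.at[s, "batch"] == "b2"]
            return np.median([
                sps.f_oneway(m.values.loc[f, b1], m.values.loc[f, b2]).statistic
                for f in m.features
            ])

        assert batch_f(out) < batch_f(qm)

    def test_single_batch_warns_noop(self):
        design = synth.make_design(["t0", "t1"], 3, n_batches=1)
        m = random_quant(design, n_features=5, seed=9)
        with pytest.warns(UserWarning, match="single batch"):
            out = correct_batch(m)
        pd.testing.assert_frame_equal(out.values, m.values)


class TestStableFeaturesAndRUV:
    def test_constant_feature_ranks_first(self, toy_design):
        m = random_quant(toy_design, n_features=10, seed=1)
        m.values.iloc[4] = 7.0
        assert select_stable_features(m, 1) == ["f004"]

    def test_all_features_returned_when_n_large(self, toy_design):
        m = random_quant(toy_design, n_features=6, seed=2)
        assert len(select_stable_features(m, 100)) == 6

    def test_stable_selection_enriches_background(self):
        design = synth.timecourse_design()
        models = synth.make_kinase_models(5, seed=3)
        qm, _, truth = synth.simulate_phospho(
            models, 20, 200, design, mnar_quantile=0.0, mcar_rate=0.0, seed=4,
        )
        ratios = to_ratios(qm, "0h")
        chosen = select_stable_features(ratios, 50)
        background = sum(truth.site_to_kinase[s] is None for s in chosen)
        assert background / len(chosen) >= 0.8

    def _ruv_construction(self, k_features=30, n_controls=10, seed=0,
                          control_noise=0.1):
        """Data = noise + gamma (x) w, with the unwanted loading gamma large on
        the controls; control_noise scales the controls' residual variation."""
        design = synth.timecourse_design()
        rng = np.random.default_rng(seed)
        n = len(design)
        w = rng.normal(size=n)
        base = rng.normal(0, 1, size=(k_features, n))
        base[:n_controls] *= control_noise
        gamma = np.zeros(k_features)
        gamma[:n_controls] = rng.normal(2, 0.5, size=n_controls)
        vals = pd.DataFrame(
            base + np.outer(gamma, w),
            index=[f"f{i:03d}" for i in range(k_features)],
            columns=list(design.index),
        )
        m = QuantMatrix(values=vals, design=design, scale="ratio")
        return m, [f"f{i:03d}" for i in range(n_controls)], w

    def test_ruv_removes_constructed_factor(self):
        m, controls, w = self._ruv_construction()
        out = ruv_normalize(m, controls, k=1)
        for c in controls:
            r = np.corrcoef(out.values.loc[c], w)[0, 1]
            assert abs(r) < 0.1

    def test_ruv_idempotent(self):
        # controls carry (essentially) only the unwanted factor: the second
        # pass finds nothing left to remove
        m, controls, _ = self._ruv_construction(seed=1, control_noise=1e-12)
        once = ruv_normalize(m, controls, k=1)
        twice = ruv_normalize(once, controls, k=1)
        assert np.abs(once.values.to_numpy() - twice.values.to_numpy()).max() < 1e-8

    def test_k_zero_disallowed(self):
        m, controls, _ = self._ruv_construction(seed=2)
        with pytest.raises(ValueError, match="k must be"):
            ruv_normalize(m, controls, k=0)


class TestProteomeCorrection:
    def _pair(self):
        pdesign = synth.make_design(["t0", "t1"], 2)
        site_vals = pd.DataFrame(
            [[0.0, 0.0, 3.0, 3.0], [0.0, 0.0, 1.0, 1.0]],
            index=["s1", "s2"], columns=pdesign.index,
        )
        prot_vals = pd.DataFrame(
            [[0.0, 0.0, 1.0, 1.0]], index=["pA"], columns=pdesign.index
        )
        phospho = QuantMatrix(values=site_vals, design=pdesign, scale="ratio")
        protein = QuantMatrix(values=prot_vals, design=pdesign.copy(), scale="ratio")
        return phospho, protein

    def test_subtracts_host_protein_ratio(self):
        phospho, protein = self._pair()
        out, unmapped = proteome_correct(phospho, protein, {"s1": "pA"})
        assert out.values.loc["s1", "t1_r1"] == pytest.approx(2.0)
        assert unmapped == ["s2"]
        # unmapped site untouched
        assert out.values.loc["s2", "t1_r1"] == pytest.approx(1.0)

    def test_zero_protein_ratio_is_identity(self):
        phospho, protein = self._pair()
        protein.values.loc["pA"] = 0.0
        out, _ = proteome_correct(phospho, protein, {"s1": "pA"})
        pd.testing.assert_frame_equal(out.values, phospho.values)

    def test_matched_trend_cancels(self):
        phospho, protein = self._pair()
        protein.values.loc["pA"] = phospho.values.loc["s1"]
        out, _ = proteome_correct(phospho, protein, {"s1": "pA"})
        assert np.allclose(out.values.loc["s1"], 0.0)

    def test_absent_condition_rejected(self):
        phospho, protein = self._pair()
        with pytest.raises(ValueError, match="t9"):
            proteome_correct(phospho, protein, {"s1": "pA"}, conditions=["t9"])
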