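"""Statistical battery: exact small-sample behavior against enumeration
oracles, gate calibration, and the cohort table builder."""

import numpy as np
import pingouin as pg
import pytest

from lmh_octa import stats as ST

import oracles


class TestMannWhitney:
    def test_separated_groups_enumeration_example(self):
        rep = ST.mann_whitney([1, 2, 3], [10, 11, 12])
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_samples_degenerate(self):
        rep = ST.mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert rep.p_value == 1.0
        assert rep.degenerate

    @pytest.mark.parametrize("nx,ny", [(2, 2), (3, 4), (4, 4), (2, 6)])
    def test_exact_matches_oracle_with_ties(self, nx, ny, rng):
        for _ in range(5):
            x = rng.integers(0, 5, nx).astype(float)
            y = rng.integers(0, 5, ny).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            assert ST.mann_whitney(x, y).p_value == pytest.approx(
                oracles.mw_exact_p(x, y)
            )


class TestSignedRank:
    def test_uniform_decline_five_pairs(self):
        before = [5, 6, 7, 8, 9]
        after = [4, 5, 6, 7, 8]
        rep = ST.signed_rank(before, after)
        assert rep.p_value == pytest.approx(2 / 32)  # all-negative sign pattern

    def test_no_change_degenerate(self):
        rep = ST.signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.p_value == 1.0
        assert rep.degenerate

    @pytest.mark.parametrize("m", [3, 5, 8])
    def test_exact_dp_matches_sign_enumeration(self, m, rng):
        for _ in range(5):
            before = rng.normal(size=m)
            after = before + rng.integers(-2, 3, m)  # induces ties and zeros
            if np.all(after == before):
                continue
            assert ST.signed_rank(before, after).p_value == pytest.approx(
                oracles.signed_rank_exact_p(before, after)
            )


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert ST.spearman(x, [2.0, 3.0, 5.0, 7.0, 11.0])[0] == pytest.approx(1.0)
        assert ST.spearman(x, [9.0, 7.0, 5.0, 3.0, 1.0])[0] == pytest.approx(-1.0)

    def test_four_point_example_full_enumeration(self):
        rho, p = ST.spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)
        assert p == pytest.approx(oracles.spearman_exact_p([1, 2, 3, 4], [2, 1, 4, 3]))

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exact_matches_oracle(self, n, rng):
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.integers(0, 3, n).astype(float)
            if np.ptp(y) == 0:
                continue
            assert ST.spearman(x, y)[1] == pytest.approx(
                oracles.spearman_exact_p(list(x), list(y))
            )

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError):
            ST.spearman([1, 2, 3, 4], [5, 5, 5, 5])


class TestICC:
    def test_identical_raters_unity(self):
        rep = ST.icc_two_way([[1, 1], [2, 2], [3, 3]])
        assert rep.statistic == pytest.approx(1.0)

    def test_three_subject_example_against_oracles(self):
        m = [[1, 2], [2, 3], [3, 4]]
        ours = ST.icc_two_way(m).statistic
        assert ours == pytest.approx(oracles.icc_21_variance_components(m))
        # hand ANOVA: MSR = 2, MSC = 1.5 -> denominator of the hand form
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject": [0, 0, 1, 1, 2, 2],
                "rater": ["a", "b"] * 3,
                "score": [1, 2, 2, 3, 3, 4],
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc_a1 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(icc_a1, abs=1e-10)

    def test_constant_offset_agreement_below_consistency(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(size=20)
        m = np.column_stack([g1, g1 + 0.5])
        agreement = ST.icc_two_way(m).statistic
        # consistency ICC ignores the rater shift entirely
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 2),
                "rater": ["a", "b"] * 20,
                "score": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc_c1 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert agreement < icc_c1

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(200, 2))
        assert abs(ST.icc_two_way(m).statistic) < 0.1

    def test_no_subject_variance_flagged(self):
        rep = ST.icc_two_way([[1.0, 1.0], [1.0, 1.0]])
        assert rep.degenerate

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(15, 2))
        a = ST.icc_two_way(m).statistic
        b = ST.icc_two_way(m * 3.7).statistic
        assert a == pytest.approx(b)


class TestCategorical:
    def test_lhep_prevalence_contrast(self):
        # 4/14 vs 0/14 positive: small expected counts force Fisher
        rep = ST.categorical_test([[4, 10], [0, 14]])
        assert rep.test_name == "fisher_exact"
        assert rep.p_value == pytest.approx(0.098, abs=5e-4)

    def test_symmetric_table_null(self):
        assert ST.categorical_test([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_perfect_separation_matches_hypergeometric_oracle(self):
        # expected cells 3.5 < 5 -> the Fisher branch
        rep = ST.categorical_test([[7, 0], [0, 7]])
        assert rep.test_name == "fisher_exact"
        assert rep.p_value == pytest.approx(oracles.fisher_exact_p([[7, 0], [0, 7]]))
        # the oracle itself reproduces scipy on a larger separation table
        from scipy.stats import fisher_exact

        assert oracles.fisher_exact_p([[10, 0], [0, 10]]) == pytest.approx(
            fisher_exact([[10, 0], [0, 10]])[1]
        )

    def test_large_balanced_uses_chi2(self):
        rep = ST.categorical_test([[30, 20], [18, 32]])
        assert rep.test_name == "chi2_yates"

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            ST.categorical_test([[0, 0], [3, 4]])


class TestGateAndDescriptives:
    def test_gaussian_passes_gate_mostly(self):
        hits = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(size=200)
            hits += ST.normality_gate(x) == "normal"
        assert hits >= 45

    def test_lognormal_fails_gate(self):
        for seed in range(20):
            x = np.random.default_rng(seed).lognormal(sigma=1.0, size=200)
            assert ST.normality_gate(x) == "non_normal"

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ST.normality_gate([2.0, 2.0, 2.0, 2.0])

    def test_descriptive_styles(self):
        assert ST.descriptives([1, 2, 3, 4, 5], "non_normal") == (3.0, 2.0)
        loc, spread = ST.descriptives([1, 2, 3], "normal")
        assert (loc, spread) == (2.0, 1.0)
        assert ST.descriptives([4.2], "non_normal")[1] == 0.0

    def test_truncated_percentages(self):
        assert ST.count_percent(10, 28, 1) == 35.7
        assert ST.count_percent(4, 14, 2) == 28.57


class TestCompareGroups:
    def test_gate_routes_to_t_or_mw(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        assert "t" in ST.compare_groups(x, y).test_name
        xl = rng.lognormal(sigma=1.2, size=30)
        assert "mann_whitney" in ST.compare_groups(xl, y).test_name

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        rej = sum(
            ST.compare_groups(rng.normal(size=14), rng.normal(size=14)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08


class TestResultsTables:
    def test_missing_columns_named(self, cohort):
        broken = cohort.patients.drop(columns=["bcva_followup", "lhep"])
        with pytest.raises(ST.MissingColumnsError) as exc:
            ST.build_results_tables(broken)
        assert {"bcva_followup", "lhep"} <= set(exc.value.missing)

    def test_identical_groups_stay_mostly_null(self):
        # relabel one cohort's patients at random: no row should be
        # significant beyond alpha-level noise
        from lmh_octa import synthdata as S

        cfg = S.SimulationConfig(seed=23)
        eff = S.default_group_effects()
        for k, v in list(eff.items()):
            if v[0] in ("mean_sd", "median_iqr", "bernoulli", "categorical"):
                eff[k] = (v[0], v[2], v[2])
        cfg.group_effects = eff
        pvals = []
        for seed in (1, 2, 3):
            c = S.simulate_cohort(cfg, seed=seed)
            tabs = ST.build_results_tables(c.patients)
            pvals += [
                p for p in tabs["table1"]["p_value"].tolist()
                if np.isfinite(p)
            ]
        # 3 cohorts x 12 rows: expect ~5% rejections, allow generous noise
        assert np.mean(np.asarray(pvals) < 0.05) < 0.25

    def test_tables_cover_expected_rows(self, cohort):
        tabs = ST.build_results_tables(cohort.patients)
        assert len(tabs["table1"]) == 12
        assert len(tabs["table2"]) == 18
        assert len(tabs["paired"]) == 4
        assert len(tabs["correlations"]) == 3
        assert ((tabs["table1"]["p_value"] >= 0) & (tabs["table1"]["p_value"] <= 1)).all()

    def test_directionality_and_links(self, cohort):
        tabs = ST.build_results_tables(cohort.patients)
        t2 = tabs["table2"].set_index("variable")
        for row in ("SCP Foveal VD (%)", "SCP Foveal PD (%)"):
            assert t2.loc[row, "tl_location"] < t2.loc[row, "st_location"]
        corr = tabs["correlations"]
        assert corr.loc[0, "rho"] < -0.9  # more loss, less parafoveal perfusion
        assert corr.loc[1, "rho"] > 0.9  # faster loss, larger BCVA decline
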