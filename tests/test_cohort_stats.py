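"""Association analysis: exclusions, scaling, PCA scores, grid, power."""

import numpy as np
import pandas as pd
import pytest

from retfractal.cohort_gen import CohortSpec, generate_cohort
from retfractal.cohort_stats import (
    AssociationResult,
    apply_exclusions,
    contralateral_check,
    count_significant,
    derive_domain_scores,
    fit_association,
    iq_scale,
    power_correlation,
    run_grid,
)


def null_spec(**kw):
    return CohortSpec(
        fractal_missing_all=0.0,
        fractal_missing_each=0.0,
        iq_missing_rate=0.0,
        domain_missing_rate={"g": 0.0, "speed": 0.0, "memory": 0.0},
        mmse_low_rate=0.0,
        ungradable_rate=0.0,
        **kw,
    )


class TestExclusions:
    def test_663_roster_leaves_648(self):
        """6 possible-dementia + 9 substandard-image participants drop out."""
        roster = generate_cohort(null_spec(n=663, seed=1))
        roster.loc[:5, "mmse"] = 20  # 6 participants below cutoff
        roster.loc[6:14, "gradable"] = 0  # 9 further with no usable image
        kept, counts = apply_exclusions(roster)
        assert counts == {"mmse_below_cutoff": 6, "no_gradable_image": 9}
        assert len(kept) == 648

    def test_empty_roster(self):
        empty = generate_cohort(CohortSpec(n=10)).iloc[0:0]
        kept, counts = apply_exclusions(empty)
        assert len(kept) == 0
        assert counts == {"mmse_below_cutoff": 0, "no_gradable_image": 0}

    def test_double_failure_counted_once_under_first_rule(self):
        roster = generate_cohort(null_spec(n=20, seed=2))
        roster.loc[0, "mmse"] = 20
        roster.loc[0, "gradable"] = 0
        kept, counts = apply_exclusions(roster)
        assert counts["mmse_below_cutoff"] == 1
        assert counts["no_gradable_image"] == 0
        assert len(kept) == 19

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="mmse"):
            apply_exclusions(pd.DataFrame({"x": [1]}))


class TestIqScale:
    def test_output_moments_exact(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(40, 10, 500)
        ages = rng.normal(4100, 110, 500)
        out = iq_scale(raw, ages)
        assert out.mean() == pytest.approx(100.0, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(15.0, abs=1e-9)

    def test_rank_preserved_when_age_independent(self):
        raw = np.array([10.0, 30.0, 20.0, 50.0, 40.0])
        base = np.array([4000.0, 4010.0, 4020.0, 4030.0, 4040.0])
        # make ages exactly uncorrelated with the scores, so the age fit is flat
        c = raw - raw.mean()
        ages = base - (base - base.mean()) @ c / (c @ c) * c
        out = iq_scale(raw, ages)
        assert (np.argsort(out) == np.argsort(raw)).all()

    def test_perfect_age_dependence_gives_constant(self):
        ages = np.linspace(4000, 4400, 100)
        raw = 3.0 + 0.01 * ages
        with pytest.raises(ValueError, match="zero variance"):
            iq_scale(raw, ages)

    def test_missing_propagates(self):
        raw = np.array([10.0, np.nan, 20.0, 50.0, 40.0])
        out = iq_scale(raw, np.array([4000.0, 4010.0, 4020.0, 4030.0, 4040.0]))
        assert np.isnan(out[1])
        assert np.isfinite(np.delete(out, 1)).all()


class TestDomainScores:
    def test_two_perfectly_correlated_subtests(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        df = pd.DataFrame({"t1": a, "t2": 2 * a + 5})
        scores = derive_domain_scores(df, {"dom": ["t1", "t2"]})["dom"]
        za = (a - a.mean()) / a.std(ddof=1)
        assert np.allclose(np.abs(np.corrcoef(scores, za)[0, 1]), 1.0)

    def test_standardized_output(self):
        df = generate_cohort(CohortSpec(n=2000, seed=4))
        scores = derive_domain_scores(df[["matrix_reasoning", "block_design", "symbol_search"]],
                                      {"g": ["matrix_reasoning", "block_design", "symbol_search"]})
        assert scores["g"].mean() == pytest.approx(0.0, abs=1e-9)
        assert scores["g"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance(self):
        df = generate_cohort(CohortSpec(n=500, seed=5))
        tests = ["matrix_reasoning", "block_design", "letter_number_sequencing"]
        a = derive_domain_scores(df[tests], {"g": tests})["g"]
        b = derive_domain_scores(df[tests[::-1]], {"g": tests[::-1]})["g"]
        assert np.allclose(a, b)

    def test_sign_oriented_higher_is_better(self):
        """Scores correlate positively with the underlying ability."""
        df = generate_cohort(null_spec(n=5000, seed=6))
        tests = ["symbol_search", "digit_symbol_coding", "simple_rt", "choice_rt"]
        scores = derive_domain_scores(df[tests], {"speed": tests})["speed"]
        assert np.corrcoef(scores, df.speed)[0, 1] > 0.5

    def test_single_subtest_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            derive_domain_scores(pd.DataFrame({"t": [1.0, 2.0]}), {"d": ["t"]})


class TestFitAssociation:
    def test_beta_recovery(self):
        """Injected standardized effect of 0.30 is recovered within 0.02."""
        df = generate_cohort(
            null_spec(n=20_000, seed=7, true_effects={("right", "d1", "g"): 0.30})
        )
        res = fit_association(df, 1, "right", "d1", "g")
        assert res.beta == pytest.approx(0.30, abs=0.02)
        assert res.p < 1e-10

    def test_attenuation_by_childhood_iq(self):
        """When the fractal-cognition link runs through childhood IQ,
        adjusting for IQ (model 2) shrinks the coefficient."""
        df = generate_cohort(null_spec(n=20_000, seed=8, iq_fractal_corr=0.25))
        m1 = fit_association(df, 1, "right", "d1", "g")
        m2 = fit_association(df, 2, "right", "d1", "g")
        assert m1.beta > 0.10
        assert abs(m2.beta) < abs(m1.beta) / 2

    def test_per_sd_scaling_invariance(self):
        df = generate_cohort(null_spec(n=2000, seed=9))
        base = fit_association(df, 1, "left", "d0", "speed")
        scaled_df = df.copy()
        scaled_df["d0_left"] = scaled_df["d0_left"] * 1000.0
        scaled = fit_association(scaled_df, 1, "left", "d0", "speed")
        assert scaled.beta == pytest.approx(base.beta, rel=1e-9)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)

    def test_type_one_error_calibrated(self):
        """Model-1 test on null cohorts rejects at 5% (0.05 +/- 0.01)."""
        n_reps = 2000
        rejections = 0
        for rep in range(n_reps):
            df = generate_cohort(null_spec(n=648, seed=10_000 + rep))
            res = fit_association(df, 1, "right", "d1", "g")
            rejections += res.p < 0.05
        rate = rejections / n_reps
        assert 0.04 <= rate <= 0.06

    def test_singular_design_rejected(self):
        df = generate_cohort(null_spec(n=200, seed=11))
        df["age"] = 72.0  # constant covariate duplicates the intercept
        with pytest.raises(ValueError, match="singular"):
            fit_association(df, 1, "right", "d1", "g")


class TestGridAndCounts:
    @pytest.fixture(scope="class")
    def grid(self):
        df = generate_cohort(CohortSpec(n=663, seed=12))
        kept, _ = apply_exclusions(df)
        return run_grid(kept)

    def test_cardinality(self, grid):
        assert len(grid) == 72
        for model in (1, 2, 3):
            assert sum(r.model == model for r in grid) == 24

    def test_count_significant_thresholds(self):
        mk = lambda p, i: AssociationResult(1, "left", "dbox", "g", 100, 0.1, p)
        results = [mk(p, i) for i, p in enumerate([0.01, 0.06, 0.11])]
        counts = count_significant(results)
        assert counts.loc[0, "significant"] == 1
        assert counts.loc[0, "trend"] == 1

    def test_contralateral_logic(self):
        r = AssociationResult(1, "right", "d1", "g", 500, 0.10, 0.021)
        l_null = AssociationResult(1, "left", "d1", "g", 500, 0.01, 0.904)
        out = contralateral_check([r, l_null])
        assert not out.verified.iloc[0]
        r_sig = AssociationResult(1, "right", "d1", "g", 500, 0.10, 0.01)
        l_sig = AssociationResult(1, "left", "d1", "g", 500, 0.10, 0.01)
        assert contralateral_check([r_sig, l_sig]).verified.iloc[0]
        l_flip = AssociationResult(1, "left", "d1", "g", 500, -0.10, 0.01)
        assert not contralateral_check(
            [AssociationResult(1, "right", "d1", "g", 500, 0.10, 0.01), l_flip]
        ).verified.iloc[0]

    def test_null_grid_significance_near_alpha(self, grid):
        counts = count_significant(grid)
        # 24 dependent tests at alpha=.05: a handful at most under the null
        assert counts.significant.max() <= 6


class TestPowerCorrelation:
    def test_design_power_for_small_effect(self):
        assert power_correlation(648, 0.11, 0.05) == pytest.approx(0.80, abs=0.01)

    def test_power_at_null_equals_alpha(self):
        assert power_correlation(100, 0.0, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n_and_r(self):
        powers_n = [power_correlation(n, 0.11) for n in (50, 200, 648, 2000, 10000)]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))
        assert powers_n[-1] > 0.999
        powers_r = [power_correlation(648, r) for r in (0.05, 0.11, 0.2, 0.4)]
        assert all(a < b for a, b in zip(powers_r, powers_r[1:]))

    def test_preconditions(self):
        with pytest.raises(ValueError):
            power_correlation(3, 0.1)
        with pytest.raises(ValueError):
            power_correlation(100, 1.0)
        with pytest.raises(ValueError):
            power_correlation(100, 0.1, alpha=0.0)
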