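"""Effect-size machinery: LRR, pooling, exclusion effects, meta-regression,
back-projection, predation intensity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import marshcascade.effects as eff

means = st.floats(0.1, 100)
sds = st.floats(0.0, 10)
ns = st.integers(2, 50)


class TestPredationIntensity:
    @pytest.mark.parametrize("eaten,total,expected", [
        (15, 30, 50.0), (0, 30, 0.0), (30, 30, 100.0)])
    def test_percentage(self, eaten, total, expected):
        assert eff.predation_intensity(eaten, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            eff.predation_intensity(0, 0)

    def test_wilcoxon_all_zero_is_uninformative(self):
        stat, p = eff.intensity_wilcoxon([0.0] * 5)
        assert p == 1.0

    def test_wilcoxon_positive_sites_significant(self):
        # n=8 strictly positive: exact signed-rank two-sided p = 2/2^8
        stat, p = eff.intensity_wilcoxon([40, 55, 35, 60, 20, 45, 50, 30])
        assert p == pytest.approx(2 / 256)
        assert p < 0.05


class TestLRR:
    def test_equal_means_zero(self):
        e = eff.lrr_effect(5.0, 1.0, 8, 5.0, 1.0, 8)
        assert e.lrr == 0.0

    def test_known_ratio_no_variance(self):
        e = eff.lrr_effect(2.0, 0.0, 8, 1.0, 0.0, 8)
        assert e.lrr == pytest.approx(math.log(2)) and e.var == 0.0

    @given(means, sds, ns, means, sds, ns)
    def test_antisymmetry(self, xp, sp, np_, xe, se, ne):
        a = eff.lrr_effect(xp, sp, np_, xe, se, ne)
        b = eff.lrr_effect(xe, se, ne, xp, sp, np_)
        assert a.lrr == pytest.approx(-b.lrr, abs=1e-12)
        assert a.var == pytest.approx(b.var, rel=1e-12)

    def test_variance_matches_monte_carlo_delta_oracle(self):
        # empirical var of ln(mean_P) - ln(mean_E) over lognormal samples
        rng = np.random.default_rng(5)
        mu_p, sd_p, mu_e, sd_e, n = 10.0, 2.0, 6.0, 1.5, 40
        sims = 4000
        lrrs = []
        for _ in range(sims):
            xp = rng.lognormal(math.log(mu_p) - 0.5 * math.log1p((sd_p / mu_p) ** 2),
                               math.sqrt(math.log1p((sd_p / mu_p) ** 2)), n)
            xe = rng.lognormal(math.log(mu_e) - 0.5 * math.log1p((sd_e / mu_e) ** 2),
                               math.sqrt(math.log1p((sd_e / mu_e) ** 2)), n)
            lrrs.append(math.log(xp.mean()) - math.log(xe.mean()))
        formula = eff.lrr_effect(mu_p, sd_p, n, mu_e, sd_e, n).var
        assert np.var(lrrs) == pytest.approx(formula, rel=0.10)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            eff.lrr_effect(0.0, 1.0, 8, 1.0, 1.0, 8)


class TestPooling:
    def test_single_effect_passthrough(self):
        e = eff.lrr_effect(2.0, 0.5, 8, 1.0, 0.5, 8)
        pooled = eff.pooled_random_effects([e])
        assert pooled.lrr == e.lrr and pooled.tau2 == 0.0 and pooled.k == 1

    def test_two_homogeneous_equal_variance_studies_average(self):
        effs = [eff.EffectSize(lrr=0.1, var=1.0),
                eff.EffectSize(lrr=0.2, var=1.0)]
        pooled = eff.pooled_random_effects(effs)
        assert pooled.tau2 == 0.0
        assert pooled.lrr == pytest.approx(0.15)

    def test_matches_metafor_reference(self):
        # reference values from R metafor 4.8, rma(method="DL")
        y = [0.42, -0.11, 0.63, 0.28, 0.05]
        v = [0.04, 0.09, 0.025, 0.16, 0.06]
        effs = [eff.EffectSize(lrr=a, var=b) for a, b in zip(y, v)]
        pooled = eff.pooled_random_effects(effs)
        assert pooled.lrr == pytest.approx(0.3142968593, abs=1e-8)
        assert pooled.se == pytest.approx(0.1427865298, abs=1e-8)
        assert pooled.tau2 == pytest.approx(0.0427384441, abs=1e-8)
        assert pooled.q_stat == pytest.approx(7.0820032726, abs=1e-8)

    def test_pooled_within_effect_range(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.normal(0, 1, 6)
            v = rng.uniform(0.01, 0.5, 6)
            effs = [eff.EffectSize(lrr=a, var=b) for a, b in zip(y, v)]
            pooled = eff.pooled_random_effects(effs)
            assert y.min() - 1e-12 <= pooled.lrr <= y.max() + 1e-12

    def test_ci_coverage_homogeneous(self):
        rng = np.random.default_rng(7)
        mu, sims, covered = 0.5, 2000, 0
        for _ in range(sims):
            v = rng.uniform(0.02, 0.1, 5)
            y = rng.normal(mu, np.sqrt(v))
            effs = [eff.EffectSize(lrr=a, var=b) for a, b in zip(y, v)]
            p = eff.pooled_random_effects(effs)
            covered += p.ci_low <= mu <= p.ci_high
        assert 0.93 <= covered / sims <= 0.97


def _burrow_frame(control_counts, exclusion_counts, month=6):
    rows = []
    for i, c in enumerate(control_counts):
        rows.append({"plot_id": f"c{i}", "treatment": "planting_control",
                     "year": 2021, "month": month, "burrows": c})
    for i, c in enumerate(exclusion_counts):
        rows.append({"plot_id": f"e{i}", "treatment": "planting_exclusion",
                     "year": 2021, "month": month, "burrows": c})
    return pd.DataFrame(rows)


class TestExclusionEffect:
    def test_equal_arms_zero(self):
        df = _burrow_frame([4, 5, 6, 7], [4, 5, 6, 7])
        (e,) = eff.exclusion_effect_on_crabs(df)
        assert e.lrr == pytest.approx(0.0)
        assert e.orientation == "exclusion/control"

    def test_e_fold_increase_gives_one(self):
        control = np.array([2.0, 4.0, 6.0, 8.0])
        df = _burrow_frame(control, control * math.e, month=7)
        (e,) = eff.exclusion_effect_on_crabs(df, shift=0.0)
        assert e.lrr == pytest.approx(1.0)

    def test_matches_lrr_effect_with_swapped_arms(self):
        df = _burrow_frame([3, 5, 8, 9], [10, 14, 19, 22])
        (e,) = eff.exclusion_effect_on_crabs(df)
        xc = np.array([3, 5, 8, 9]) + 1.0
        xe = np.array([10, 14, 19, 22]) + 1.0
        swapped = eff.lrr_effect(xc.mean(), xc.std(ddof=1), 4,
                                 xe.mean(), xe.std(ddof=1), 4)
        assert e.lrr == pytest.approx(-swapped.lrr)
        assert e.var == pytest.approx(swapped.var)

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            eff.exclusion_effect_on_crabs(pd.DataFrame({"plot_id": []}))


class TestModeratorRegression:
    def _make_effects(self, y, v):
        return [eff.EffectSize(lrr=a, var=b) for a, b in zip(y, v)]

    def test_constant_moderator_slope_zero(self):
        effs = self._make_effects([0.1, 0.5, 0.3, 0.2], [0.05] * 4)
        fit = eff.moderator_regression(effs, [2.0, 2.0, 2.0, 2.0])
        assert fit.slope == 0.0 and fit.p == 1.0

    def test_zero_variance_reduces_to_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = 0.3 + 0.7 * x
        effs = self._make_effects(y, [0.0] * 5)
        fit = eff.moderator_regression(effs, x)
        assert fit.slope == pytest.approx(0.7, abs=1e-9)
        assert fit.intercept == pytest.approx(0.3, abs=1e-9)

    def test_matches_metafor_reference(self):
        # reference values from R metafor 4.8, rma(mods=~x, method="DL")
        y = [0.42, -0.11, 0.63, 0.28, 0.05]
        v = [0.04, 0.09, 0.025, 0.16, 0.06]
        fit = eff.moderator_regression(self._make_effects(y, v),
                                       [1.0, 2.0, 3.0, 4.0, 5.0])
        assert fit.slope == pytest.approx(-0.0460240706, abs=1e-8)
        assert fit.se == pytest.approx(0.1141919969, abs=1e-8)
        assert fit.tau2 == pytest.approx(0.0707543771, abs=1e-8)
        assert fit.intercept == pytest.approx(0.4318795245, abs=1e-8)

    def test_slope_recovery_coverage(self):
        rng = np.random.default_rng(11)
        beta, sims, covered = 0.05, 500, 0
        x = np.linspace(0, 10, 12)
        for _ in range(sims):
            v = rng.uniform(0.02, 0.08, x.size)
            y = 0.2 + beta * x + rng.normal(0, np.sqrt(v))
            fit = eff.moderator_regression(self._make_effects(y, v), x)
            covered += fit.ci_low <= beta <= fit.ci_high
        assert covered / sims >= 0.93

    def test_too_few_effects_rejected(self):
        with pytest.raises(ValueError):
            eff.moderator_regression(self._make_effects([0.1], [0.1]), [1.0])


class TestBackProjection:
    def test_no_exclusion_effect(self):
        inp = eff.BackProjectionInputs(10.0, 10.0, 0.8, 50.0, 5.0)
        assert eff.back_project_crabs(inp) == pytest.approx(10.0)

    def test_no_population_change(self):
        inp = eff.BackProjectionInputs(10.0, 30.0, 0.8, 7.0, 7.0)
        assert eff.back_project_crabs(inp) == pytest.approx(10.0)

    def test_hand_arithmetic(self):
        # 10 + (-20 / 0.8) * 9 = -215
        inp = eff.BackProjectionInputs(10.0, 30.0, 0.8, 10.0, 1.0)
        assert eff.back_project_crabs(inp) == pytest.approx(-215.0)

    @given(st.floats(1, 20), st.floats(21, 60), st.floats(0.1, 1.0),
           st.floats(1, 100))
    def test_decreasing_in_historical_population(self, dc, de, p, n_now):
        lo = eff.back_project_crabs(
            eff.BackProjectionInputs(dc, de, p, n_now + 1, n_now))
        hi = eff.back_project_crabs(
            eff.BackProjectionInputs(dc, de, p, n_now + 50, n_now))
        assert hi < lo

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            eff.back_project_crabs(
                eff.BackProjectionInputs(10, 30, 1.5, 10, 1))
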