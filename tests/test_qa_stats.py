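"""Distribution summaries, heteroscedastic tests and tolerance flagging."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from protonqa.compare import compute_deviations, match_spots
from protonqa.errors import ValidationError
from protonqa.qa_stats import (
    ToleranceConfig,
    expected_squared_distance,
    factor_analysis,
    games_howell,
    levene_test,
    moving_window_flags,
    summarize,
    welch_anova,
)
from protonqa.simulator import (
    ErrorModelConfig,
    iter_campaign_sessions,
    simulate_session,
)


class TestSummarize:
    def test_constant_sample(self):
        s = summarize([1, 1, 1])
        assert (s.n, s.mean, s.sd) == (3, 1.0, 0.0)

    def test_two_point_sample(self):
        s = summarize([0, 2])
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(np.sqrt(2))
        assert s.gaussian_fit == (s.mean, s.sd)

    def test_monte_carlo_moments(self, rng):
        draws = rng.normal(0.163, 0.199, 1_000_000)
        s = summarize(draws)
        assert abs(s.mean - 0.163) < 3 * 0.199 / 1000

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize([])


class TestExpectedSquaredDistance:
    def test_study_parameters_give_printed_mean(self):
        # x: 0.163 +/- 0.199 mm, y: 0.096 +/- 0.151 mm -> 0.098 mm^2
        assert round(expected_squared_distance(0.163, 0.199, 0.096, 0.151), 3) == 0.098

    def test_zero(self):
        assert expected_squared_distance(0, 0, 0, 0) == 0.0

    def test_matches_monte_carlo(self, rng):
        mu_x, sd_x, mu_y, sd_y = 0.5, 0.2, 0.0, 0.3
        dx = rng.normal(mu_x, sd_x, 1_000_000)
        dy = rng.normal(mu_y, sd_y, 1_000_000)
        d2 = dx**2 + dy**2
        expected = expected_squared_distance(mu_x, sd_x, mu_y, sd_y)
        assert expected == pytest.approx(0.38, abs=0.005)
        assert abs(d2.mean() - expected) < 3 * d2.std(ddof=1) / 1000


class TestLevene:
    def test_identical_groups_w_zero(self, rng):
        g = rng.normal(0, 1, 50)
        w, p = levene_test([g, g.copy()])
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_detects_unequal_variances(self, rng):
        w, p = levene_test([rng.normal(0, 1, 200), rng.normal(0, 10, 200)])
        assert p < 0.05

    def test_null_p_rarely_tiny(self):
        # same-distribution groups: p > 0.001 in >= 99% of replicates
        rng = np.random.default_rng(77)
        ok = sum(
            levene_test([rng.normal(0, 1, 100), rng.normal(0, 1, 100)])[1] > 0.001
            for _ in range(300)
        )
        assert ok >= 297

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            levene_test([[1.0], [1.0, 2.0]])


class TestWelchAnova:
    def test_two_groups_equal_welch_t_squared(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(1, 3, 50)
        f, df1, df2, p = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t.statistic**2, rel=1e-10)
        assert p == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_reference_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        groups = [rng.normal(0, 1, 50), rng.normal(1, 3, 50), rng.normal(0.5, 5, 70)]
        f, df1, df2, p = welch_anova(groups)
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat([0, 1, 2], [50, 50, 70])}
        )
        ref = pg.welch_anova(dv="y", between="g", data=df)
        assert f == pytest.approx(float(ref["F"].iloc[0]), abs=1e-6)
        assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), abs=1e-6)

    def test_reduces_to_oneway_anova_when_homoscedastic(self, rng):
        # equal group sizes and (population) variances: Welch F tracks the
        # classic one-way F closely
        groups = [rng.normal(m, 1.0, 2000) for m in (0.0, 0.05, 0.1)]
        f_w, _, _, _ = welch_anova(groups)
        f_c, _ = sps.f_oneway(*groups)
        assert f_w == pytest.approx(f_c, rel=0.02)

    def test_null_type_one_error_calibrated(self):
        # heteroscedastic null at alpha = 0.05, 2000 replicates
        rng = np.random.default_rng(1234)
        rej = sum(
            welch_anova(
                [rng.normal(0, 1, 20), rng.normal(0, 3, 30), rng.normal(0, 10, 40)]
            )[3]
            < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rej / 2000 <= 0.07

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValidationError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])


class TestGamesHowell:
    def test_identical_groups(self, rng):
        g = rng.normal(0, 1, 40)
        table = games_howell([g, g.copy(), g.copy()])
        assert np.allclose(table["mean_diff"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_shifted_group_detected(self, rng):
        groups = [rng.normal(0, 1, 100), rng.normal(0, 1, 100), rng.normal(5, 1, 100)]
        table = games_howell(groups, labels=["a", "b", "c"])
        by_pair = {(r.group_a, r.group_b): r.p for r in table.itertuples()}
        assert by_pair[("a", "c")] < 0.01
        assert by_pair[("b", "c")] < 0.01
        assert by_pair[("a", "b")] > 0.05

    def test_two_group_p_agrees_with_welch_t(self, rng):
        a, b = rng.normal(0, 1, 60), rng.normal(0.4, 2, 45)
        table = games_howell([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert table["p"].iloc[0] == pytest.approx(t.pvalue, abs=1e-3)

    def test_matches_reference_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        groups = [rng.normal(0, 1, 30), rng.normal(0.5, 2, 40), rng.normal(1, 4, 50)]
        table = games_howell(groups)
        df = pd.DataFrame(
            {"y": np.concatenate(groups), "g": np.repeat([0, 1, 2], [30, 40, 50])}
        )
        ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        np.testing.assert_allclose(table["p"], ref["pval"], atol=1e-6)
        np.testing.assert_allclose(table["df"], ref["df"], atol=1e-6)


def _dev_table(dx, dy=None, window_room="G1", date=dt.date(2025, 5, 1), layers=None):
    n = len(dx)
    return pd.DataFrame(
        {
            "room": window_room,
            "date": date,
            "layer_index": np.zeros(n, int) if layers is None else layers,
            "spot_index": np.arange(n),
            "energy": 100.0,
            "dx": dx,
            "dy": np.zeros(n) if dy is None else dy,
            "d": np.hypot(dx, np.zeros(n) if dy is None else dy),
            "d2": np.asarray(dx) ** 2,
            "dmu": np.zeros(n),
        }
    )


def brute_force_flags(values, window, tol):
    """Naive O(n*window) re-scan: spot flagged iff any covering window's
    |mean| > tol."""
    n = len(values)
    flagged = np.zeros(n, dtype=bool)
    for start in range(n - window + 1):
        if abs(np.mean(values[start : start + window])) > tol:
            flagged[start : start + window] = True
    return flagged


class TestMovingWindowFlags:
    def test_zero_deviations_no_flags(self):
        table = _dev_table(np.zeros(200))
        report = moving_window_flags(table, ToleranceConfig(window=50))
        assert report.counts("annual") == 0
        assert report.counts("daily") == 0

    def test_constant_exceedance_flags_every_spot_all_layers(self):
        layers = np.repeat(np.arange(4), 50)
        table = _dev_table(np.full(200, 1.1), layers=layers)
        report = moving_window_flags(table, ToleranceConfig(window=50))
        sf = next(iter(report.sessions.values()))
        assert sf.annual.all()
        assert not sf.daily.any()  # 1.1 mm < 2.0 mm daily tolerance
        assert sf.affected_layers_annual == [0, 1, 2, 3]
        assert report.counts("annual") == 200

    def test_localized_offset_matches_brute_force(self):
        rng = np.random.default_rng(8)
        layers = np.repeat(np.arange(20), 30)
        dx = rng.normal(0, 0.2, 600)
        dx[(layers >= 5) & (layers <= 8)] += 1.1
        table = _dev_table(dx, layers=layers)
        report = moving_window_flags(table, ToleranceConfig(window=50))
        sf = next(iter(report.sessions.values()))
        expected = brute_force_flags(dx, 50, 1.0)
        np.testing.assert_array_equal(sf.annual_x, expected)
        assert set(sf.affected_layers_annual) <= set(range(4, 10))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rolling_equals_brute_force_on_noise(self, seed):
        rng = np.random.default_rng(seed)
        dx = rng.normal(0.8, 0.8, 400)  # means hover near the tolerance
        dy = rng.normal(-0.8, 0.8, 400)
        table = _dev_table(dx, dy)
        report = moving_window_flags(table, ToleranceConfig(window=25))
        sf = next(iter(report.sessions.values()))
        np.testing.assert_array_equal(sf.annual_x, brute_force_flags(dx, 25, 1.0))
        np.testing.assert_array_equal(sf.annual_y, brute_force_flags(dy, 25, 1.0))
        np.testing.assert_array_equal(sf.daily_x, brute_force_flags(dx, 25, 2.0))
        np.testing.assert_array_equal(
            sf.annual, brute_force_flags(dx, 25, 1.0) | brute_force_flags(dy, 25, 1.0)
        )

    def test_window_larger_than_session_rejected(self):
        with pytest.raises(ValidationError):
            moving_window_flags(_dev_table(np.zeros(10)), ToleranceConfig(window=50))

    def test_windows_never_span_sessions(self):
        # two sessions each individually in tolerance, but whose concatenation
        # would exceed it: must produce zero flags
        a = _dev_table(np.full(60, 0.9), window_room="G1")
        b = _dev_table(np.full(60, 1.05) * -1, window_room="G2")
        table = pd.concat([a, b], ignore_index=True)
        report = moving_window_flags(table, ToleranceConfig(window=50))
        assert report.counts("annual") == 60  # only G2's own windows exceed
        assert report.sessions[("G1", dt.date(2025, 5, 1))].annual.sum() == 0


class TestFactorAnalysis:
    def _campaign_table(self, spec):
        frames = [
            compute_deviations(match_spots(spec.plan, s), spec.factors)
            for _, _, s, _ in iter_campaign_sessions(spec)
        ]
        return pd.concat(frames, ignore_index=True)

    def test_injected_room_effect_detected(self, small_campaign):
        small_campaign.error_model.room_offsets = {"G1": (0.0, 0.0), "G2": (0.3, 0.0)}
        table = self._campaign_table(small_campaign)
        res = factor_analysis(table, "room", "dx")
        assert not res.skipped
        assert res.welch[3] < 0.05
        assert len(res.games_howell) == 1

    def test_null_jitter_rarely_significant(self, small_plan):
        # i.i.d. jitter only: each factor non-significant in >= 90% of reps
        from protonqa.simulator import CampaignSpec

        hits = {"energy": 0, "date": 0, "room": 0}
        reps = 20
        for rep in range(reps):
            spec = CampaignSpec(
                rooms=["G1", "G2"],
                dates=[dt.date(2025, 5, d) for d in (1, 8)],
                plan=small_plan,
                error_model=ErrorModelConfig(sigma_x=0.2, sigma_y=0.2),
                seed=1000 + rep,
            )
            table = self._campaign_table(spec)
            for factor in hits:
                res = factor_analysis(table, factor, "dx")
                hits[factor] += res.welch[3] > 0.05
        for factor, n_ok in hits.items():
            assert n_ok >= int(0.9 * reps) - 1, (factor, n_ok)

    def test_single_room_skipped_with_warning(self, small_plan, null_model):
        s = simulate_session(
            small_plan, "G1", dt.date(2025, 5, 1),
            ErrorModelConfig(sigma_x=0.2, sigma_y=0.2), seed=3,
        )
        table = compute_deviations(match_spots(small_plan, s))
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = factor_analysis(table, "room", "dx")
        assert res.skipped

    def test_energy_factor_detects_slope(self, small_campaign):
        small_campaign.error_model.energy_slope = (0.02, 0.0)
        table = self._campaign_table(small_campaign)
        res = factor_analysis(table, "energy", "dx")
        assert res.welch[3] < 0.05
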