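import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from speccurve import cleaning as cl
from speccurve import scales as scl
from speccurve import simulate as sim
from speccurve.cleaning import (CleaningReport, clean_dataset, flag_outliers,
                                reverse_wellbeing, score_scale,
                                weekly_game_time)
from speccurve.scales import ScaleDefinition


class TestCleanDataset:
    def test_study_counts_fixture(self):
        """743 starters, 289 incomplete, 30 careless completers -> 424."""
        df, _ = sim.generate_dataset(sim.GeneratorConfig(seed=0))
        retained, rep = clean_dataset(df)
        assert (rep.n_initial, rep.n_incomplete_removed,
                rep.n_careless_removed, rep.n_retained) == (743, 289, 30, 424)
        assert len(retained) == 424
        assert retained[scl.all_item_columns()].notna().all().all()

    def test_all_complete_noop(self, survey424):
        df, _ = survey424
        retained, rep = clean_dataset(df)
        assert (rep.n_incomplete_removed, rep.n_careless_removed) == (0, 0)
        assert rep.n_retained == len(df)

    def test_sensitivity_mode_removes_nobody(self):
        df, _ = sim.generate_dataset(sim.GeneratorConfig(
            n_respondents=120, seed=3))
        retained, rep = clean_dataset(df, sensitivity_mode=True)
        assert len(retained) == 120
        assert rep.sensitivity_mode
        assert rep.n_retained == rep.n_initial == 120

    def test_missing_check_columns_schema_error(self):
        df = pd.DataFrame({"respondent_id": [1], "vat_1": [3]})
        with pytest.raises(KeyError):
            clean_dataset(df)

    def test_conservation_invariant(self):
        df, _ = sim.generate_dataset(sim.GeneratorConfig(
            n_respondents=200, seed=17))
        _, rep = clean_dataset(df)
        assert rep.n_initial == (rep.n_incomplete_removed
                                 + rep.n_careless_removed + rep.n_retained)
        with pytest.raises(ValueError):
            CleaningReport(10, 4, 4, 4)

    def test_careless_removals_match_ground_truth(self):
        df, truth = sim.generate_dataset(sim.GeneratorConfig(
            n_respondents=500, seed=8))
        retained, rep = clean_dataset(df)
        assert rep.n_careless_removed == len(truth.careless_ids)
        assert not set(truth.careless_ids) & \
            set(retained["respondent_id"])


class TestScoring:
    def test_constant_and_reverse(self):
        scale = ScaleDefinition("s", ("a", "b"), reverse=("b",))
        df = pd.DataFrame({"a": [3.0, 5.0], "b": [3.0, 5.0]})
        out = score_scale(df, scale)
        assert out.iloc[0] == 3.0          # all items 3
        assert out.iloc[1] == (5 + 1) / 2  # reverse coding: 6 - 5

    def test_brute_force_mean_oracle(self):
        rng = np.random.default_rng(0)
        items = tuple(f"i{k}" for k in range(11))
        rev = items[3:5]
        scale = ScaleDefinition("s", items, reverse=rev)
        df = pd.DataFrame(rng.integers(1, 6, (40, 11)).astype(float),
                          columns=items)
        got = score_scale(df, scale).to_numpy()
        expected = np.array([
            np.mean([6 - row[c] if c in rev else row[c] for c in items])
            for _, row in df.iterrows()])
        assert np.abs(got - expected).max() < 1e-12

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        items = tuple(f"i{k}" for k in range(6))
        df = pd.DataFrame(rng.integers(1, 6, (20, 6)).astype(float),
                          columns=items)
        s1 = score_scale(df, ScaleDefinition("s", items, reverse=("i2",)))
        perm = ("i4", "i0", "i2", "i5", "i1", "i3")
        s2 = score_scale(df, ScaleDefinition("s", perm, reverse=("i2",)))
        assert np.allclose(s1, s2)

    def test_core_only_and_missing(self):
        scale = ScaleDefinition("s", ("a", "b", "c"), core=("a", "c"))
        df = pd.DataFrame({"a": [1.0], "b": [5.0], "c": [3.0]})
        assert score_scale(df, scale, core_only=True).iloc[0] == 2.0
        df.loc[0, "c"] = np.nan
        with pytest.raises(ValueError):
            score_scale(df, scale)
        assert np.isnan(score_scale(df, scale, on_missing="nan").iloc[0])

    @pytest.mark.parametrize("wd,we,expected", [
        (2.0, 4.0, 18.0), (0.0, 0.0, 0.0), (3.0, 5.0, 25.0)])
    def test_weekly_game_time(self, wd, we, expected):
        assert weekly_game_time(wd, we) == expected

    def test_weekly_game_time_negative_rejected(self):
        with pytest.raises(ValueError):
            weekly_game_time(-1.0, 2.0)

    @given(st.floats(1.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_reversal_involution(self, x):
        assert reverse_wellbeing(reverse_wellbeing(x)) == pytest.approx(x)

    @pytest.mark.parametrize("x,expected", [(1.0, 5.0), (3.0, 3.0),
                                            (4.5, 1.5)])
    def test_reverse_values(self, x, expected):
        assert reverse_wellbeing(x) == expected


class TestFlagOutliers:
    @staticmethod
    def _frame(weekly_h, session=None):
        n = len(weekly_h)
        return pd.DataFrame({
            "respondent_id": np.arange(1, n + 1),
            "weekday_hours": np.asarray(weekly_h) / 5.0,
            "weekend_hours": np.zeros(n),
            "session_minutes": np.full(n, 60.0) if session is None
            else np.asarray(session, dtype=float),
        })

    def test_zero_variance_no_flags(self):
        df = self._frame(np.full(50, 20.0))
        assert flag_outliers(df) == set()

    def test_extreme_respondent_flagged(self):
        # direct mean/SD oracle: only the 500-hour respondent exceeds 3 SD
        weekly = np.concatenate([np.full(100, 20.0), [500.0]])
        rng = np.random.default_rng(0)
        weekly[:100] += rng.normal(0, 1.0, 100)
        df = self._frame(weekly)
        mu, sd = weekly.mean(), weekly.std(ddof=1)
        oracle = set(df.loc[weekly >= mu + 3 * sd, "respondent_id"])
        assert flag_outliers(df) == oracle == {101}

    def test_zero_weekly_time_flagged(self):
        weekly = np.concatenate([np.full(30, 20.0)
                                 + np.arange(30) * 0.1, [0.0]])
        df = self._frame(weekly)
        assert 31 in flag_outliers(df)

    def test_session_duration_rule(self):
        session = np.concatenate([np.full(60, 60.0)
                                  + np.arange(60), [2000.0]])
        df = self._frame(np.full(61, 20.0) + np.arange(61) * 0.01, session)
        assert 61 in flag_outliers(df)
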