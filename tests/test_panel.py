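"""Panel container, I/O, filters, pair extraction and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import adforecast as af
from adforecast.panel import SIGNS, PanelValidationError
from conftest import make_panel_df


class TestReadPanel:
    def test_well_formed_csv_round_trips(self, tmp_path):
        df = make_panel_df({"A": {"all": [1, 2, 3]}, "B": {"all": [0, 4, 2]}})
        p = tmp_path / "panel.csv"
        df.to_csv(p, index=False)
        ds = af.read_panel(p)
        assert len(ds) == 6
        assert ds.patients == ["A", "B"]

    def test_out_of_range_score_rejected_naming_cell(self, tmp_path):
        df = make_panel_df({"A": {"all": [1, 5, 3]}})
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(PanelValidationError, match="dryness"):
            af.read_panel(p)

    def test_day_gaps_accepted_as_absent_days(self, tmp_path):
        df = make_panel_df({"A": {"all": [1, 2, 3, 4]}})
        df = df[df["day"] != 3]
        p = tmp_path / "gap.csv"
        df.to_csv(p, index=False)
        ds = af.read_panel(p)
        assert list(ds.data["day"]) == [1, 2, 4]

    def test_schema_remapping(self, tmp_path):
        df = make_panel_df({"A": {"all": [1, 2]}}).rename(columns={"patient_id": "pid"})
        p = tmp_path / "renamed.csv"
        df.to_csv(p, index=False)
        ds = af.read_panel(p, schema={"patient_id": "pid"})
        assert ds.patients == ["A"]

    def test_duplicate_patient_day_rejected(self):
        df = make_panel_df({"A": {"all": [1, 2]}})
        with pytest.raises(PanelValidationError, match="duplicate"):
            af.PanelDataset(pd.concat([df, df.iloc[[0]]]))

    def test_missing_cells_preserved(self):
        df = make_panel_df({"A": {"all": [1, None, 3]}})
        ds = af.PanelDataset(df)
        assert np.isnan(ds.data["dryness"].iloc[1])


class TestMinObservationsFilter:
    def _panel(self, n_obs_a):
        scores = {"A": {"all": [1] * n_obs_a}, "B": {"all": [2] * 12}}
        return af.PanelDataset(make_panel_df(scores))

    def test_patient_below_threshold_removed(self):
        ds = af.filter_min_observations(self._panel(9), 10)
        assert ds.patients == ["B"]

    def test_boundary_patient_retained(self):
        ds = af.filter_min_observations(self._panel(10), 10)
        assert ds.patients == ["A", "B"]

    def test_min_one_keeps_everything(self):
        ds = self._panel(5)
        assert af.filter_min_observations(ds, 1).patients == ds.patients

    def test_idempotent(self):
        once = af.filter_min_observations(self._panel(9), 10)
        twice = af.filter_min_observations(once, 10)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_partially_missing_day_counts_as_observed(self):
        df = make_panel_df({"A": {"dryness": [1, None], "oedema": [None, 2]}})
        ds = af.filter_min_observations(af.PanelDataset(df), 2)
        assert ds.patients == ["A"]


class TestTransitionPairs:
    def test_gap_in_scores_breaks_pairs(self):
        df = make_panel_df({"A": {"all": [2, None, 1, 1]}})
        pairs = af.extract_transition_pairs(af.PanelDataset(df), "dryness")
        assert [(p.day, p.s_t, p.s_next) for p in pairs] == [(3, 1, 1)]

    def test_fully_observed_series_gives_t_minus_one_pairs(self):
        df = make_panel_df({"A": {"all": [0, 1, 2, 3, 4, 3, 2]}})
        pairs = af.extract_transition_pairs(af.PanelDataset(df), "itching")
        assert len(pairs) == 6

    def test_day_gap_breaks_pairs(self):
        df = make_panel_df({"A": {"all": [1, 2, 3]}})
        df.loc[df["day"] == 2, "day"] = 5  # days 1, 5, 3 -> sorted 1, 3, 5
        pairs = af.extract_transition_pairs(af.PanelDataset(df), "dryness")
        assert pairs == []

    def test_missing_covariate_drops_pair_only_when_requested(self):
        df = make_panel_df(
            {"A": {"all": [1, 2, 3]}}, covariates={"pm10": [50.0, np.nan, 40.0]}
        )
        ds = af.PanelDataset(df)
        with_cov = af.extract_transition_pairs(ds, "dryness", ("pm10",))
        without = af.extract_transition_pairs(ds, "dryness")
        assert [p.day for p in with_cov] == [1]
        assert [p.day for p in without] == [1, 2]

    def test_unknown_sign_or_covariate_rejected(self):
        ds = af.PanelDataset(make_panel_df({"A": {"all": [1, 2]}}))
        with pytest.raises(ValueError, match="unknown sign"):
            af.extract_transition_pairs(ds, "swelling")
        with pytest.raises(ValueError, match="unknown covariate"):
            af.extract_transition_pairs(ds, "dryness", ("humidity",))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pair_count_matches_bruteforce_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        scores = {}
        for k in range(3):
            vals = rng.integers(0, 5, size=12).astype(float)
            vals[rng.random(12) < 0.35] = np.nan
            scores[f"p{k}"] = {"all": [None if np.isnan(v) else v for v in vals]}
        ds = af.PanelDataset(make_panel_df(scores))
        pairs = af.extract_transition_pairs(ds, "redness")
        expected = 0
        for _, sub in ds.data.groupby("patient_id"):
            days = dict(zip(sub["day"], sub["redness"]))
            for d, v in days.items():
                if d + 1 in days and not np.isnan(v) and not np.isnan(days[d + 1]):
                    expected += 1
        assert len(pairs) == expected


class TestSymptomState:
    def test_boundary_case_is_state_one(self):
        scores = dict(itching=1, sleep=1, redness=1, dryness=1, oedema=0, oozing=0)
        assert af.derive_symptom_state(scores) == 1

    def test_single_nonzero_skin_sign_is_state_zero(self):
        scores = dict(itching=4, sleep=4, redness=1, dryness=0, oedema=0, oozing=0)
        assert af.derive_symptom_state(scores) == 0

    def test_all_zero_is_state_zero(self):
        assert af.derive_symptom_state({s: 0 for s in SIGNS}) == 0

    def test_missing_score_raises(self):
        scores = {s: 1 for s in SIGNS}
        scores["sleep"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            af.derive_symptom_state(scores)

    def test_agrees_with_bruteforce_over_all_combinations(self):
        grids = np.stack(np.meshgrid(*[np.arange(5)] * 6, indexing="ij"), -1).reshape(-1, 6)
        for combo in grids[::7]:  # every 7th of the 15,625 combinations
            scores = dict(zip(SIGNS, (int(v) for v in combo)))
            expected = int(
                (scores["itching"] + scores["sleep"] >= 2)
                and sum(scores[s] > 0 for s in ("redness", "dryness", "oedema", "oozing")) >= 2
            )
            assert af.derive_symptom_state(scores) == expected


class TestStandardize:
    def _pairs(self, values):
        return [
            af.TransitionPair("A", d + 1, 1, 1, covariates=(v,))
            for d, v in enumerate(values)
        ]

    def test_two_point_sample_maps_to_plus_minus_one(self):
        out, stats = af.standardize_covariates(self._pairs([0.0, 2.0]), ("temp",))
        assert [p.covariates[0] for p in out] == [-1.0, 1.0]

    def test_reused_stats_center_new_data(self):
        _, stats = af.standardize_covariates(self._pairs([0.0, 2.0]), ("temp",))
        out, _ = af.standardize_covariates(self._pairs([1.0]), ("temp",), stats)
        assert out[0].covariates[0] == 0.0

    def test_tcs_passes_through_unscaled(self):
        pairs = [af.TransitionPair("A", d, 1, 1, covariates=(float(d % 2),)) for d in range(4)]
        out, _ = af.standardize_covariates(pairs, ("tcs",))
        assert [p.covariates[0] for p in out] == [0.0, 1.0, 0.0, 1.0]

    def test_zero_variance_names_covariate(self):
        with pytest.raises(ValueError, match="rh"):
            af.standardize_covariates(self._pairs([3.0, 3.0]), ("rh",))

    def test_round_trip_restores_values(self):
        vals = [1.0, 5.0, 2.5, -3.0]
        out, stats = af.standardize_covariates(self._pairs(vals), ("temp",))
        restored = [stats.inverse(np.array(p.covariates))[0] for p in out]
        np.testing.assert_allclose(restored, vals, atol=1e-12)


class TestCrossCorrelogram:
    def test_identity_covariate_peaks_at_lag_zero(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 5, 80).astype(float)
        df = make_panel_df({"A": {"all": list(s)}}, covariates={"temp": list(s - s.mean())})
        tab = af.cross_correlogram(af.PanelDataset(df), "dryness", "temp", 3)
        assert tab.loc[tab["lag"] == 0, "correlation"].iloc[0] == pytest.approx(1.0)

    def test_shifted_covariate_peaks_at_the_shift(self):
        rng = np.random.default_rng(1)
        s = rng.integers(0, 5, 120).astype(float)
        x = np.roll(s, -2)  # x(t) = s(t+2), so x(t-2) aligns with s(t)
        df = make_panel_df({"A": {"all": list(s)}}, covariates={"temp": list(x)})
        tab = af.cross_correlogram(af.PanelDataset(df), "dryness", "temp", 4)
        best = tab.loc[tab["correlation"].idxmax()]
        assert best["lag"] == 2
        assert best["correlation"] > 0.95

    def test_independent_noise_gives_small_correlations(self):
        rng = np.random.default_rng(2)
        scores = {f"p{k}": {"all": list(rng.integers(0, 5, 200))} for k in range(5)}
        df = make_panel_df(scores, covariates=None)
        df["temp"] = rng.normal(size=len(df))
        tab = af.cross_correlogram(af.PanelDataset(df), "dryness", "temp", 3)
        assert np.all(np.abs(tab["correlation"]) < 0.1)

    def test_insufficient_data_reports_nan_not_error(self):
        df = make_panel_df({"A": {"all": [1, 2]}}, covariates={"temp": [1.0, 2.0]})
        tab = af.cross_correlogram(af.PanelDataset(df), "dryness", "temp", 3)
        assert np.isnan(tab.loc[tab["lag"] == 3, "correlation"].iloc[0])
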