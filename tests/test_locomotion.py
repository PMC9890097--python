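"""Locomotor bouts, speed-model fitting and distance accumulation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import quollacc as q


def rle_bouts(labels, targets):
    """Run-length-encoding oracle for bout extraction."""
    out = []
    pos = 0
    for lab, grp in itertools.groupby(labels):
        n = len(list(grp))
        if lab in targets:
            out.append((lab, pos, n))
        pos += n
    return out


class TestExtractBouts:
    def test_walking_runs(self):
        labels = ["Walking"] * 3 + ["Sitting"] + ["Walking"] * 2
        bouts = q.extract_bouts(labels, ["Walking"])
        assert list(bouts["duration_s"]) == [3.0, 2.0]
        assert list(bouts["start_s"]) == [0.0, 4.0]

    def test_alternating_gives_unit_bouts(self):
        labels = ["Walking", "Sitting"] * 2
        bouts = q.extract_bouts(labels, ["Walking"])
        assert list(bouts["duration_s"]) == [1.0, 1.0]

    def test_label_change_between_gaits_breaks_bout(self):
        labels = ["Walking", "Galloping", "Walking"]
        bouts = q.extract_bouts(labels, ["Walking", "Galloping"])
        assert len(bouts) == 3

    def test_matches_rle_oracle(self, rng):
        labels = rng.choice(["Walking", "Galloping", "Sitting", "Bounding"], 500)
        targets = {"Walking", "Bounding"}
        bouts = q.extract_bouts(labels, targets)
        want = rle_bouts(labels, targets)
        assert len(bouts) == len(want)
        for row, (lab, pos, n) in zip(bouts.itertuples(), want):
            assert (row.behavior, row.start_s, row.duration_s) == (lab, pos, n)

    def test_mean_vba_over_run(self):
        labels = ["Walking"] * 3 + ["Sitting"] * 2
        vba = [2.0, 3.0, 4.0, 1.0, 1.0]
        bouts = q.extract_bouts(labels, ["Walking"], epoch_vba=vba)
        assert bouts.loc[0, "mean_vba"] == pytest.approx(3.0)

    def test_empty_result_allowed(self):
        assert len(q.extract_bouts(["Sitting"] * 5, ["Walking"])) == 0


class TestFitSpeedModel:
    def test_noiseless_exact_recovery(self):
        spec = q.CalibrationSpec(
            coef={"Walking": (0.2, 1.5)}, n_bouts=20,
            vba_range={"Walking": (1.0, 4.0)}, residual_sd=0.0, seed=0)
        model = q.fit_speed_model(q.generate_calibration(spec))
        a, b = model.coef["Walking"]
        assert a == pytest.approx(0.2, abs=1e-10)
        assert b == pytest.approx(1.5, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0)

    def test_recovery_within_three_se(self):
        spec = q.CalibrationSpec(n_bouts=200, residual_sd=0.05, seed=3)
        model = q.fit_speed_model(q.generate_calibration(spec))
        for gait, (a_true, b_true) in spec.coef.items():
            a, b = model.coef[gait]
            se_a, se_b = model.se[gait]
            assert abs(a - a_true) < 3 * se_a
            assert abs(b - b_true) < 3 * se_b

    def test_slope_ordering_preserved(self):
        spec = q.CalibrationSpec(
            coef={"Walking": (0.0, 0.8), "Bounding": (0.0, 1.6)},
            n_bouts=100, residual_sd=0.02, seed=5,
            vba_range={"Walking": (1.2, 3.2), "Bounding": (4.5, 8.0)})
        model = q.fit_speed_model(q.generate_calibration(spec))
        assert model.coef["Walking"][1] < model.coef["Bounding"][1]

    def test_too_few_bouts_rejected(self):
        df = pd.DataFrame({"gait": ["Walking"] * 2,
                           "mean_vba": [1.0, 2.0], "speed": [0.5, 1.0]})
        with pytest.raises(ValueError, match="Walking"):
            q.fit_speed_model(df)

    def test_non_positive_values_rejected_with_row(self):
        df = pd.DataFrame({"gait": ["Walking"] * 3,
                           "mean_vba": [1.0, -2.0, 3.0],
                           "speed": [0.5, 1.0, 1.5]})
        with pytest.raises(ValueError, match="row 1"):
            q.fit_speed_model(df)


class TestPredictSpeed:
    def identity_model(self):
        return q.SpeedModel(coef={"Walking": (0.0, 1.0)},
                            se={"Walking": (0.0, 0.0)},
                            r_squared=1.0, residual_var=0.0)

    def test_identity(self):
        assert q.predict_speed(self.identity_model(), "Walking", 2.5) == \
            pytest.approx(2.5)

    def test_monotone_in_vba(self):
        m = self.identity_model()
        v = np.array([1.0, 2.0, 4.0])
        s = q.predict_speed(m, "Walking", v)
        assert (np.diff(s) > 0).all()

    def test_gallop_uses_walking_coefficients(self):
        m = self.identity_model()
        assert q.predict_speed(m, "Galloping", 3.0) == \
            q.predict_speed(m, "Walking", 3.0)

    def test_round_trip_with_zero_noise(self):
        spec = q.CalibrationSpec(residual_sd=0.0, n_bouts=25, seed=7)
        tab = q.generate_calibration(spec)
        model = q.fit_speed_model(tab)
        for row in tab.itertuples():
            assert q.predict_speed(model, row.gait, row.mean_vba) == \
                pytest.approx(row.speed, rel=1e-9)

    def test_missing_gait_rejected(self):
        with pytest.raises(ValueError, match="Jumping"):
            q.predict_speed(self.identity_model(), "Jumping", 2.0)

    def test_non_positive_vba_rejected(self):
        with pytest.raises(ValueError):
            q.predict_speed(self.identity_model(), "Walking", 0.0)


class TestDistance:
    def test_simple_product(self):
        assert q.bout_distance(0.5, 120.0) == 60.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            q.bout_distance(1.0, 0.0)

    def test_daily_totals_match_brute_force(self, rng):
        n = 50
        bouts = pd.DataFrame({
            "start_s": rng.uniform(0, 3 * 86400, n),
            "distance_m": rng.uniform(10, 500, n),
            "individual": rng.choice(["a", "b"], n),
        })
        daily = q.daily_distance(bouts)
        for row in daily.itertuples():
            mask = ((bouts["individual"] == row.individual)
                    & (bouts["start_s"] // 86400 == row.day))
            assert row.distance_km == pytest.approx(
                bouts.loc[mask, "distance_m"].sum() / 1000.0)

    def test_midnight_bout_assigned_by_start(self):
        bouts = pd.DataFrame({
            "start_s": [86390.0],  # starts on day 0, runs into day 1
            "duration_s": [120.0],
            "distance_m": [60.0],
            "individual": ["a"],
        })
        daily = q.daily_distance(bouts)
        assert list(daily["day"]) == [0]

    def test_order_invariant(self, rng):
        n = 30
        bouts = pd.DataFrame({
            "start_s": rng.uniform(0, 86400, n),
            "distance_m": rng.uniform(1, 100, n),
            "individual": ["a"] * n,
        })
        shuffled = bouts.sample(frac=1, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            q.daily_distance(bouts), q.daily_distance(shuffled))
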