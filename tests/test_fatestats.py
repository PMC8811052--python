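"""Cohort statistics: KM oracle equivalence, extravasation arithmetic,
outcome fractions, motility projection, and the test-selection screen."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lungfate.fatestats import (
    compare_groups,
    extravasation_stats,
    km_retention,
    motility_analysis,
    survival_outcomes,
)
from lungfate.synthetic import simulate_timelapse
from lungfate.tracking import CellTrack


def hand_product_limit(durations, events, grid):
    """Independent product-limit oracle: direct textbook computation."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    for t in grid:
        s = 1.0
        for u in sorted(set(durations[(events == 1) & (durations <= t)])):
            d = int(np.sum((durations == u) & (events == 1)))
            n_at_risk = int(np.sum(durations >= u))
            s *= 1.0 - d / n_at_risk
        out.append(s)
    return np.asarray(out)


def track_from_events(arrival_h=0.0, disappearance=None, death=None,
                      extravasation=None, growth=None, censored_at_h=None,
                      outcome="retained", animal="a0"):
    obs = pd.DataFrame([{"session_h": arrival_h, "x_um": 0.0, "y_um": 0.0,
                         "area_um2": 200.0, "compartment": "intravascular"}])
    return CellTrack(
        track_id=0, arrival_session_h=arrival_h, observations=obs,
        disappearance_interval=disappearance, death_interval=death,
        extravasation_interval=extravasation, growth_interval=growth,
        censored_at_h=censored_at_h, outcome=outcome, animal_id=animal,
    )


class TestKMRetention:
    grid = np.arange(0.0, 72.0, 8.0)

    def test_no_events_survival_one(self):
        tracks = [track_from_events() for _ in range(10)]
        km = km_retention({"g": tracks})
        assert (km["curves"]["g"]["survival"] == 1.0).all()

    def test_hand_fixture(self):
        # events at 16 h and 24 h, one censored at 32 h, two complete:
        # S = 1, 1, 0.8, 0.6, 0.6, ...
        tracks = [
            track_from_events(disappearance=1, outcome="disappeared"),
            track_from_events(disappearance=2, outcome="disappeared"),
            track_from_events(censored_at_h=32.0, outcome="censored"),
            track_from_events(),
            track_from_events(),
        ]
        km = km_retention({"g": tracks})
        surv = km["curves"]["g"]["survival"].to_numpy()
        assert surv[:5] == pytest.approx([1.0, 1.0, 0.8, 0.6, 0.6])

    def test_enumerated_small_fixtures_match_oracle(self):
        # every event/censor pattern over 4 cells and 3 intervals
        grid = np.array([0.0, 8.0, 16.0, 24.0])
        patterns = itertools.product(
            [(None, None), (1, None), (2, None), (None, 16.0), (None, 24.0)],
            repeat=4,
        )
        for pattern in itertools.islice(patterns, 0, None, 7):
            tracks, durations, events = [], [], []
            for dis, cens in pattern:
                tracks.append(track_from_events(
                    disappearance=dis, censored_at_h=cens,
                    outcome="disappeared" if dis is not None else "censored"))
                if dis is not None:
                    durations.append((dis + 1) * 8.0)
                    events.append(1)
                else:
                    durations.append(cens if cens is not None else 24.0)
                    events.append(0)
            km = km_retention({"g": tracks}, horizon_h=24.0)
            expected = hand_product_limit(durations, events, grid)
            got = km["curves"]["g"]["survival"].to_numpy()
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_constant_hazard_closed_form(self):
        # h = 0.2 per interval: S(64) = 0.8^8; estimate within 3 SE
        rng = np.random.default_rng(0)
        n = 1500
        tracks = []
        for _ in range(n):
            k = rng.geometric(0.2) - 1
            if k < 8:
                tracks.append(track_from_events(disappearance=k,
                                                outcome="disappeared"))
            else:
                tracks.append(track_from_events())
        km = km_retention({"g": tracks})
        s64 = km["curves"]["g"]["survival"].iloc[-1]
        p = 0.8**8
        assert abs(s64 - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_logrank_two_groups(self):
        a = [track_from_events(disappearance=0, outcome="disappeared")
             for _ in range(30)] + [track_from_events() for _ in range(10)]
        b = [track_from_events() for _ in range(40)]
        km = km_retention({"a": a, "b": b})
        assert km["logrank"]["p_value"] < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_retention({"g": []})

    def test_censoring_does_not_change_earlier_curve(self):
        base = [track_from_events(disappearance=1, outcome="disappeared"),
                track_from_events(), track_from_events()]
        withc = base + [track_from_events(censored_at_h=48.0, outcome="censored")]
        km_a = km_retention({"g": base})["curves"]["g"]["survival"]
        km_b = km_retention({"g": withc})["curves"]["g"]["survival"]
        # before the censoring time the estimates use the same event times
        assert km_a.iloc[2] != 1.0
        assert km_b.iloc[1] == km_a.iloc[1] == 1.0


class TestExtravasationStats:
    def test_all_first_interval(self):
        tracks = [track_from_events(extravasation=0,
                                    outcome="extrav_survived_single")
                  for _ in range(6)]
        ex = extravasation_stats(tracks)
        assert ex["mean_extravasation_time_h"] == 4.0
        assert ex["sem_extravasation_time_h"] == 0.0
        assert ex["pct_extravasated"] == 100.0

    def test_hand_arithmetic(self):
        # counts {2,1,1} at intervals 0,1,2: mean (2*4 + 12 + 20)/4 = 10 h
        tracks = (
            [track_from_events(extravasation=0, outcome="extrav_survived_single")] * 2
            + [track_from_events(extravasation=1, outcome="extrav_survived_single")]
            + [track_from_events(extravasation=2, outcome="extrav_survived_single")]
        )
        ex = extravasation_stats(tracks)
        assert ex["mean_extravasation_time_h"] == pytest.approx(10.0)
        assert ex["histogram"]["n_cells"].tolist()[:3] == [2, 1, 1]

    def test_percentage_includes_non_extravasated(self):
        tracks = ([track_from_events(extravasation=0,
                                     outcome="extrav_survived_single")] * 3
                  + [track_from_events()] * 7)
        assert extravasation_stats(tracks)["pct_extravasated"] == 30.0


class TestSurvivalOutcomes:
    def test_all_survive(self):
        tracks = [track_from_events(extravasation=0,
                                    outcome="extrav_survived_single")] * 5
        out = survival_outcomes(tracks)
        assert out["survived_single"] == 1.0

    def test_hand_fractions(self):
        tracks = (
            [track_from_events(extravasation=0, death=2,
                               outcome="extrav_died")] * 7
            + [track_from_events(extravasation=0,
                                 outcome="extrav_survived_single")] * 2
            + [track_from_events(extravasation=0, growth=1,
                                 outcome="extrav_grew")]
        )
        out = survival_outcomes(tracks)
        assert (out["died"], out["survived_single"], out["grew"]) == (0.7, 0.2, 0.1)

    def test_no_extravasated_warns(self):
        with pytest.warns(UserWarning):
            out = survival_outcomes([track_from_events()])
        assert np.isnan(out["died"])


class TestMotility:
    def test_stationary_cells_infinite_exit(self):
        df = simulate_timelapse(5, 0.0, 0.5, 8.0, seed=0)
        res = motility_analysis(df, center_to_boundary_um=256.0)
        assert np.isinf(res["projected_min_exit_time_h"])

    def test_projection_is_division(self):
        # ballistic cell at 2 um/h, boundary 256 um -> 128 h
        df = simulate_timelapse(3, 2.0, 0.5, 8.0, seed=1, mode="ballistic")
        res = motility_analysis(df, center_to_boundary_um=256.0)
        assert res["projected_min_exit_time_h"] == pytest.approx(128.0)

    def test_fastest_cell_sets_projection(self):
        # max mean speed 256/69 um/h -> projected exit exactly 69 h
        v = 256.0 / 69.0
        df = simulate_timelapse(1, v, 0.5, 10.0, seed=2, mode="ballistic")
        slow = simulate_timelapse(1, v / 4, 0.5, 10.0, seed=3, mode="ballistic")
        slow["cell_id"] += 1
        res = motility_analysis(pd.concat([df, slow]), center_to_boundary_um=256.0)
        assert res["projected_min_exit_time_h"] == pytest.approx(69.0)

    def test_single_frame_tracks_excluded(self):
        df = pd.DataFrame([{"cell_id": 0, "frame": 0, "t_h": 0.0,
                            "x_um": 0.0, "y_um": 0.0}])
        with pytest.raises(ValueError):
            motility_analysis(df)


class TestCompareGroups:
    def test_hand_t_statistic(self):
        # {1,2,3} vs {4,5,6}: t = -3.674 (classic pooled-variance arithmetic)
        res = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res["statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert "t-test" in res["test"]

    def test_identical_groups_null(self):
        with pytest.warns(UserWarning):
            res = compare_groups({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res["p_value"] > 0.9

    def test_skewed_data_selects_mann_whitney(self):
        rng = np.random.default_rng(4)
        a = np.exp(rng.normal(0, 2, 30))
        b = np.exp(rng.normal(0.2, 2, 30))
        res = compare_groups({"a": a, "b": b})
        assert "Mann-Whitney" in res["test"]

    def test_three_normal_groups_anova_sidak(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(mu, 1, 12)
                  for k, mu in [("a", 0.0), ("b", 0.1), ("c", 3.0)]}
        res = compare_groups(groups)
        assert "ANOVA" in res["test"]
        pw = res["pairwise"].set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "p_value"] < 0.001
        assert pw.loc[("a", "b"), "p_value"] > 0.05

    def test_three_skewed_groups_kruskal_dunn(self):
        rng = np.random.default_rng(6)
        groups = {k: np.exp(rng.normal(mu, 1.5, 15))
                  for k, mu in [("a", 0.0), ("b", 0.0), ("c", 2.5)]}
        res = compare_groups(groups)
        assert "Kruskal-Wallis" in res["test"]
        pw = res["pairwise"].set_index(["group_a", "group_b"])
        assert pw.loc[("a", "c"), "p_value"] < 0.01

    def test_type_one_error_calibrated(self):
        # permuting labels of one pooled sample: rejections ~ alpha
        rng = np.random.default_rng(7)
        pooled = rng.normal(0, 1, 24)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            perm = rng.permutation(pooled)
            res = compare_groups({"a": perm[:12], "b": perm[12:]})
            rejections += res["p_value"] < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) <= 4 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1, 2, 3]})
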