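"""Generator correctness: fate chain, tissue patterns, rendering, migration."""

import numpy as np
import pandas as pd
import pytest

from lungfate.params import ConfigurationError, FateParams, FieldGeometry, TissueParams
from lungfate.synthetic import (
    markov_endpoints,
    render_field,
    simulate_cohort,
    simulate_timelapse,
    simulate_tissue,
    simulate_tissue_with_true_ratio,
    solve_enrichment_amp,
)
from lungfate.spatial import distance_to_tmem


def brute_force_endpoints(params: FateParams, n: int, rng) -> dict:
    """Direct per-cell enumeration of the fate chain (oracle for the DP)."""
    K = params.n_intervals
    pd_, pe = params.hazard("p_disappear"), params.hazard("p_extravasate")
    pm, pg = params.hazard("p_die"), params.hazard("p_grow")
    states = {"di": 0, "de": 0, "gr": 0, "ev": 0, "iv": 0}
    extrav_times = []
    for _ in range(n):
        state = "iv"
        for k in range(K):
            u, v = rng.random(), rng.random()
            if state == "iv":
                if u < pd_[k]:
                    state = "di"
                    break
                if u < pd_[k] + pe[k]:
                    state = "ev"
                    extrav_times.append((k + 0.5) * params.interval_h)
            elif state == "ev":
                if v < pm[k]:
                    state = "de"
                    break
                if v < pm[k] + pg[k]:
                    state = "gr"
        states[state] += 1
    return {
        "retention": 1 - (states["di"] + states["de"]) / n,
        "extrav": len(extrav_times) / n,
        "mean_t": float(np.mean(extrav_times)) if extrav_times else np.nan,
    }


class TestMarkovEndpoints:
    def test_matches_brute_force_enumeration(self, rng):
        params = FateParams(p_disappear=0.1, p_extravasate=0.25,
                            p_die=0.15, p_grow=0.05)
        truth = markov_endpoints(params)
        n = 40000
        sim = brute_force_endpoints(params, n, rng)
        assert truth["retention_horizon"] == pytest.approx(
            sim["retention"], abs=4 * np.sqrt(0.25 / n))
        assert truth["extravasation_fraction"] == pytest.approx(
            sim["extrav"], abs=4 * np.sqrt(0.25 / n))
        assert truth["mean_extravasation_time_h"] == pytest.approx(
            sim["mean_t"], abs=0.5)

    def test_geometric_survival_closed_form(self):
        # constant disappearance hazard 0.3, nothing else: survival (0.7)^8
        params = FateParams(p_disappear=0.3, p_extravasate=0.0,
                            p_die=0.0, p_grow=0.0)
        e = markov_endpoints(params)
        assert e["retention_horizon"] == pytest.approx(0.7**8)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ConfigurationError, match="multiple"):
            markov_endpoints(FateParams(horizon_h=60.0))


class TestSimulateCohort:
    def test_zero_hazards_everyone_retained(self, geometry):
        params = FateParams(arrival_rate=5.0, p_disappear=0.0,
                            p_extravasate=0.0, p_die=0.0, p_grow=0.0)
        res = simulate_cohort(params, geometry, seed=0)
        truth = res.truth[~res.truth.pre_existing]
        assert (truth["outcome"] == "retained-intravascular").all()
        # every cell observed intravascular at all 9 sessions of its follow-up
        cells = res.detections[res.detections.kind == "cell"]
        per_cell = cells.groupby("cell_id")
        assert (per_cell.size() == params.n_intervals + 1).all()
        assert (cells["compartment"] == "intravascular").all()

    def test_forced_extravasation_first_interval(self, geometry):
        params = FateParams(arrival_rate=5.0, p_disappear=0.0,
                            p_extravasate=1.0, p_die=0.0, p_grow=0.0)
        res = simulate_cohort(params, geometry, seed=0)
        truth = res.truth[~res.truth.pre_existing]
        assert (truth["extravasation_interval"] == 0).all()

    def test_geometric_disappearance_fraction(self):
        # p_disappear 0.3 constant: fraction never disappearing ~ 0.7^8
        geometry = FieldGeometry(field_size_um=2048.0)
        params = FateParams(arrival_rate=125.0, p_disappear=0.3,
                            p_extravasate=0.0, p_die=0.0, p_grow=0.0,
                            n_arrival_intervals=8)
        res = simulate_cohort(params, geometry, seed=3)
        truth = res.truth[~res.truth.pre_existing]
        n = len(truth)
        assert n >= 900
        frac = (truth["outcome"] == "retained-intravascular").mean()
        p = 0.7**8
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_determinism(self, geometry):
        params = FateParams(arrival_rate=4.0, censor_prob=0.1)
        a = simulate_cohort(params, geometry, seed=11)
        b = simulate_cohort(params, geometry, seed=11)
        pd.testing.assert_frame_equal(a.detections, b.detections)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.censoring, b.censoring)

    def test_truth_detections_conserved(self, geometry):
        params = FateParams(arrival_rate=6.0, p_disappear=0.1,
                            p_extravasate=0.2, p_die=0.1, p_grow=0.05)
        res = simulate_cohort(params, geometry, seed=5)
        cells = res.detections[res.detections.kind == "cell"]
        # every detection belongs to exactly one truth record and vice versa
        assert set(cells["cell_id"]) == set(res.truth["cell_id"])
        assert res.truth["cell_id"].is_unique
        # outcome labels partition the cohort
        counts = res.truth["outcome"].value_counts()
        assert counts.sum() == len(res.truth)

    def test_event_ordering_invariant(self, geometry):
        params = FateParams(arrival_rate=8.0, p_disappear=0.1,
                            p_extravasate=0.3, p_die=0.2, p_grow=0.1)
        truth = simulate_cohort(params, geometry, seed=9).truth
        ext = truth["extravasation_interval"]
        for col in ("death_interval", "growth_interval"):
            both = truth[ext.notna() & truth[col].notna()]
            assert (both[col] >= both["extravasation_interval"]).all()
        # disappearance only without extravasation
        assert truth[truth.disappearance_interval.notna()][
            "extravasation_interval"].isna().all()

    def test_censored_cells_stop_being_observed(self, geometry):
        params = FateParams(arrival_rate=10.0, censor_prob=0.5,
                            p_disappear=0.0, p_extravasate=0.0,
                            p_die=0.0, p_grow=0.0)
        res = simulate_cohort(params, geometry, seed=2)
        assert len(res.censoring) > 0
        cells = res.detections[res.detections.kind == "cell"]
        last = cells.groupby("cell_id")["session_h"].max()
        for row in res.censoring.itertuples():
            assert last[row.cell_id] == pytest.approx(row.censored_at_h)

    def test_binomial_transition_consistency(self):
        # empirical first-interval transition rates within 4 SD of hazards
        geometry = FieldGeometry(field_size_um=2048.0)
        params = FateParams(arrival_rate=150.0, p_disappear=0.15,
                            p_extravasate=0.25, p_die=0.0, p_grow=0.0,
                            n_arrival_intervals=8)
        truth = simulate_cohort(params, geometry, seed=13).truth
        truth = truth[~truth.pre_existing]
        n = len(truth)
        f_dis = (truth["disappearance_interval"] == 0).mean()
        f_ext = (truth["extravasation_interval"] == 0).mean()
        assert abs(f_dis - 0.15) <= 4 * np.sqrt(0.15 * 0.85 / n)
        assert abs(f_ext - 0.25) <= 4 * np.sqrt(0.25 * 0.75 / n)


class TestSimulateTissue:
    def test_flat_enrichment_is_uniform_subsample(self, rng):
        tp = TissueParams(enrichment_amp=1.0, baseline_pos_frac=0.2)
        pattern, truth = simulate_tissue(tp, (1000.0, 1000.0), rng)
        # positivity must not depend on doorway distance
        d = truth["distance_to_tmem_um"]
        near = truth[d < 100]["marker_positive"].mean()
        far = truth[d >= 100]["marker_positive"].mean()
        n_near = (d < 100).sum()
        se = np.sqrt(0.2 * 0.8 * (1 / n_near + 1 / (len(d) - n_near)))
        assert abs(near - far) <= 4 * se

    def test_positive_fraction_at_zero_matches_closed_form(self):
        # E=3, tau=40, baseline 0.05: p(0) = 0.15
        tp = TissueParams(enrichment_amp=3.0, decay_len_um=40.0,
                          baseline_pos_frac=0.05)
        hits, n0 = 0, 0
        for s in range(30):
            _, truth = simulate_tissue(tp, (1200.0, 1200.0), seed=s)
            at_zero = truth[truth["distance_to_tmem_um"] == 0.0]
            hits += at_zero["marker_positive"].sum()
            n0 += len(at_zero)
        frac = hits / n0
        assert abs(frac - 0.15) <= 4 * np.sqrt(0.15 * 0.85 / n0)

    def test_positivity_curve_matches_p_of_d(self):
        tp = TissueParams(enrichment_amp=4.0, baseline_pos_frac=0.1)
        obs, exp, ns = [], [], []
        frames = [simulate_tissue(tp, (1500.0, 1500.0), seed=s)[1]
                  for s in range(20)]
        truth = pd.concat(frames, ignore_index=True)
        for lo, hi in [(0, 1), (20, 60), (60, 120), (120, 250), (250, 600)]:
            sel = truth[(truth.distance_to_tmem_um >= lo)
                        & (truth.distance_to_tmem_um < hi)]
            if len(sel) < 50:
                continue
            p_bin = sel["p_positive"].mean()
            f_bin = sel["marker_positive"].mean()
            assert abs(f_bin - p_bin) <= 4 * np.sqrt(p_bin * (1 - p_bin) / len(sel))

    def test_overflowing_probability_rejected(self):
        tp = TissueParams(enrichment_amp=20.0, baseline_pos_frac=0.2)
        with pytest.raises(ConfigurationError):
            simulate_tissue(tp, (500.0, 500.0), seed=0)

    def test_solved_amp_hits_target_ratio(self, rng):
        tp = TissueParams(baseline_pos_frac=0.05, tmem_count=6)
        pattern, truth, e = simulate_tissue_with_true_ratio(
            2.2, tp, (1000.0, 1000.0), rng)
        d = truth["distance_to_tmem_um"].to_numpy()
        p = truth["p_positive"].to_numpy()
        near = p[(d >= 0) & (d < 80)].mean()
        far = p[(d >= 160) & (d < 200)].mean()
        assert near / far == pytest.approx(2.2, rel=1e-9)
        assert e > 1

    def test_unreachable_ratio_raises(self):
        tp = TissueParams(decay_len_um=5.0)  # enrichment decays immediately
        d = np.linspace(0, 400, 500)
        with pytest.raises(ConfigurationError):
            solve_enrichment_amp(d, 5.0, tp)


class TestRenderField:
    def test_no_detections_no_noise_is_blank(self, vessels, geometry):
        geom = FieldGeometry(field_size_um=256.0, noise_sd=0.0)
        img = render_field(pd.DataFrame(columns=["x_um", "y_um", "area_um2", "kind"]),
                          vessels, geom, seed=0)
        assert np.all(img.channel("tumor") == 0)

    def test_single_cell_peak_at_position(self, vessels):
        geom = FieldGeometry(field_size_um=256.0, noise_sd=0.0)
        det = pd.DataFrame([{"x_um": 100.0, "y_um": 100.0,
                             "area_um2": 200.0, "kind": "cell"}])
        img = render_field(det, vessels, geom, seed=0)
        peak = np.unravel_index(np.argmax(img.channel("tumor")),
                                img.channel("tumor").shape)
        assert peak == (100, 100)

    def test_negative_control_is_noise_only(self, vessels, geometry):
        det = pd.DataFrame([{"x_um": 50.0, "y_um": 50.0,
                             "area_um2": 200.0, "kind": "cell"}])
        img = render_field(det, vessels, geometry, seed=4, negative_control=True)
        tumor = img.channel("tumor")
        assert abs(tumor.mean()) < 1.0
        assert tumor.std() == pytest.approx(geometry.noise_sd, rel=0.05)

    def test_out_of_bounds_detection_rejected(self, vessels, geometry):
        det = pd.DataFrame([{"x_um": 999.0, "y_um": 10.0,
                             "area_um2": 200.0, "kind": "cell"}])
        with pytest.raises(ValueError, match="outside field"):
            render_field(det, vessels, geometry, seed=0)


class TestSimulateTimelapse:
    def test_zero_speed_is_static(self):
        df = simulate_timelapse(5, 0.0, 0.5, 8.0, seed=0)
        for _, g in df.groupby("cell_id"):
            assert g["x_um"].nunique() == 1
            assert g["y_um"].nunique() == 1

    def test_ballistic_net_displacement(self):
        v, T = 3.0, 8.0
        df = simulate_timelapse(4, v, 0.5, T, seed=1, mode="ballistic")
        for _, g in df.sort_values("frame").groupby("cell_id"):
            dx = g["x_um"].iloc[-1] - g["x_um"].iloc[0]
            dy = g["y_um"].iloc[-1] - g["y_um"].iloc[0]
            assert np.hypot(dx, dy) == pytest.approx(v * T, rel=1e-9)

    def test_random_walk_msd_linear_in_time(self):
        # MSD(t) = step^2 * n_steps for an isotropic walk
        dt, v = 0.5, 4.0
        df = simulate_timelapse(500, v, dt, 20.0, seed=2)
        start = df[df.frame == 0].set_index("cell_id")
        step2 = (v * dt) ** 2
        for frame in (10, 20, 40):
            cur = df[df.frame == frame].set_index("cell_id")
            sq = ((cur.x_um - start.x_um) ** 2 + (cur.y_um - start.y_um) ** 2)
            expected = step2 * frame
            assert sq.mean() == pytest.approx(expected, rel=0.2)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_timelapse(3, -1.0, 0.5, 8.0, seed=0)
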