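"""The normalized GFP:RFP metric, fate threshold, transitions, contacts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from midgut4d.notch import (
    ContactThresholds,
    NotchConfig,
    RatioSeries,
    classify_contact,
    detect_transition,
    estimate_threshold,
    flag_bleedover,
    internuclear_distance,
    normalize_ratios,
    sibling_contact_timeline,
    summarize_contact_states,
)


def make_tracks(rows):
    df = pd.DataFrame(
        rows, columns=["movie_id", "cell_id", "frame", "gfp_raw", "rfp_raw"]
    )
    df["t_min"] = df["frame"] * 7.5
    df["label"] = "stem"
    return df


class TestNormalization:
    def test_per_movie_maximum(self):
        df = make_tracks(
            [("m1", 0, 0, 10.0, 100.0), ("m1", 1, 0, 20.0, 50.0)]
        )
        out = normalize_ratios(df)
        cell0 = out[out["cell_id"] == 0].iloc[0]
        # gfp 10/20 = 0.5; rfp 100/100 = 1.0 -> ratio 0.5
        assert cell0["ratio"] == pytest.approx(0.5)

    def test_gain_invariance(self):
        df = make_tracks(
            [("m1", 0, f, 5.0 + f, 50.0 + f) for f in range(5)]
            + [("m1", 1, f, 9.0, 80.0) for f in range(5)]
        )
        scaled = df.copy()
        scaled[["gfp_raw", "rfp_raw"]] *= 3.0
        r1 = normalize_ratios(df)["ratio"].to_numpy()
        r2 = normalize_ratios(scaled)["ratio"].to_numpy()
        assert np.array_equal(r1, r2)

    def test_zero_rfp_flagged_not_infinite(self):
        df = make_tracks([("m1", 0, 0, 10.0, 0.0), ("m1", 1, 0, 20.0, 50.0)])
        out = normalize_ratios(df)
        bad = out[out["cell_id"] == 0].iloc[0]
        assert not bad["valid"] and np.isnan(bad["ratio"])

    def test_missing_column(self):
        with pytest.raises(ValueError, match="rfp_raw"):
            normalize_ratios(pd.DataFrame({"movie_id": [], "cell_id": [],
                                           "frame": [], "gfp_raw": []}))


class TestThresholdEstimation:
    def test_two_gaussian_mixture(self, rng):
        values = np.concatenate(
            [rng.normal(0.1, 0.02, 5000), rng.normal(0.9, 0.02, 5000)]
        )
        thr, modes = estimate_threshold(values)
        assert 0.45 <= thr <= 0.55
        assert modes[0] == pytest.approx(0.1, abs=0.02)
        assert modes[1] == pytest.approx(0.9, abs=0.02)

    def test_asymmetric_mixture_like_pooled_progenitors(self, rng):
        values = np.concatenate(
            [
                np.abs(rng.normal(0.015, 0.01, 12000)),
                rng.normal(0.528, 0.12, 6000),
            ]
        )
        thr, modes = estimate_threshold(values)
        assert modes[0] < thr < modes[1]

    def test_unimodal_rejected(self, rng):
        with pytest.raises(ValueError, match="unimodal"):
            estimate_threshold(rng.normal(0.5, 0.05, 2000))

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            estimate_threshold(np.linspace(0, 1, 50))


def make_series(t_min, ratio, cell_id=0):
    t = np.asarray(t_min, dtype=float)
    r = np.asarray(ratio, dtype=float)
    return RatioSeries(cell_id, "m1", t, r, np.ones(len(t), dtype=bool))


class TestTransitions:
    def test_worked_transition_duration(self):
        # baseline 0.049 flat to t=3.5 h, reaching the 0.17 threshold at
        # t=10.4 h, climbing to 0.364 by 15 h -> 6.9 h transition period
        t = np.arange(0, 901, 6.0)
        r = np.interp(t, [0, 210, 624, 900], [0.049, 0.049, 0.17, 0.364])
        r[t == 624.0] = 0.17
        res = detect_transition(make_series(t, r))
        assert res["status"] == "transition"
        ev = res["event"]
        assert ev.baseline_value == pytest.approx(0.049)
        assert ev.crossing_time_min == pytest.approx(624.0, abs=6.0)
        assert ev.duration_hr == pytest.approx(6.9, abs=0.1)

    def test_constant_low_series_is_no_event(self):
        t = np.arange(0, 300, 7.5)
        res = detect_transition(make_series(t, np.full(len(t), 0.05)))
        assert res["status"] == "no_transition"

    def test_entirely_above_is_already_enteroblast(self):
        t = np.arange(0, 300, 7.5)
        res = detect_transition(make_series(t, np.full(len(t), 0.5)))
        assert res["status"] == "already_enteroblast"

    def test_single_frame_spike_not_scored(self):
        t = np.arange(0, 300, 7.5)
        r = np.full(len(t), 0.05)
        r[20] = 0.8
        res = detect_transition(make_series(t, r))
        assert res["status"] == "no_transition"

    def test_reverse_crossing_reported(self):
        t = np.arange(0, 300, 7.5)
        r = np.where(t < 150, 0.4, 0.05)
        res = detect_transition(make_series(t, r))
        assert res["status"] == "no_transition"
        assert len(res["reversions"]) == 1


class TestContactClassification:
    @pytest.mark.parametrize(
        "d,state",
        [
            (5.9, "contact"),
            (6.0, "indeterminate"),
            (10.0, "indeterminate"),
            (15.5, "indeterminate"),
            (15.6, "separated"),
            (20.0, "separated"),
            (0.0, "contact"),
        ],
    )
    def test_boundaries(self, d, state):
        assert classify_contact(d) == state

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    def test_total_exhaustive_partition(self, d):
        assert classify_contact(d) in {"contact", "indeterminate", "separated"}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_contact(-1.0)

    def test_pythagorean_distance(self):
        assert internuclear_distance((0, 0, 0), (3, 4, 0)) == 5.0
        assert internuclear_distance((1, 2, 3), (1, 2, 3)) == 0.0

    def test_distance_matches_norm_oracle(self, rng):
        for _ in range(30):
            a, b = rng.normal(size=(2, 3)) * 20
            assert internuclear_distance(a, b) == pytest.approx(
                np.sqrt(np.sum((a - b) ** 2))
            )


def pair_tracks(distances, interval=7.5):
    frames = np.arange(len(distances))
    base = {"frame": frames, "t_min": frames * interval}
    t1 = pd.DataFrame({**base, "x_um": 0.0, "y_um": 0.0, "z_um": 0.0})
    t2 = pd.DataFrame(
        {**base, "x_um": np.asarray(distances, dtype=float), "y_um": 0.0, "z_um": 0.0}
    )
    return t1, t2


class TestSiblingTimeline:
    def test_steady_contact(self):
        t1, t2 = pair_tracks([5.0] * 10)
        tl = sibling_contact_timeline(t1, t2)
        assert all(s == "contact" for s in tl["state"])
        assert tl["alternations"] == 0 and not tl["separated_ge_1h"]

    def test_excursion_and_return(self):
        t1, t2 = pair_tracks([5, 5, 20, 20, 5, 5])
        tl = sibling_contact_timeline(t1, t2)
        assert tl["alternations"] == 2
        assert not tl["permanent_separation"]

    def test_separation_run_of_one_hour(self):
        # 9 consecutive separated frames at 7.5 min span exactly 60 min
        t1, t2 = pair_tracks([5] * 3 + [20] * 9 + [5] * 3)
        tl = sibling_contact_timeline(t1, t2)
        assert tl["longest_separation_min"] == pytest.approx(60.0)
        assert tl["separated_ge_1h"]

    def test_permanent_separation(self):
        t1, t2 = pair_tracks([5] * 3 + [20] * 5)
        assert sibling_contact_timeline(t1, t2)["permanent_separation"]

    def test_disjoint_tracks_rejected(self):
        t1, t2 = pair_tracks([5] * 4)
        t2 = t2.assign(frame=t2["frame"] + 100)
        with pytest.raises(ValueError):
            sibling_contact_timeline(t1, t2)

    def test_indeterminate_frames_do_not_alternate(self):
        states = ["contact", "indeterminate", "separated", "indeterminate", "contact"]
        s = summarize_contact_states(np.arange(5) * 7.5, states)
        assert s["alternations"] == 2


class TestBleedover:
    def make_frame(self, positions, ratios):
        return pd.DataFrame(
            {
                "movie_id": "m1",
                "cell_id": range(len(positions)),
                "frame": 0,
                "t_min": 0.0,
                "x_um": [p[0] for p in positions],
                "y_um": [p[1] for p in positions],
                "z_um": [p[2] for p in positions],
                "ratio": ratios,
                "valid": True,
            }
        )

    def test_isolated_cell_stays_valid(self):
        df = self.make_frame([(0, 0, 0), (50, 0, 0)], [0.05, 0.9])
        out = flag_bleedover(df)
        assert out["valid"].all()

    def test_cell_near_bright_neighbour_flagged(self):
        df = self.make_frame([(0, 0, 0), (3, 0, 0)], [0.05, 0.8])
        out = flag_bleedover(df)
        assert not out.loc[out["cell_id"] == 0, "valid"].iloc[0]
        # the bright cell itself is not flagged by its own signal
        assert out.loc[out["cell_id"] == 1, "valid"].iloc[0]

    def test_dim_neighbour_not_flagged(self):
        df = self.make_frame([(0, 0, 0), (3, 0, 0)], [0.05, 0.06])
        assert flag_bleedover(df)["valid"].all()
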