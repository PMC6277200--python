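"""Generator contracts: quotas, determinism, event round trips, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

from midgut4d.extrusion import detect_pulses, ring_area
from midgut4d.divisions import angle_hv, angle_lc
from midgut4d.segmentation import TypingConfig, segment_nuclei
from midgut4d.synthetic import (
    ExtrusionSpec,
    MitosisSpec,
    SimConfig,
    TransitionSpec,
    generate_extrusion_event,
    generate_mitosis_event,
    generate_tracks,
    render_volume,
)


class TestConfigValidation:
    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_cells=0)

    def test_fraction_sum_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(stem_fraction=0.6, ec_fraction=0.6)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_frames=1)


class TestTracks:
    def test_exact_quota_labels(self):
        cfg = SimConfig(rng_seed=1, n_cells=100, stem_fraction=0.2, n_frames=4)
        tracks, truth = generate_tracks(cfg)
        counts = pd.Series(list(truth.labels.values())).value_counts()
        assert counts["stem"] == 20

    def test_identical_seed_identical_bytes(self, tmp_path):
        cfg = SimConfig(rng_seed=9, n_cells=30, n_frames=8)
        a, _ = generate_tracks(cfg)
        b, _ = generate_tracks(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_one_row_per_cell_per_frame(self, small_config):
        tracks, _ = generate_tracks(small_config)
        assert not tracks.duplicated(["cell_id", "frame"]).any()
        per_cell = tracks.groupby("cell_id")["frame"].agg(["min", "max", "count"])
        assert (per_cell["count"] == per_cell["max"] - per_cell["min"] + 1).all()

    def test_volume_size_rule_by_construction(self, small_config):
        tracks, _ = generate_tracks(small_config)
        ec = tracks[tracks["label"] == "enterocyte"]["volume_um3"]
        others = tracks[tracks["label"] != "enterocyte"]["volume_um3"]
        assert (ec > 113).all()
        assert (others <= 113).all()

    def test_nuclei_on_tube_surface(self, small_config):
        tracks, _ = generate_tracks(small_config)
        cy, cz = small_config.axis_center
        r = np.hypot(tracks["y_um"] - cy, tracks["z_um"] - cz)
        assert np.allclose(r, small_config.tube_radius, atol=1e-6)

    def test_pooled_ratio_density_is_bimodal(self):
        cfg = SimConfig(rng_seed=21, n_cells=251, n_frames=116)
        tracks, _ = generate_tracks(cfg)
        from midgut4d.notch import normalize_ratios

        ratios = normalize_ratios(tracks)
        values = ratios.loc[ratios["valid"], "ratio"].to_numpy()
        grid = np.linspace(0, 1.0, 1001)
        density = gaussian_kde(values, bw_method="silverman")(grid)
        lo, hi = cfg.ratio_modes
        i_lo, i_hi = np.searchsorted(grid, [lo, hi])
        between = density[i_lo : i_hi + 1]
        # interior minimum strictly between the modes
        assert between.min() < density[i_lo] and between.min() < density[i_hi]

    def test_overlapping_events_rejected(self):
        sched = tuple((10.0, 20.0) for _ in range(5))
        with pytest.raises(ValueError, match="overlap"):
            generate_tracks(
                SimConfig(
                    rng_seed=1,
                    n_cells=40,
                    n_frames=30,
                    mitoses=(
                        MitosisSpec(0.0, sched, cell_index=0),
                        MitosisSpec(7.5, sched, cell_index=0),
                    ),
                )
            )


class TestExtrusionEvents:
    def test_pulse_schedule_has_requested_pulses(self, small_config):
        cfg = SimConfig(rng_seed=2, frame_interval=5.0, n_frames=200)
        _, _, _, truth = generate_extrusion_event(cfg, ExtrusionSpec(0, 360, 6))
        kinds = truth["segment_kinds"]
        assert kinds.count("constriction") == 6
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_final_area_below_5pct(self):
        cfg = SimConfig(rng_seed=2, frame_interval=5.0, n_frames=200)
        ring, _, _, _ = generate_extrusion_event(cfg, ExtrusionSpec(0, 360, 6))
        a0 = ring_area(ring["points"][0])
        a1 = ring_area(ring["points"][-1])
        assert a1 < 0.05 * a0

    def test_zero_noise_round_trip_recovers_pulses(self):
        cfg = SimConfig(rng_seed=2, frame_interval=5.0, n_frames=200)
        ring, _, _, truth = generate_extrusion_event(cfg, ExtrusionSpec(0, 360, 6))
        areas = [ring_area(ring["points"][i]) for i in range(len(ring["frames"]))]
        dec = detect_pulses(ring["t_min"], areas)
        assert dec.n_constrictions == truth["n_pulses"]
        # constriction rates faster than relaxation, driving net closure
        assert abs(dec.mean_constriction_rate) > abs(dec.mean_relaxation_rate)

    def test_too_short_closure_rejected(self):
        cfg = SimConfig(rng_seed=2, frame_interval=7.5, n_frames=40)
        with pytest.raises(ValueError):
            generate_extrusion_event(cfg, ExtrusionSpec(0, 7.5, 1))


class TestMitosisEvents:
    def test_all_zero_schedule(self, small_config):
        spec = MitosisSpec(0.0, ((0.0, 0.0),) * 4)
        rec, _, _ = generate_mitosis_event(small_config, spec)
        for t in rec.poles:
            assert angle_hv(rec.poles[t], rec.planes[t]) == pytest.approx(0.0, abs=1e-6)

    def test_scheduled_angles_recovered(self, small_config):
        sched = ((24.0, 5.0), (60.0, 30.0), (62.0, 80.0), (2.0, 45.0))
        rec, _, _ = generate_mitosis_event(small_config, MitosisSpec(0.0, sched))
        times = sorted(rec.poles)
        for (hv, lc), t in zip(sched, times):
            assert angle_hv(rec.poles[t], rec.planes[t]) == pytest.approx(hv, abs=1e-6)
            measured_lc = angle_lc(
                rec.poles[t][0], rec.poles[t][1], rec.long_axis, rec.planes[t]
            )
            assert measured_lc == pytest.approx(lc, abs=1e-6)

    def test_45min_at_7p5_gives_7_mitotic_frames(self, small_config):
        sched = ((10.0, 10.0),) * 7  # endpoints inclusive
        rec, _, _ = generate_mitosis_event(small_config, MitosisSpec(0.0, sched))
        assert rec.t_decondense - rec.t_condense == pytest.approx(45.0)
        assert len(rec.poles) == 7

    def test_angle_out_of_range_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_mitosis_event(
                small_config, MitosisSpec(0.0, ((100.0, 0.0), (0.0, 0.0)))
            )


class TestRendering:
    def test_single_nucleus_segmentation_round_trip(self):
        cfg = SimConfig(rng_seed=3, n_cells=1, n_frames=2)
        frame = pd.DataFrame(
            {
                "cell_id": [0],
                "x_um": [40.0],
                "y_um": [45.0],
                "z_um": [45.0],
                "volume_um3": [180.0],
                "label": ["enterocyte"],
            }
        )
        stack = render_volume(frame, cfg, noise_sd=0.0)
        typing = TypingConfig(
            threshold_method="fixed", fixed_thresholds={"rfp": 100.0},
            min_component_volume=20.0,
        )
        table, _ = segment_nuclei(stack[2], cfg.voxel_size, typing, "rfp")
        assert len(table) == 1
        got = table.iloc[0]
        assert abs(got["x_um"] - 40.0) <= 1.0
        assert abs(got["y_um"] - 45.0) <= 1.0
        assert abs(got["z_um"] - 45.0) <= 1.0

    def test_empty_table_blank_stack(self):
        cfg = SimConfig(rng_seed=3, n_cells=1, n_frames=2)
        stack = render_volume(
            pd.DataFrame(columns=["cell_id", "x_um", "y_um", "z_um", "volume_um3", "label"]),
            cfg,
            noise_sd=0.0,
        )
        assert stack.sum() == 0.0

    def test_two_distant_nuclei_two_components(self):
        cfg = SimConfig(rng_seed=3, n_cells=2, n_frames=2)
        frame = pd.DataFrame(
            {
                "cell_id": [0, 1],
                "x_um": [30.0, 60.0],
                "y_um": [45.0, 45.0],
                "z_um": [45.0, 45.0],
                "volume_um3": [180.0, 180.0],
                "label": ["enterocyte", "enterocyte"],
            }
        )
        stack = render_volume(frame, cfg, noise_sd=0.0)
        typing = TypingConfig(
            threshold_method="fixed", fixed_thresholds={"rfp": 100.0},
            min_component_volume=20.0,
        )
        table, _ = segment_nuclei(stack[2], cfg.voxel_size, typing, "rfp")
        assert len(table) == 2

    def test_out_of_field_centroid_rejected(self):
        cfg = SimConfig(rng_seed=3, n_cells=1, n_frames=2)
        frame = pd.DataFrame(
            {
                "cell_id": [7],
                "x_um": [1e4],
                "y_um": [45.0],
                "z_um": [45.0],
                "volume_um3": [180.0],
                "label": ["enterocyte"],
            }
        )
        with pytest.raises(ValueError, match="7"):
            render_volume(frame, cfg)


class TestTransitionRoundTrip:
    def test_zero_noise_crossings_within_one_frame(self):
        from midgut4d.notch import detect_transitions, normalize_ratios, ratio_series

        specs = tuple(
            TransitionSpec(baseline_end_min=120 + 30 * k, crossing_min=420 + 30 * k)
            for k in range(4)
        )
        cfg = SimConfig(
            rng_seed=5,
            n_cells=100,
            n_frames=96,
            intensity_noise_sd=0.0,
            transitions=specs,
        )
        tracks, truth = generate_tracks(cfg)
        events = detect_transitions(ratio_series(normalize_ratios(tracks)))
        by_cell = {e.cell_id: e for e in events}
        assert len(events) == len(specs)
        for t in truth.transitions:
            ev = by_cell[t["cell_id"]]
            assert abs(ev.crossing_time_min - t["crossing_time_min"]) <= cfg.frame_interval
            assert abs(ev.baseline_time_min - t["baseline_time_min"]) <= cfg.frame_interval
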