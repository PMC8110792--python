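"""Generators: determinism, ground-truth consistency, recovery at scale."""

import math

import numpy as np
import pytest

from gconequant.fret_glisa import fret_efficiency
from gconequant.growthcone_morph import classify_collapse_image, make_factin_mask
from gconequant.stripe_guidance import SphereGeometry, segment_neurites
from gconequant.synthetic_data import (
    FretParams,
    GrowthConeParams,
    SceneParams,
    TrackParams,
    generate_stripe_pattern,
    rasterize_traces,
    render_scene,
    simulate_fret_pair,
    simulate_growth_cone,
    simulate_neurite_traces,
    simulate_scene,
    simulate_timelapse_track,
)


# ---------------------------------------------------------------- stripes

class TestStripePattern:
    def test_equal_alternating_lanes_cover_half(self):
        p = generate_stripe_pattern(50.0, (1000, 1000), 1.0, "vertical")
        assert p.cue_fraction() == 0.5
        # 10 cue lanes of 50 px each
        first_row = p.cue_mask[0]
        transitions = np.diff(first_row.astype(int)) != 0
        assert transitions.sum() == 19  # 20 lanes -> 19 boundaries

    def test_single_lane_when_width_spans_image(self):
        p = generate_stripe_pattern(1000.0, (100, 1000), 1.0, "vertical")
        assert p.cue_fraction() == 1.0

    def test_horizontal_is_transpose_of_vertical(self):
        v = generate_stripe_pattern(37.0, (200, 200), 0.8, "vertical")
        h = generate_stripe_pattern(37.0, (200, 200), 0.8, "horizontal")
        assert np.array_equal(h.cue_mask, v.cue_mask.T)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_stripe_pattern(0.0, (10, 10), 1.0)
        with pytest.raises(ValueError):
            generate_stripe_pattern(10.0, (10, 10), -1.0)

    def test_analytic_label_agrees_with_raster(self):
        p = generate_stripe_pattern(50.0, (300, 300), 1.0, "vertical")
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = rng.uniform(0, 299)
            y = rng.uniform(0, 299)
            col = int(x)
            row = int(y)
            assert p.is_cue((col + 0.5) * p.scale, (row + 0.5) * p.scale) \
                == p.cue_mask[row, col]


# ---------------------------------------------------------------- traces

class TestNeuriteTraces:
    def test_same_seed_gives_identical_vertices(self):
        b1 = simulate_scene(SceneParams(n_neurites=20, seed=7))
        b2 = simulate_scene(SceneParams(n_neurites=20, seed=7))
        for t1, t2 in zip(b1.traces, b2.traces):
            assert np.array_equal(t1.vertices, t2.vertices)

    def test_beta_zero_is_independent_of_stripe_map(self):
        params = SceneParams(n_neurites=15, avoidance_beta=0.0, seed=3)
        wide = generate_stripe_pattern(50.0, (1200, 1200), 1.0)
        narrow = generate_stripe_pattern(17.0, (1200, 1200), 1.0)
        sph = SphereGeometry((600.0, 600.0), params.sphere_radius)
        t_wide = simulate_neurite_traces(params, wide, sph)
        t_narrow = simulate_neurite_traces(params, narrow, sph)
        for a, b in zip(t_wide, t_narrow):
            assert np.array_equal(a.vertices, b.vertices)

    def test_zero_neurites_yields_empty_list(self):
        b = simulate_scene(SceneParams(n_neurites=0))
        assert b.traces == []

    def test_high_beta_blocks_cue_entry_after_first_boundary(self):
        """With near-total avoidance, no vertex should sit on a cue lane
        once its trace has crossed a lane boundary."""
        params = SceneParams(n_neurites=100, avoidance_beta=20.0, seed=11)
        b = simulate_scene(params)
        n_cue_after_crossing = 0
        n_after_crossing = 0
        for tr in b.traces:
            labels = [b.stripes.is_cue(x, y) for x, y in tr.vertices]
            crossed = False
            for i in range(1, len(labels)):
                if labels[i] != labels[i - 1]:
                    crossed = True
                if crossed:
                    n_after_crossing += 1
                    n_cue_after_crossing += labels[i]
        assert n_after_crossing > 500  # the statistic is well sampled
        assert n_cue_after_crossing / n_after_crossing < 0.01

    def test_first_vertex_on_rim(self):
        b = simulate_scene(SceneParams(n_neurites=10, seed=2))
        for tr in b.traces:
            d = math.hypot(tr.vertices[0, 0] - b.sphere.center[0],
                           tr.vertices[0, 1] - b.sphere.center[1])
            assert d == pytest.approx(b.sphere.radius, abs=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(avoidance_beta=-1.0)
        with pytest.raises(ValueError):
            SceneParams(n_neurites=-1)


# ---------------------------------------------------------------- rendering

class TestRenderScene:
    def test_noiseless_render_thresholds_back_to_traces(self):
        b = simulate_scene(SceneParams(n_neurites=30, seed=5, max_length=200.0,
                                       sphere_radius=100.0))
        r = render_scene(b.traces, b.stripes, b.sphere, psf_sigma=0.5,
                         background=0.0, noise_sd=0.0)
        # thresholding anywhere in (0, peak) recovers a mask covering the raster
        from scipy import ndimage

        for frac in (0.1, 0.5):
            mask = r.factin > frac * r.factin.max()
            if not mask.any():
                continue
            # every raster pixel within 1 px of the mask
            dist = ndimage.distance_transform_edt(~mask)
            assert dist[r.trace_raster].max() <= 1.0

    def test_background_only_segments_to_empty(self):
        stripes = generate_stripe_pattern(50.0, (300, 300), 1.0)
        sph = SphereGeometry((150.0, 150.0), 50.0)
        r = render_scene([], stripes, sph, background=0.2, noise_sd=0.0)
        with pytest.warns(UserWarning):
            mask = segment_neurites(r.factin, 1.0)
        assert not mask.any()

    def test_stripe_channel_preserves_cue_fraction(self):
        b = simulate_scene(SceneParams(n_neurites=5, seed=0))
        r = render_scene(b.traces, b.stripes, b.sphere)
        assert (r.stripe_channel > 0).mean() == b.stripes.cue_fraction()

    def test_out_of_canvas_traces_warn(self):
        from gconequant.stripe_guidance import NeuriteTrace

        stripes = generate_stripe_pattern(10.0, (50, 50), 1.0)
        tr = NeuriteTrace(0, np.array([[10.0, 10.0], [200.0, 10.0]]))
        with pytest.warns(UserWarning):
            rasterize_traces([tr], stripes.shape, stripes.scale)


# ---------------------------------------------------------------- growth cones

class TestGrowthConeGenerator:
    def test_fixed_seed_is_byte_identical(self):
        a = simulate_growth_cone(GrowthConeParams(state="spread", seed=9))
        b = simulate_growth_cone(GrowthConeParams(state="spread", seed=9))
        assert np.array_equal(a.image, b.image)

    def test_collapsed_truth_satisfies_rule(self):
        for seed in range(10):
            gc = simulate_growth_cone(GrowthConeParams(state="collapsed", seed=seed))
            assert gc.truth.collapsed
            assert gc.truth.n_filopodia <= 2
            assert gc.truth.max_filopodium_length_um < 10.0

    def test_collapsed_noiseless_classifies_collapsed(self):
        gc = simulate_growth_cone(GrowthConeParams(state="collapsed",
                                                   noise_sd=0.0, seed=4))
        assert classify_collapse_image(gc.image, gc.scale).collapsed

    def test_spread_cones_classify_not_collapsed(self):
        calls = []
        for seed in range(100):
            gc = simulate_growth_cone(
                GrowthConeParams(state="spread", filopodia_count_mean=8.0, seed=seed)
            )
            calls.append(classify_collapse_image(gc.image, gc.scale).collapsed)
        assert np.mean(calls) <= 0.05  # >= 95 % called spread


# ---------------------------------------------------------------- tracks

class TestTimelapseTracks:
    def test_noiseless_track_steps_one_micron(self):
        tr, truth = simulate_timelapse_track(
            TrackParams(true_rate=12.0, frame_interval=5.0, n_frames=10,
                        position_noise_sd=0.0)
        )
        assert np.allclose(np.diff(tr.positions), 1.0)

    def test_certain_retraction_subtracts_magnitude(self):
        tr, truth = simulate_timelapse_track(
            TrackParams(true_rate=12.0, frame_interval=5.0, n_frames=6,
                        position_noise_sd=0.0, retraction_prob=1.0,
                        retraction_magnitude=50.0)
        )
        assert np.allclose(np.diff(truth.true_positions), 1.0 - 50.0)
        assert len(truth.retraction_frames) == 5

    def test_rate_recovery_long_track(self):
        from gconequant.kinetics import extension_rate

        tr, _ = simulate_timelapse_track(
            TrackParams(true_rate=12.0, n_frames=1000, position_noise_sd=0.5,
                        seed=21)
        )
        est = extension_rate(tr)
        # only the endpoints matter below the cap: SE = 60*sqrt(2)*sd/T
        se = 60.0 * math.sqrt(2) * 0.5 / (tr.t_min[-1] - tr.t_min[0])
        assert abs(est.rate_um_per_hr - 12.0) <= 3 * se


# ---------------------------------------------------------------- FRET

class TestFretPairs:
    def test_zero_efficiency_estimates_near_zero(self):
        ests = []
        for seed in range(50):
            pair, _ = simulate_fret_pair(FretParams(true_efficiency=0.0, seed=seed))
            ests.append(fret_efficiency(pair).efficiency)
        assert abs(np.mean(ests)) <= 0.005

    def test_noiseless_full_bleach_is_exact(self):
        pair, _ = simulate_fret_pair(
            FretParams(true_efficiency=0.2, bleach_fraction=1.0, noise_model="none")
        )
        res = fret_efficiency(pair)
        assert res.valid
        assert res.efficiency == pytest.approx(0.2, abs=1e-12)
        assert res.acceptor_bleach_fraction == pytest.approx(1.0, abs=1e-12)

    def test_mean_recovery_under_poisson_noise(self):
        ests = []
        for seed in range(100):
            pair, _ = simulate_fret_pair(
                FretParams(true_efficiency=0.2, donor_base=1e4, seed=seed)
            )
            ests.append(fret_efficiency(pair).efficiency)
        assert abs(np.mean(ests) - 0.2) <= 0.01

    def test_estimator_bias_shrinks_with_photon_budget(self):
        def mean_abs_bias(budget):
            ests = []
            for seed in range(40):
                pair, _ = simulate_fret_pair(
                    FretParams(true_efficiency=0.25, donor_base=budget, seed=seed)
                )
                ests.append(fret_efficiency(pair).efficiency)
            return abs(np.mean(ests) - 0.25)

        assert mean_abs_bias(1e5) <= mean_abs_bias(1e3) + 1e-3

    def test_partial_bleach_flagged_invalid(self):
        pair, _ = simulate_fret_pair(
            FretParams(true_efficiency=0.2, bleach_fraction=0.5, noise_model="none")
        )
        res = fret_efficiency(pair, min_bleach_fraction=0.7)
        assert not res.valid

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FretParams(true_efficiency=1.0)
        with pytest.raises(ValueError):
            FretParams(bleach_fraction=0.0)
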