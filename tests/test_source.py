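"""Source analysis: spherical forward model sanity and symmetry, the
defining zero-localization property of the standardized inverse, ROI
averaging arithmetic, and source-slope behaviour on constructed data."""

import numpy as np
import pytest

from ldaep.preprocess import EvokedSet
from ldaep.source import (
    SOURCE_WINDOWS,
    _SPHERE_CENTER,
    build_head_model,
    compute_sloreta_transform,
    compute_source_ldaep,
    default_alpha,
    forward_gain,
    load_head_model,
    roi_mean_current_density,
    save_head_model,
    standardized_power,
)


class TestHeadModel:
    def test_lead_field_well_posed(self, small_head_model):
        m = small_head_model
        norms = np.linalg.norm(m.gain, axis=0)
        assert np.all(np.isfinite(m.gain))
        assert np.all(norms > 0)

    def test_rows_are_average_referenced(self, small_head_model):
        g = small_head_model.gain
        assert np.abs(g.mean(axis=0)).max() < 1e-10 * np.abs(g).max()

    def test_rois_nonempty_disjoint_lateral(self, small_head_model):
        m = small_head_model
        left, right = m.rois["left"], m.rois["right"]
        assert len(left) > 0 and len(right) > 0
        assert np.intersect1d(left, right).size == 0
        assert np.all(m.positions[left][:, 0] < _SPHERE_CENTER[0])
        assert np.all(m.positions[right][:, 0] > _SPHERE_CENTER[0])

    def test_requested_grid_size_honoured(self):
        m = build_head_model(n_sources=254)
        assert m.n_sources == 254

    def test_mirrored_sources_give_mirrored_columns(self):
        """Left/right symmetry of the spherical conductor, checked with an
        explicitly symmetric sensor ring."""
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        names = [f"E{i}" for i in range(12)]
        pos = {
            n: _SPHERE_CENTER + 0.09 * np.array([
                np.cos(a) * np.cos(0.6), np.sin(a) * np.cos(0.6), np.sin(0.6)])
            for n, a in zip(names, ang)
        }
        src = _SPHERE_CENTER + np.array([[-0.05, -0.01, 0.02]])
        mirrored = src * np.array([-1, 1, 1])
        mirrored[:, 0] += 2 * _SPHERE_CENTER[0]
        g = forward_gain(src, [[0, 0, 1]], names, pos)[:, 0]
        gm = forward_gain(mirrored, [[0, 0, 1]], names, pos)[:, 0]
        perm = [
            int(np.argmin(np.abs(
                ((ang - ((np.pi - a) % (2 * np.pi)) + np.pi) % (2 * np.pi)) - np.pi)))
            for a in ang
        ]
        assert np.allclose(g, gm[perm], atol=1e-6 * np.abs(g).max())

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_head_model(n_sources=50, source_radius=0.09)
        with pytest.raises(ValueError):
            build_head_model(n_sources=1)

    def test_serialization_round_trip(self, small_head_model, tmp_path):
        p = tmp_path / "model.npz"
        save_head_model(small_head_model, p)
        back = load_head_model(p)
        assert np.array_equal(back.gain, small_head_model.gain)
        assert back.sensors == small_head_model.sensors
        for k in small_head_model.rois:
            assert np.array_equal(back.rois[k], small_head_model.rois[k])
        assert (tmp_path / "model.npz.yaml").exists()


class TestSloreta:
    def test_zero_input_gives_zero_power(self, small_head_model):
        op = compute_sloreta_transform(small_head_model, alpha=0.0)
        act = standardized_power(op, np.zeros((small_head_model.n_sensors, 3)))
        assert np.nanmax(act.power) == 0.0

    @pytest.mark.parametrize("alpha_mode", ["zero", "default"])
    def test_zero_localization_error_exhaustive(self, small_head_model, alpha_mode):
        """For every grid source, the noiseless forward field must peak at
        exactly that source — the defining property of the resolution-
        standardized minimum norm (brute force over all sources)."""
        m = small_head_model
        alpha = 0.0 if alpha_mode == "zero" else default_alpha(m)
        op = compute_sloreta_transform(m, alpha)
        power = standardized_power(op, m.gain).power  # column j = source j field
        assert np.array_equal(np.nanargmax(power, axis=0), np.arange(m.n_sources))

    def test_quadratic_scaling(self, small_head_model, rng):
        op = compute_sloreta_transform(small_head_model, default_alpha(small_head_model))
        x = rng.normal(size=(small_head_model.n_sensors, 4))
        p1 = standardized_power(op, x).power
        p2 = standardized_power(op, 3.0 * x).power
        assert np.allclose(p2, 9.0 * p1)

    def test_reference_invariance(self, small_head_model, rng):
        op = compute_sloreta_transform(small_head_model, default_alpha(small_head_model))
        x = rng.normal(size=(small_head_model.n_sensors, 4))
        p1 = standardized_power(op, x).power
        p2 = standardized_power(op, x + rng.normal(size=(1, 4))).power
        assert np.allclose(p1, p2)

    def test_free_orientation_localization(self):
        m = build_head_model(n_sources=60, orientation_mode="free")
        op = compute_sloreta_transform(m, alpha=0.0)
        rng = np.random.default_rng(5)
        for j in rng.choice(60, size=10, replace=False):
            ori = rng.normal(size=3)
            x = m.gain[:, 3 * j : 3 * j + 3] @ (ori / np.linalg.norm(ori))
            act = standardized_power(op, x[:, None])
            assert np.nanargmax(act.power[:, 0]) == j

    def test_negative_alpha_rejected(self, small_head_model):
        with pytest.raises(ValueError):
            compute_sloreta_transform(small_head_model, alpha=-1.0)


class TestRoiMean:
    def _activity(self, model, value=3.0):
        from ldaep.source import SourceActivity

        power = np.full((model.n_sources, 11), value)
        return SourceActivity(power, np.linspace(0, 250, 11), 0.0)

    def test_constant_activity_returns_constant(self, small_head_model):
        act = self._activity(small_head_model, 3.0)
        assert roi_mean_current_density(act, small_head_model, "left", (60, 240)) == 3.0

    def test_linearity(self, small_head_model, rng):
        from ldaep.source import SourceActivity

        power = rng.uniform(0, 1, (small_head_model.n_sources, 11))
        act = SourceActivity(power, np.linspace(0, 250, 11), 0.0)
        act2 = SourceActivity(2 * power, act.times_ms, 0.0)
        a = roi_mean_current_density(act, small_head_model, "right", (60, 240))
        b = roi_mean_current_density(act2, small_head_model, "right", (60, 240))
        assert b == pytest.approx(2 * a)

    def test_avg_is_mean_of_hemispheres(self, small_head_model, rng):
        from ldaep.source import SourceActivity

        power = rng.uniform(0, 1, (small_head_model.n_sources, 11))
        act = SourceActivity(power, np.linspace(0, 250, 11), 0.0)
        l = roi_mean_current_density(act, small_head_model, "left", (60, 240))
        r = roi_mean_current_density(act, small_head_model, "right", (60, 240))
        a = roi_mean_current_density(act, small_head_model, "avg", (60, 240))
        assert a == pytest.approx(0.5 * (l + r))

    def test_unknown_roi_and_bad_window_rejected(self, small_head_model):
        act = self._activity(small_head_model)
        with pytest.raises(ValueError):
            roi_mean_current_density(act, small_head_model, "occipital", (60, 240))
        with pytest.raises(ValueError):
            roi_mean_current_density(act, small_head_model, "left", (900, 1000))


class TestSourceLdaep:
    def _evoked_from_sources(self, model, amplitudes_by_intensity, src_cols):
        """Sensor data generated through the model's own lead field: the
        named source columns carry a 60-240 ms bump scaled per intensity."""
        times = np.arange(-100.0, 401.0)
        bump = np.exp(-0.5 * ((times - 150.0) / 40.0) ** 2)
        data = {}
        for inten, amp in amplitudes_by_intensity.items():
            x = np.zeros((model.n_sensors, len(times)))
            for c in src_cols:
                x += np.outer(model.gain[:, c], amp * bump)
            data[inten] = x
        n = {i: 1 for i in data}
        return EvokedSet(data, times, list(model.sensors), n, {i: 0.0 for i in data})

    def test_monotone_source_amplitude_gives_positive_slope(self, small_head_model):
        m = small_head_model
        cols = [m.rois["left"][0], m.rois["right"][0]]
        amps = {i: 1.0 + 0.05 * (i - 55) for i in (55, 65, 75, 85, 95)}
        ev = self._evoked_from_sources(m, amps, cols)
        res = compute_source_ldaep(ev, m)
        for roi in ("left", "right", "avg"):
            assert res.slopes["broad"][roi] > 0

    def test_intensity_independent_amplitude_gives_zero_slope(self, small_head_model):
        m = small_head_model
        cols = [m.rois["left"][0]]
        ev = self._evoked_from_sources(m, {i: 2.0 for i in (55, 65, 75, 85, 95)}, cols)
        res = compute_source_ldaep(ev, m)
        scale = abs(np.mean(res.roi_means["broad"]["avg"]))
        assert abs(res.slopes["broad"]["avg"]) < 1e-9 * max(scale, 1e-30) + 1e-30

    def test_left_lateralized_dependence_detected(self, small_head_model):
        m = small_head_model
        amps = {i: 1.0 + 0.05 * (i - 55) for i in (55, 65, 75, 85, 95)}
        ev = self._evoked_from_sources(m, amps, [m.rois["left"][0]])
        res = compute_source_ldaep(ev, m)
        assert res.slopes["broad"]["left"] > res.slopes["broad"]["right"]

    def test_gain_scaling_cancels_end_to_end(self, small_head_model):
        """Amplifier gain cancels: data generated through a globally scaled
        lead field and inverted with that same lead field give identical
        source slopes."""
        import copy

        m = small_head_model
        amps = {i: 1.0 + 0.05 * (i - 55) for i in (55, 65, 75, 85, 95)}
        cols = [m.rois["left"][0], m.rois["right"][0]]
        res1 = compute_source_ldaep(self._evoked_from_sources(m, amps, cols), m)

        m2 = copy.deepcopy(m)
        m2.gain = 10.0 * m.gain
        res2 = compute_source_ldaep(self._evoked_from_sources(m2, amps, cols), m2)
        for w in SOURCE_WINDOWS:
            for roi in ("left", "right", "avg"):
                assert res2.slopes[w][roi] == pytest.approx(
                    res1.slopes[w][roi], rel=1e-6)

    def test_simulated_subject_has_positive_broad_slope(self, noisy_recording,
                                                        small_head_model):
        from ldaep.preprocess import preprocess_recording

        raw, _ = noisy_recording
        evoked = preprocess_recording(raw)
        res = compute_source_ldaep(evoked, small_head_model)
        assert res.slopes["broad"]["avg"] > 0
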