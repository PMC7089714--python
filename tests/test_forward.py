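import numpy as np
import pytest

from pact_recon.delay import focal_line_delay, point_delay
from pact_recon.forward import (
    Absorber,
    Phantom,
    VesselPhantom,
    fixture_suite,
    load_phantom,
    simulate,
    sphere_signal,
)
from pact_recon.geometry import ArrayGeometry, ScanTrajectory


class TestSphereSignal:
    def test_zero_crossing_at_center_of_n_shape(self):
        assert sphere_signal(8.0, 2.0, 1.0, 2.0, t=4.0) == 0.0

    def test_leading_compression_peak(self):
        # t = (d - a)/v_s with power-of-two-friendly values: exact arithmetic
        d, a, v_s, p0 = 8.0, 2.0, 2.0, 3.0
        t = (d - a) / v_s
        assert sphere_signal(d, a, p0, v_s, t) == p0 * a / (2 * d)

    def test_trailing_rarefaction_peak(self):
        d, a, v_s, p0 = 8.0, 2.0, 2.0, 3.0
        t = (d + a) / v_s
        assert sphere_signal(d, a, p0, v_s, t) == -p0 * a / (2 * d)

    def test_n_shape_integrates_to_zero(self):
        d, a, v_s = 20.0, 1.5, 1.54
        t = np.linspace((d - 2 * a) / v_s, (d + 2 * a) / v_s, 40001)
        p = sphere_signal(d, a, 2.0, v_s, t)
        assert np.trapezoid(p, t) == pytest.approx(0.0, abs=1e-6)

    def test_zero_outside_support(self):
        d, a, v_s = 10.0, 1.0, 1.0
        assert sphere_signal(d, a, 1.0, v_s, t=(d - 2 * a) / v_s) == 0.0
        assert sphere_signal(d, a, 1.0, v_s, t=(d + 2 * a) / v_s) == 0.0

    def test_point_pulse_centered_and_peak_normalized(self):
        d, v_s, sigma = 15.4, 1.54, 0.2
        tc = d / v_s
        t = np.linspace(tc - 2.0, tc + 2.0, 20001)
        p = sphere_signal(d, 0.0, 2.5, v_s, t, pulse_sigma=sigma)
        assert p[np.argmin(np.abs(t - tc))] == pytest.approx(0.0, abs=1e-3)
        assert np.max(np.abs(p)) == pytest.approx(2.5, rel=1e-6)
        # odd about the center: leading lobe positive (compression first)
        assert p[np.argmax(p)] > 0 and t[np.argmax(p)] < tc

    def test_receiver_inside_absorber_rejected(self):
        with pytest.raises(ValueError):
            sphere_signal(1.0, 2.0, 1.0, 1.54, t=0.0)


class TestSimulate:
    geometry = ArrayGeometry(n_elements=6, pitch=1.0, focal_length=0.0)
    trajectory = ScanTrajectory(step_size=1.0, n_positions=4)

    def test_empty_phantom_no_noise_gives_zeros(self):
        data = simulate(
            Phantom(), self.geometry, self.trajectory, duration=10.0
        )
        np.testing.assert_array_equal(data.samples, 0.0)

    def test_point_arrival_at_predicted_delay(self):
        """Per trace, the signal envelope peaks within one sample of the
        delay module's predicted arrival — closing the loop between the
        forward model and the delay model."""
        center = (12.0, 0.5, 1.5)
        data = simulate(
            Phantom(absorbers=(Absorber(center=center),)),
            self.geometry, self.trajectory,
            sampling_rate=20.0, duration=15.0, model="point",
        )
        lat = self.geometry.element_lateral_positions
        for e in range(self.geometry.n_elements):
            for s in range(self.trajectory.n_positions):
                elem = np.array([0.0, lat[e], float(s)])
                tau = point_delay(np.array(center), elem, 1.54)
                trace = data.samples[:, e, s]
                # the DoG zero-crossing sits at tau, its two lobes ±sigma
                k_peak = np.argmax(trace)  # leading compression lobe
                t_peak = k_peak / 20.0
                assert abs((t_peak + 0.25) - tau) <= 2.5 / 20.0

    def test_focal_line_model_shifts_arrivals(self):
        # shallow absorber: the minus branch pulls the arrival earlier
        geometry = ArrayGeometry(n_elements=4, pitch=1.0, focal_length=10.0)
        center = (6.0, 0.5, 1.0)
        kwargs = dict(sampling_rate=20.0, duration=25.0)
        p_point = simulate(
            Phantom(absorbers=(Absorber(center=center),)),
            geometry, self.trajectory, model="point", **kwargs,
        )
        p_focal = simulate(
            Phantom(absorbers=(Absorber(center=center),)),
            geometry, self.trajectory, model="focal_line", **kwargs,
        )
        elem = np.array([0.0, geometry.element_lateral_positions[0], 0.0])
        shift = focal_line_delay(np.array(center), elem, 10.0, 1.54) - point_delay(
            np.array(center), elem, 1.54
        )
        k_point = np.argmax(p_point.samples[:, 0, 0])
        k_focal = np.argmax(p_focal.samples[:, 0, 0])
        assert (k_focal - k_point) / 20.0 == pytest.approx(shift, abs=0.1)

    def test_two_absorbers_superpose_exactly(self):
        a1 = Absorber(center=(8.0, 0.0, 1.0), radius=0.5)
        a2 = Absorber(center=(12.0, 1.0, 2.0))
        kwargs = dict(sampling_rate=10.0, duration=15.0)
        both = simulate(
            Phantom(absorbers=(a1, a2)), self.geometry, self.trajectory, **kwargs
        )
        s1 = simulate(Phantom(absorbers=(a1,)), self.geometry, self.trajectory, **kwargs)
        s2 = simulate(Phantom(absorbers=(a2,)), self.geometry, self.trajectory, **kwargs)
        np.testing.assert_array_equal(both.samples, s1.samples + s2.samples)

    def test_amplitude_linearity_exact(self):
        a = Absorber(center=(9.0, 0.0, 1.0), radius=1.0, amplitude=1.0)
        a3 = Absorber(center=(9.0, 0.0, 1.0), radius=1.0, amplitude=3.0)
        kwargs = dict(sampling_rate=10.0, duration=12.0)
        s1 = simulate(Phantom(absorbers=(a,)), self.geometry, self.trajectory, **kwargs)
        s3 = simulate(Phantom(absorbers=(a3,)), self.geometry, self.trajectory, **kwargs)
        np.testing.assert_array_equal(s3.samples, 3.0 * s1.samples)

    def test_seed_determinism_and_divergence(self):
        phantom = lambda seed: Phantom(
            absorbers=(Absorber(center=(10.0, 0.0, 1.0)),), noise_sd=0.1, seed=seed
        )
        kwargs = dict(sampling_rate=10.0, duration=12.0)
        r1 = simulate(phantom(11), self.geometry, self.trajectory, **kwargs)
        r2 = simulate(phantom(11), self.geometry, self.trajectory, **kwargs)
        r3 = simulate(phantom(12), self.geometry, self.trajectory, **kwargs)
        assert r1.samples.tobytes() == r2.samples.tobytes()
        assert r1.samples.tobytes() != r3.samples.tobytes()

    def test_out_of_window_absorber_warns_with_name(self):
        with pytest.warns(UserWarning, match="absorber 0"):
            simulate(
                Phantom(absorbers=(Absorber(center=(30.0, 0.0, 1.0)),)),
                self.geometry, self.trajectory,
                sampling_rate=10.0, duration=5.0,
            )

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate(Phantom(), self.geometry, self.trajectory, duration=-1.0)


class TestVesselPhantom:
    def test_spheres_cover_polyline_continuously(self):
        vp = VesselPhantom(
            control_points=((10.0, -3.0, 0.0), (10.0, 3.0, 0.0)),
            tube_radius=0.5,
            sphere_spacing=0.5,
        )
        absorbers = vp.to_absorbers()
        centers = np.array([a.center for a in absorbers])
        gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        assert np.all(gaps <= vp.tube_radius + 1e-12)  # overlapping spheres
        np.testing.assert_allclose(centers[0], (10.0, -3.0, 0.0))
        np.testing.assert_allclose(centers[-1], (10.0, 3.0, 0.0))

    def test_spacing_larger_than_radius_rejected(self):
        with pytest.raises(ValueError):
            VesselPhantom(((0, 0, 0), (1, 1, 1)), tube_radius=0.3, sphere_spacing=0.5)


class TestFixtureSuite:
    @pytest.mark.parametrize(
        "name", ["point_grid", "three_tubes", "full_array_small"]
    )
    def test_fixtures_are_deterministic(self, name):
        f1 = fixture_suite(name)
        f2 = fixture_suite(name)
        assert f1.geometry == f2.geometry
        assert f1.phantom == f2.phantom
        assert f1.grid.dims == f2.grid.dims

    def test_full_array_small_matches_validation_array(self):
        f = fixture_suite("full_array_small")
        assert f.geometry.n_elements == 128
        assert f.geometry.center_frequency == 2.25
        assert f.trajectory.step_size == 0.1
        assert f.trajectory.n_positions < 400  # scaled down

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError):
            fixture_suite("nope")


class TestPhantomFile:
    def test_load_phantom_yaml(self, tmp_path):
        p = tmp_path / "ph.yaml"
        p.write_text(
            "absorbers:\n"
            "  - {center_mm: [10.0, 0.0, 1.0], radius_mm: 0.5, amplitude: 2.0}\n"
            "  - {center_mm: [12.0, 1.0, 2.0]}\n"
            "noise_sd: 0.05\n"
            "seed: 3\n"
        )
        phantom = load_phantom(p)
        assert len(phantom.absorbers) == 2
        assert phantom.absorbers[0].radius == 0.5
        assert phantom.absorbers[1].amplitude == 1.0
        assert phantom.noise_sd == 0.05
        assert phantom.seed == 3

    def test_unknown_keys_warn(self, tmp_path):
        p = tmp_path / "ph.yaml"
        p.write_text("absorbers: []\nglitter: yes\n")
        with pytest.warns(UserWarning, match="glitter"):
            load_phantom(p)

    def test_malformed_absorber_rejected(self, tmp_path):
        p = tmp_path / "ph.yaml"
        p.write_text("absorbers:\n  - {radius_mm: 1.0}\n")
        with pytest.raises(ValueError):
            load_phantom(p)
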