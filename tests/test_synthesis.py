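"""Frequency grid, band-to-time conversion, and echo assembly."""

import warnings

import numpy as np
import pytest

from leafecho.acoustics import Medium
from leafecho.fixtures import make_leaf_scene
from leafecho.geometry import DiscSet
from leafecho.metric import envelope
from leafecho.synthesis import (FrequencyGrid, band_to_time,
                                leaf_transfer_function, synthesize_echo,
                                _sum_binned, _sum_direct)


class TestFrequencyGrid:
    def test_default_spacing_and_record(self):
        grid = FrequencyGrid()
        assert grid.spacing == pytest.approx(10.0)
        n_full, k0 = grid.full_record_bins(400e3)
        assert (n_full, k0) == (40000, 6000)
        assert grid.frequencies[0] == 60e3
        assert len(grid.frequencies) == 2000

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(200e3, 260e3).full_record_bins(400e3)

    def test_misaligned_grid_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(60.5e3, 80e3, 2000).full_record_bins(400e3)


class TestBandToTime:
    def test_zero_spectrum_gives_zero_waveform(self):
        x = band_to_time(np.zeros(2000, dtype=complex))
        assert x.shape == (40000,)
        assert np.all(x == 0.0)

    def test_parseval_on_windowed_spectrum(self, rng):
        grid = FrequencyGrid()
        spec = rng.standard_normal(2000) + 1j * rng.standard_normal(2000)
        x = band_to_time(spec, grid)
        windowed = spec * np.hanning(2000)
        # real signal from one-sided band: energy = 2/N * sum|X|^2
        expected = 2.0 * np.sum(np.abs(windowed) ** 2) / 40000
        assert np.sum(x ** 2) == pytest.approx(expected, rel=1e-10)

    def test_unit_spectrum_peaks_at_time_zero(self):
        x = band_to_time(np.ones(2000, dtype=complex))
        assert np.argmax(np.abs(x)) == 0

    def test_forward_transform_round_trip(self, rng):
        grid = FrequencyGrid()
        spec = rng.standard_normal(2000) + 1j * rng.standard_normal(2000)
        x = band_to_time(spec, grid)
        back = np.fft.rfft(x)[6000:8000]
        np.testing.assert_allclose(back, spec * np.hanning(2000),
                                   atol=1e-12 * np.abs(spec).max())


class TestLeafTransferFunction:
    def test_phase_slope_encodes_round_trip_delay(self, on_axis_pose,
                                                  medium):
        grid = FrequencyGrid()
        # ranges below the 10 Hz grid's unambiguous delay (0.05 s ~ 8.6 m)
        for r in (1.5, 4.0, 7.0):
            scene = make_leaf_scene([r])
            H = leaf_transfer_function(scene.leaves, on_axis_pose, grid,
                                       medium)
            phase = np.unwrap(np.angle(H))
            slope = np.polyfit(grid.frequencies, phase, 1)[0]
            tau = -slope / (2 * np.pi)
            assert tau == pytest.approx(2 * r / medium.sound_speed,
                                        rel=1e-9)

    def test_amplitude_follows_inverse_square(self, on_axis_pose, medium):
        grid = FrequencyGrid()
        H1 = leaf_transfer_function(make_leaf_scene([2.0]).leaves,
                                    on_axis_pose, grid, medium)
        H2 = leaf_transfer_function(make_leaf_scene([4.0]).leaves,
                                    on_axis_pose, grid, medium)
        assert np.abs(H2).max() == pytest.approx(np.abs(H1).max() / 4.0)

    def test_grazing_incidence_is_silent(self, on_axis_pose, medium):
        scene = make_leaf_scene([2.0], incidence_angles=[90.0])
        H = leaf_transfer_function(scene.leaves, on_axis_pose,
                                   FrequencyGrid(), medium)
        np.testing.assert_allclose(np.abs(H), 0.0, atol=1e-16)

    def test_near_field_warns(self, on_axis_pose, medium):
        disc = DiscSet([[0.5, 0, 0]], [[-1.0, 0, 0]], [0.02])
        with pytest.warns(UserWarning):
            leaf_transfer_function(disc, on_axis_pose, FrequencyGrid(),
                                   medium)


class TestSynthesizeEcho:
    def test_empty_cloud_gives_zero_waveform(self, on_axis_pose):
        echo = synthesize_echo(DiscSet.empty(), on_axis_pose)
        assert np.all(echo.samples == 0.0)

    def test_single_leaf_envelope_peak_at_round_trip_delay(self,
                                                           on_axis_pose):
        scene = make_leaf_scene([1.715])
        echo = synthesize_echo(scene.leaves, scene.pose)
        t_peak = np.argmax(envelope(echo)) / echo.sampling_rate
        assert abs(t_peak - 0.01) <= 1.0 / echo.sampling_rate

    def test_delay_accuracy_over_random_ranges(self, rng):
        """Envelope peak within one sample of 2r/c across 100 ranges."""
        ranges = rng.uniform(1.0, 10.0, 100)
        scene = make_leaf_scene(ranges)
        # synthesise each leaf alone (a combined scene would overlap peaks)
        errors = []
        for r, tau in zip(ranges, scene.expected_delays):
            one = make_leaf_scene([r])
            echo = synthesize_echo(one.leaves, one.pose, method="direct")
            t_peak = np.argmax(envelope(echo)) / echo.sampling_rate
            errors.append(abs(t_peak - tau) * echo.sampling_rate)
        assert max(errors) <= 1.0

    def test_superposition_is_exact(self, random_disc_cloud, on_axis_pose):
        half = len(random_disc_cloud) // 2
        idx = np.arange(len(random_disc_cloud))
        a = random_disc_cloud.select(idx < half)
        b = random_disc_cloud.select(idx >= half)
        ea = synthesize_echo(a, on_axis_pose, method="direct")
        eb = synthesize_echo(b, on_axis_pose, method="direct")
        eab = synthesize_echo(random_disc_cloud, on_axis_pose,
                              method="direct")
        np.testing.assert_allclose(ea.spectrum + eb.spectrum, eab.spectrum,
                                   rtol=0, atol=1e-12 *
                                   np.abs(eab.spectrum).max())
        np.testing.assert_allclose(ea.samples + eb.samples, eab.samples,
                                   rtol=0,
                                   atol=1e-12 * np.abs(eab.samples).max())

    @pytest.mark.parametrize("absorption", [False, True])
    def test_binned_agrees_with_direct(self, random_disc_cloud,
                                       on_axis_pose, absorption):
        med = Medium(absorption_enabled=absorption)
        grid = FrequencyGrid()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direct = _sum_direct(random_disc_cloud, on_axis_pose, grid,
                                 med, "cosine")
            binned = _sum_binned(random_disc_cloud, on_axis_pose, grid,
                                 med, 400e3)
        tol = 1e-6 if not absorption else 1e-3
        assert np.abs(direct - binned).max() <= tol * np.abs(direct).max()

    def test_deterministic_given_inputs(self, random_disc_cloud,
                                        on_axis_pose):
        e1 = synthesize_echo(random_disc_cloud, on_axis_pose)
        e2 = synthesize_echo(random_disc_cloud, on_axis_pose)
        np.testing.assert_array_equal(e1.samples, e2.samples)

    def test_loss_threshold_removes_out_of_budget_leaves(self,
                                                         on_axis_pose):
        # one leaf on axis at 2 m, one 70 deg off axis (beam 60 deg wide:
        # two-way attenuation alone is 6*(140/60)^2 = 32.7 dB; at 85 deg
        # it is 48 dB and spreading pushes it past a 30 dB budget)
        near = make_leaf_scene([2.0]).leaves
        echo_all = synthesize_echo(near, on_axis_pose,
                                   loss_threshold_db=80.0)
        echo_tight = synthesize_echo(near, on_axis_pose,
                                     loss_threshold_db=5.0)
        assert np.abs(echo_all.samples).max() > 0
        assert np.all(echo_tight.samples == 0.0)


class TestLeafSceneFixture:
    def test_two_leaves_resolve_in_time(self):
        scene = make_leaf_scene([2.0, 3.0])
        echo = synthesize_echo(scene.leaves, scene.pose)
        env = envelope(echo)
        t = np.array(scene.expected_delays) * echo.sampling_rate
        # local peaks near both expected delays
        for ti in t:
            lo, hi = int(ti) - 40, int(ti) + 40
            assert env[lo:hi].max() > 0.3 * env.max()

    def test_grazing_leaf_adds_nothing(self, medium):
        base = make_leaf_scene([2.0])
        extra = make_leaf_scene([2.0, 3.0], incidence_angles=[0.0, 90.0])
        e1 = synthesize_echo(base.leaves, base.pose)
        e2 = synthesize_echo(extra.leaves, extra.pose)
        np.testing.assert_allclose(e1.samples, e2.samples,
                                   atol=1e-14 * np.abs(e1.samples).max())
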