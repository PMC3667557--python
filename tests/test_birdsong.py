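"""Birdsong generator, syrinx, song annotation, omission editing, sonogram."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from actinf.birdsong import (
    BirdsongConfig,
    LorenzParams,
    annotate_chirps,
    control_map,
    generate_song,
    lorenz_flow,
    omit_chirps,
    params_from_causes,
    sonogram,
    syrinx,
)


class TestLorenz:
    def test_origin_is_equilibrium(self):
        assert np.allclose(lorenz_flow(np.zeros(3), LorenzParams()), 0.0)

    def test_matches_reference_integrator(self):
        # oracle: scipy's adaptive RK at tight tolerance, same trajectory;
        # the flow itself is checked by integrating it with classical RK4
        # (the trajectory is chaotic, so both integrators must be accurate)
        p = LorenzParams(rate=0.01)
        x0 = np.array([1.0, 1.0, 25.0])
        n_bins, n_sub = 1000, 20
        h = 1.0 / n_sub
        x = x0.copy()
        for _ in range(n_bins * n_sub):
            k1 = lorenz_flow(x, p)
            k2 = lorenz_flow(x + 0.5 * h * k1, p)
            k3 = lorenz_flow(x + 0.5 * h * k2, p)
            k4 = lorenz_flow(x + h * k3, p)
            x = x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        sol = solve_ivp(lambda t, y: lorenz_flow(y, p), (0, n_bins), x0,
                        rtol=1e-11, atol=1e-12)
        ref = sol.y[:, -1]
        assert np.linalg.norm(x - ref) / np.linalg.norm(ref) < 1e-4

    def test_trajectory_stays_bounded(self):
        # the attractor lies well inside a ball of radius ~ 2*rayleigh
        p = LorenzParams(rate=0.02)
        x = np.array([1.0, 1.0, 25.0])
        radius = []
        for _ in range(10_000):
            x = x + lorenz_flow(x, p)
            radius.append(np.linalg.norm(x - [0, 0, p.rayleigh]))
        assert max(radius) < 3 * p.rayleigh

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            LorenzParams(rate=0.0)


class TestControlMap:
    def setup_method(self):
        self.cfg = BirdsongConfig()

    def test_attractor_mean_maps_to_canonical_pair(self):
        ray, pr = params_from_causes(control_map(np.zeros(3), self.cfg), self.cfg)
        assert ray == pytest.approx(self.cfg.rayleigh_center)
        assert pr == pytest.approx(10.0)

    def test_monotone_in_each_input(self):
        ys = np.linspace(-30, 30, 21)
        rays = [params_from_causes(control_map(np.array([y, 0, 0]), self.cfg),
                                   self.cfg)[0] for y in ys]
        prs = [params_from_causes(control_map(np.array([0, y, 0]), self.cfg),
                                  self.cfg)[1] for y in ys]
        assert all(b > a for a, b in zip(rays, rays[1:]))
        assert all(b > a for a, b in zip(prs, prs[1:]))

    def test_outputs_stay_in_admissible_box_over_slow_cycle(self):
        song = generate_song(rng_seed=0)
        for y in song.true_slow:
            ray, pr = params_from_causes(control_map(y, self.cfg), self.cfg)
            assert (self.cfg.rayleigh_center - self.cfg.rayleigh_span
                    <= ray
                    <= self.cfg.rayleigh_center + self.cfg.rayleigh_span)
            assert 10 - self.cfg.prandtl_span <= pr <= 10 + self.cfg.prandtl_span


class TestSyrinx:
    def setup_method(self):
        self.cfg = BirdsongConfig()

    def test_frequency_clamped_to_2_5_khz(self):
        for x3 in np.linspace(-100, 150, 40):
            f, _ = syrinx(np.array([12.0, 0.0, x3]), self.cfg)
            assert 2.0 <= f <= 5.0
        f_low, _ = syrinx(np.array([12.0, 0.0, -1e3]), self.cfg)
        assert f_low == pytest.approx(2.0, abs=1e-6)

    def test_amplitude_rectified(self):
        for x1 in np.linspace(-30, 30, 25):
            _, a = syrinx(np.array([x1, 0.0, 25.0]), self.cfg)
            assert a >= 0.0

    def test_frequency_in_band_whenever_sounding(self):
        song = generate_song(rng_seed=0)
        sounding = song.amplitude > 0.05
        assert np.all((song.frequency[sounding] >= 2.0)
                      & (song.frequency[sounding] <= 5.0))


class TestGenerateSong:
    def test_bit_identical_for_fixed_seed(self):
        a, b = generate_song(rng_seed=3), generate_song(rng_seed=3)
        assert np.array_equal(a.amplitude, b.amplitude)
        assert np.array_equal(a.frequency, b.frequency)
        assert a.chirps == b.chirps

    def test_song_has_enough_chirps_for_omission(self):
        song = generate_song(rng_seed=0)
        assert len(song.chirps) >= 4

    def test_interchirp_interval_about_one_second(self):
        song = generate_song(rng_seed=0)
        onsets = [c[0] for c in song.chirps]
        gaps_s = np.diff(onsets) * song.bin_ms / 1000.0
        assert np.all((gaps_s > 0.4) & (gaps_s < 2.0))
        assert 0.5 < np.mean(gaps_s) < 1.5

    def test_annotations_match_threshold_crossing_oracle(self):
        song = generate_song(rng_seed=2)
        # independent scan for contiguous supra-threshold runs
        thr = 0.2 * song.amplitude.max()
        above = song.amplitude > thr
        runs, start = [], None
        for i, f in enumerate(above):
            if f and start is None:
                start = i
            if not f and start is not None:
                if i - start >= 3:
                    runs.append((start, i))
                start = None
        if start is not None and len(above) - start >= 3:
            runs.append((start, len(above)))
        assert runs == song.chirps


class TestOmitChirps:
    def test_zero_omission_is_identity(self):
        song = generate_song(rng_seed=0)
        same = omit_chirps(song, 0)
        assert same is song

    def test_earlier_bins_bit_identical(self):
        song = generate_song(rng_seed=0)
        edited = omit_chirps(song, 3)
        cut = song.chirps[-3][0]
        assert np.array_equal(edited.amplitude[:cut], song.amplitude[:cut])
        assert np.array_equal(edited.frequency, song.frequency)
        assert np.all(edited.amplitude[cut:] == 0.0)

    def test_silenced_bin_count_matches_counting_oracle(self):
        song = generate_song(rng_seed=0)
        edited = omit_chirps(song, 2)
        cut = song.chirps[-2][0]
        removed = int(np.sum(song.amplitude > 0)) - int(
            np.sum(edited.amplitude > 0)
        )
        assert removed == int(np.sum(song.amplitude[cut:] > 0))

    def test_too_many_chirps_rejected(self):
        song = generate_song(rng_seed=0)
        with pytest.raises(ValueError):
            omit_chirps(song, len(song.chirps) + 1)


class TestSonogram:
    def test_silence_gives_zero_image(self):
        img = sonogram(np.full(10, 3.0), np.zeros(10))
        assert np.all(img == 0.0)

    def test_single_bin_ridge_centred_on_frequency(self):
        grid = np.linspace(2.0, 5.0, 64)
        img = sonogram(np.array([3.5]), np.array([1.0]), freq_grid=grid)
        assert grid[np.argmax(img[:, 0])] == pytest.approx(3.5, abs=0.05)

    def test_column_energy_proportional_to_amplitude(self):
        freq = np.full(4, 3.2)
        amp = np.array([0.5, 1.0, 2.0, 4.0])
        img = sonogram(freq, amp)
        integral = img.sum(axis=0)  # numeric integration over frequency
        ratios = integral / amp
        assert np.allclose(ratios, ratios[0], rtol=1e-9)


class TestRecognition:
    def test_recovers_slow_control_signals(self, birdsong_regimes):
        # on the intact song the inferred control parameters should track
        # the generator's (parameter/state recovery)
        from actinf.birdsong import run_birdsong, params_from_causes

        song, _, _ = birdsong_regimes
        rec = run_birdsong(song, (2.0, 8.0, 16.0), seed=0)
        cfg = BirdsongConfig()
        inferred = np.array([
            params_from_causes(
                [rec.mu_v0(0, 0)[t], rec.mu_v0(0, 1)[t]], cfg
            )
            for t in range(rec.n_bins)
        ])
        for k in range(2):
            r = np.corrcoef(inferred[40:, k], song.true_controls[40:, k])[0, 1]
            assert r > 0.8
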