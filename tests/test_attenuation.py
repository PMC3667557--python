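"""Sensory attenuation: squashing, process dynamics, percepts and indices."""

import numpy as np
import pytest

from actinf.attenuation import (
    AttenuationConfig,
    attenuated_log_precision,
    build_attenuation_process,
    outcome_metrics,
    perceived_force,
    squash,
)


class TestAttenuatedPrecision:
    def test_gamma_zero_keeps_baseline(self):
        for mu in [-1.0, 0.0, 2.0, 10.0]:
            assert attenuated_log_precision(mu, 0.0, 8.0) == 8.0

    def test_saturates_at_base_minus_gamma(self):
        assert attenuated_log_precision(100.0, 6.0, 8.0) == pytest.approx(2.0)

    def test_monotone_decreasing(self):
        # finite-difference sweep of the derivative
        mus = np.linspace(-3, 5, 60)
        for mu in mus:
            d = (attenuated_log_precision(mu + 1e-5, 6.0, 8.0)
                 - attenuated_log_precision(mu - 1e-5, 6.0, 8.0)) / 2e-5
            assert d <= 0.0

    def test_squash_bounded(self):
        u = np.linspace(-50, 50, 101)
        s = squash(u)
        assert np.all((s >= 0) & (s <= 1))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            AttenuationConfig(gamma=-1.0)


class TestProcess:
    def test_rest_stays_at_rest(self):
        from actinf.engine import step

        cfg = AttenuationConfig(process_noise_log_precision=32.0)
        proc = build_attenuation_process(cfg)
        x = np.zeros(2)
        for _ in range(20):
            x = step(lambda u: proc.flow(u, np.zeros(1), np.zeros(1)), x, 1.0)
        assert np.allclose(x, 0.0, atol=1e-12)

    def test_external_force_spares_proprioception(self):
        from actinf.engine import step

        cfg = AttenuationConfig(process_noise_log_precision=32.0)
        proc = build_attenuation_process(cfg)
        x = np.zeros(2)
        for _ in range(10):
            x = step(lambda u: proc.flow(u, np.array([1.0]), np.zeros(1)), x, 1.0)
        s = proc.output(x, np.array([1.0]), np.zeros(1))
        assert s[1] > 1.0  # somatosensory rises
        assert abs(s[0]) < 1e-9  # proprioception flat

    def test_force_decays_over_four_bins(self):
        from actinf.engine import step

        cfg = AttenuationConfig(process_noise_log_precision=32.0)
        proc = build_attenuation_process(cfg)
        x = np.array([2.0, 0.0])
        trace = []
        for _ in range(16):
            trace.append(x[0])
            x = step(lambda u: proc.flow(u, np.zeros(1), np.zeros(1)), x, 1.0)
        tau = -1.0 / np.polyfit(np.arange(len(trace)), np.log(trace), 1)[0]
        assert tau == pytest.approx(cfg.decay_time_constant, rel=0.02)


class TestPercept:
    def test_perceived_force_below_true_peak(self, force_suite):
        trial = force_suite["normal"]
        true_peak = float(np.max(trial.true_self_force))
        assert perceived_force(trial) < true_peak

    def test_percept_matches_band_table_scan(self, force_suite):
        # independent re-scan of the exported band series at the peak bin
        trial = force_suite["normal"]
        mu = trial.record.mu_x0(0, 0)
        peak = int(np.argmax(mu))
        lo, _ = trial.band("x", 0, 0.9)
        assert perceived_force(trial) == pytest.approx(float(lo[peak]))

    def test_no_percept_when_nothing_moves(self, force_suite):
        from dataclasses import replace

        from actinf.attenuation import run_force_trial

        cfg = replace(AttenuationConfig(), self_amplitude=0.0, duration=24)
        trial = run_force_trial(cfg, seed=0)
        with pytest.raises(ValueError):
            perceived_force(trial)


class TestOutcomeMetrics:
    def test_delusion_index_matches_band_scan(self, force_suite):
        trial = force_suite["compensated"]
        out = outcome_metrics(trial)
        lo, hi = trial.band("v", 1, 0.9)
        cfg = trial.config
        t = trial.record.time
        win = (t >= cfg.self_onset - 2 * cfg.self_width) & (
            t <= cfg.self_onset + 6 * cfg.self_width
        )
        # most extreme band edge of sign-definite (zero-excluding) bins
        excl = win & ((lo > 0) | (hi < 0))
        cand = np.where(excl & (hi < 0), hi, np.where(excl & (lo > 0), lo, 0.0))
        assert out.delusion_index == pytest.approx(
            float(cand[np.argmax(np.abs(cand))])
        )

    def test_band_ordering_self_vs_external(self, force_suite):
        trial = force_suite["external"]
        lo, hi = trial.band("x", 0, 0.9)
        width = hi - lo
        cfg = trial.config
        self_win = slice(10, 28)
        ext_win = slice(int(cfg.external_onset - 2), cfg.duration - 2)
        assert np.max(width[self_win]) > 2 * np.max(width[ext_win])
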