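"""Spike detection and the temporal-coding metric suite."""

import numpy as np
import pytest
from scipy.special import iv

from gbcsim import metrics as mt
from gbcsim import synthetic as syn


def _triangular_ap(dt_ms=0.025, base=-65.0, amp=60.0, width_ms=1.0):
    """Synthetic AP: triangular, steep slopes, on a resting baseline."""
    t = np.arange(0.0, 20.0, dt_ms)
    v = np.full_like(t, base)
    peak_t = 10.0
    rise = (t >= peak_t - width_ms / 2) & (t <= peak_t)
    fall = (t > peak_t) & (t <= peak_t + width_ms / 2)
    v[rise] = base + amp * (t[rise] - (peak_t - width_ms / 2)) / (width_ms / 2)
    v[fall] = base + amp * ((peak_t + width_ms / 2) - t[fall]) / (width_ms / 2)
    return t, v


class TestDetectSpikes:
    def test_flat_trace(self):
        t = np.arange(0, 100, 0.025)
        assert len(mt.detect_spikes(t, np.full_like(t, -65.0))) == 0

    def test_synthetic_ap_detected_at_peak(self):
        t, v = _triangular_ap()
        sp = mt.detect_spikes(t, v)
        assert len(sp) == 1
        assert sp[0] * 1e3 == pytest.approx(10.0, abs=0.05)

    def test_slow_epsp_rejected(self):
        # 10 mV EPSP with a 5 ms rise fails height and slope criteria
        t = np.arange(0.0, 30.0, 0.025)
        v = -65.0 + 10.0 * np.exp(-((t - 10.0) ** 2) / (2 * 2.0**2))
        assert len(mt.detect_spikes(t, v)) == 0

    def test_wide_peak_rejected(self):
        t, v = _triangular_ap(width_ms=5.0)
        assert len(mt.detect_spikes(t, v)) == 0


class TestVectorStrength:
    def test_identical_phase_gives_one(self):
        trains = syn.make_control_trains("periodic", f_mod=100.0, n_trials=5, seed=0)
        res = mt.vector_strength(trains, 100.0)
        assert res.vs == pytest.approx(1.0, abs=1e-9)

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(1)
        trains = [np.sort(rng.uniform(0, 1, 5000)) for _ in range(2)]
        res = mt.vector_strength(trains, 100.0)
        assert res.vs < 0.02

    def test_von_mises_bessel_oracle(self):
        kappa = 2.0
        trains = syn.make_control_trains(
            "von_mises", f_mod=100.0, kappa=kappa, n_trials=100,
            duration_s=1.0, seed=2,
        )
        res = mt.vector_strength(trains, 100.0)
        expect = iv(1, kappa) / iv(0, kappa)
        n = res.n_spikes
        se = np.sqrt((1 - expect**2) / (2 * n)) + 1e-3
        assert abs(res.vs - expect) < 3 * se
        assert res.n_groups == 10  # 10 groups of 10 trials

    def test_low_count_invalid(self):
        res = mt.vector_strength([np.array([0.001, 0.011])], 100.0)
        assert not res.valid


class TestRMTF:
    def test_constant_poisson_rate_recovered(self):
        trains = syn.make_control_trains("poisson", rate_hz=100.0, n_trials=50,
                                         duration_s=1.0, seed=3)
        out = mt.rmtf({50.0: trains, 200.0: trains}, stim_dur_s=1.0)
        for f, r in out.items():
            assert r == pytest.approx(100.0, rel=0.1)

    def test_window_is_integer_cycles(self):
        a, b = mt._cycle_window(130.0, 0.0, 1.0, 0.25)
        n = (b - a) * 130.0
        assert n == pytest.approx(round(n), abs=1e-9)
        assert b <= 1.0

    def test_onset_excluded(self):
        base = syn.make_control_trains("poisson", rate_hz=80.0, n_trials=30,
                                       duration_s=1.0, seed=4)
        burst = [np.sort(np.concatenate([t, np.random.default_rng(5).uniform(0, 0.2, 40)]))
                 for t in base]
        r1 = mt.rmtf({100.0: base}, stim_dur_s=1.0)[100.0]
        r2 = mt.rmtf({100.0: burst}, stim_dur_s=1.0)[100.0]
        assert r2 == pytest.approx(r1, rel=1e-9)  # onset spikes ignored

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            mt._cycle_window(1.0, 0.0, 1.0, 0.25)


class TestEntrainment:
    def test_one_spike_per_cycle(self):
        trains = syn.make_control_trains("periodic", f_mod=100.0, n_trials=4,
                                         duration_s=1.0, seed=0)
        ei = mt.entrainment(trains, 100.0, stim_dur_s=1.0)
        assert ei == pytest.approx(1.0, abs=0.02)

    def test_alternate_cycles_excluded(self):
        # one spike every second cycle: ISI = 2/f falls outside [0.5/f, 1.5/f]
        trains = syn.make_control_trains("periodic", f_mod=50.0, n_trials=4,
                                         duration_s=1.0, seed=0)
        ei = mt.entrainment(trains, 100.0, stim_dur_s=1.0)
        assert ei == 0.0

    def test_boundary_isi_counted_closed(self):
        # ISI exactly 0.5/f sits on the closed lower bound
        f = 100.0
        tr = [0.25 + np.arange(0, 0.74, 0.5 / f)]
        ei = mt.entrainment(tr, f, stim_dur_s=1.0)
        assert ei > 0.9  # two ISIs per cycle, each exactly at the bound

    def test_empty(self):
        assert mt.entrainment([np.array([])], 100.0, stim_dur_s=1.0) == 0.0


class TestSAC:
    def test_poisson_flat_at_one(self):
        trains = syn.make_control_trains("poisson", rate_hz=100.0, n_trials=50,
                                         duration_s=1.0, seed=6)
        res = mt.sac(trains, window_s=(0.0, 1.0))
        assert res.ci == pytest.approx(1.0, abs=0.15)
        assert np.mean(res.rate) == pytest.approx(1.0, abs=0.05)
        assert res.rate.std() < 0.15

    def test_periodic_peaks_at_multiples(self):
        trains = syn.make_control_trains("periodic", f_mod=500.0, n_trials=10,
                                         duration_s=0.5, seed=0)
        res = mt.sac(trains, binwidth_ms=0.05, maxlag_ms=5.0, window_s=(0.0, 0.5))
        assert res.ci > 10.0
        period_bin = np.argmin(np.abs(res.lags_ms - 2.0))
        assert res.rate[period_bin] > 10.0

    def test_jitter_broadens_halfwidth(self):
        rng = np.random.default_rng(7)
        widths = []
        for sigma_ms in (0.05, 0.2):
            base = syn.make_control_trains("periodic", f_mod=100.0, n_trials=20,
                                           duration_s=1.0, seed=0)
            jit = [np.sort(t + rng.normal(0, sigma_ms * 1e-3, len(t))) for t in base]
            res = mt.sac(jit, window_s=(0.0, 1.0))
            widths.append(res.halfwidth_ms)
        assert widths[0] < widths[1]

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            mt.sac([np.array([0.1])])


class TestCrossCorrelogram:
    def test_shifted_delta_train(self):
        post = [np.arange(0.01, 1.0, 0.01)]
        pre = [post[0] - 1e-3]
        lags, rate = mt.cross_correlogram(pre, post, range_ms=5.0, res_ms=0.1)
        assert len(lags) == 50  # range/res bins exactly
        peak = lags[np.argmax(rate)]
        assert peak == pytest.approx(-1.0, abs=0.06)
        assert rate.max() > 0

    def test_independent_poisson_flat(self):
        pre = syn.make_control_trains("poisson", rate_hz=200.0, n_trials=30,
                                      duration_s=1.0, seed=8)
        post = syn.make_control_trains("poisson", rate_hz=50.0, n_trials=30,
                                       duration_s=1.0, seed=9)
        lags, rate = mt.cross_correlogram(pre, post)
        assert np.mean(rate) == pytest.approx(200.0, rel=0.1)


class TestEfficacyParticipation:
    def test_perfect_efficacy(self):
        pre = [np.arange(0.01, 1.0, 0.01)] * 3
        post = [t + 1.5e-3 for t in pre]
        assert mt.efficacy(pre, post) == 1.0

    def test_participation_counting_oracle(self):
        # input A precedes exactly 40% of post spikes inside (-2.7, -0.5) ms
        post = [np.arange(0.1, 1.1, 0.01)]  # 100 spikes
        a_times = post[0][:40] - 1.5e-3
        b_times = post[0][40:] - 1.5e-3
        part = mt.participation([[a_times], [b_times]], post)
        assert part[0] == pytest.approx(0.40)
        assert part[1] == pytest.approx(0.60)

    def test_attribution_partitions_posts(self):
        rng = np.random.default_rng(10)
        post = [np.sort(rng.uniform(0.1, 1.0, 200))]
        inputs = []
        for k in range(3):
            sel = rng.random(200) < 0.5
            inputs.append([np.sort(post[0][sel] - rng.uniform(0.6e-3, 2.6e-3))])
        res = mt.efficacy_participation(inputs, post)
        covered = 0
        for tp in post[0]:
            hit = any(
                mt._fired_in_window(np.asarray(inputs[k][0]), tp, (-2.7e-3, -0.5e-3))
                for k in range(3)
            )
            covered += hit
        assert res.attribution.sum() * res.n_post == pytest.approx(covered)

    def test_zero_presyn_flagged(self):
        with pytest.raises(mt.FitError):
            mt.efficacy([np.array([])], [np.array([0.1])])


class TestLogisticFit:
    def test_noiseless_recovery(self):
        asa = np.linspace(40, 260, 12)
        eff = 0.72 / (1 + np.exp(-(asa - 148.6) / 14.3))
        fit = mt.fit_logistic(asa, eff)
        assert fit.emax == pytest.approx(0.72, abs=1e-6)
        assert fit.a50_um2 == pytest.approx(148.6, abs=1e-4)
        assert fit.k_um2 == pytest.approx(14.3, abs=1e-4)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.default_rng(12)
        asa = np.linspace(40, 260, 24)
        eff = 0.72 / (1 + np.exp(-(asa - 148.6) / 14.3)) + rng.normal(0, 0.01, 24)
        fit = mt.fit_logistic(asa, np.clip(eff, 0, 1))
        assert fit.emax == pytest.approx(0.72, rel=0.05)
        assert fit.a50_um2 == pytest.approx(148.6, rel=0.05)
        assert fit.k_um2 == pytest.approx(14.3, rel=0.05)

    def test_degenerate_raises(self):
        with pytest.raises(mt.FitError):
            mt.fit_logistic(np.linspace(40, 260, 8), np.zeros(8))


class TestLatencyRegularity:
    def test_deterministic_fsl_sd_zero(self):
        trains = [np.array([0.105, 0.2]), np.array([0.105, 0.21])]
        out = mt.fsl_ssl(trains, onset_s=0.1)
        assert out["fsl_s"].std() == 0.0
        assert out["fsl_s"][0] == pytest.approx(0.005)

    def test_poisson_cv_near_one(self):
        trains = syn.make_control_trains("poisson", rate_hz=200.0, n_trials=50,
                                         duration_s=1.0, seed=13)
        cv = mt.isi_cv(trains)
        n = sum(len(t) - 1 for t in trains)
        assert abs(cv - 1.0) < 3 / np.sqrt(n) + 0.02

    def test_dead_time_lowers_cv(self):
        trains = syn.make_control_trains("dead_time_poisson", rate_hz=300.0,
                                         dead_time_s=2e-3, n_trials=50,
                                         duration_s=1.0, seed=14)
        assert mt.isi_cv(trains) < 0.9

    def test_event_csv_round_trip(self, tmp_path):
        trains = syn.make_control_trains("poisson", rate_hz=50.0, n_trials=3,
                                         duration_s=0.5, seed=15)
        p = tmp_path / "ev.csv"
        mt.write_events_csv(p, trains)
        back = mt.read_events_csv(p)
        assert len(back) == 3
        for a, b in zip(trains, back):
            assert np.allclose(np.sort(a), b)
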