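import numpy as np
import pytest
from scipy import stats
from scipy.special import i0, i1

from thetaloco import spectral, synth, theta
from thetaloco.circstats import rayleigh_test, resultant_length


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            synth.GeneratorConfig(duration_s=-1).validate()
        with pytest.raises(ValueError):
            synth.GeneratorConfig(entrain_gain=1.5).validate()
        with pytest.raises(ValueError):
            synth.GeneratorConfig(amp_cv=-0.1).validate()


class TestPulseTrain:
    def test_count_equals_freq_times_duration(self):
        assert synth.generate_pulse_train(7.0, 30.0, 2.0).n_pulses == 14

    def test_inter_onset_interval_exact(self):
        tr = synth.generate_pulse_train(10.0, 30.0, 1.0)
        np.testing.assert_allclose(np.diff(tr.onset_t), 0.1, atol=1e-12)

    @pytest.mark.parametrize("freq", [2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
    def test_protocol_frequency_set_accepted(self, freq):
        tr = synth.generate_pulse_train(freq, 30.0, 45.0)
        assert tr.n_pulses == int(freq * 45)

    def test_overlapping_duty_cycle_rejected(self):
        with pytest.raises(ValueError, match="duty"):
            synth.generate_pulse_train(40.0, 30.0, 1.0)


class TestThetaLfp:
    def test_degenerate_config_is_pure_tone(self):
        cfg = synth.GeneratorConfig(seed=0, duration_s=60.0, amp_cv=0.0,
                                    freq_cv=0.0, noise_sd=0.0,
                                    gamma_coupling=0.0)
        tr = synth.generate_theta_lfp(cfg)
        cyc = theta.detect_theta_cycles(tr)
        interior = cyc.amplitude[2:-2]   # filter transients distort the edges
        assert np.std(interior) / np.mean(interior) < 0.02
        psd = spectral.compute_psd(tr, 10.0, 20.0)
        assert spectral.entrainment_fidelity(psd, 8.0) > 0.95

    @pytest.mark.parametrize("amp_cv", [0.1, 0.2, 0.4])
    def test_envelope_cv_calibrated(self, amp_cv):
        vals = []
        for seed in range(6):
            cfg = synth.GeneratorConfig(seed=seed, duration_s=300.0,
                                        amp_cv=amp_cv, noise_sd=0.02)
            cyc = theta.detect_theta_cycles(synth.generate_theta_lfp(cfg))
            vals.append(cyc.amplitude_cv())
        assert np.mean(vals) == pytest.approx(amp_cv, abs=0.05)

    def test_zero_coupling_pac_within_null(self, rng):
        cfg = synth.GeneratorConfig(seed=4, duration_s=120.0,
                                    gamma_coupling=0.0)
        tr = synth.generate_theta_lfp(cfg)
        ph = theta.hilbert_phase(tr)
        gt, ga = theta.detect_gamma_peaks(tr)
        gp = ph.at(gt)
        null = theta.pac_shuffle_null(gp, ga, n_shuffles=200, rng=rng)
        assert theta.modulation_coefficient(gp, ga) < np.quantile(null, 0.95)


class TestEntrainedLfp:
    def test_full_gain_pins_dominant_frequency(self):
        cfg = synth.GeneratorConfig(seed=0, duration_s=60.0, entrain_gain=1.0,
                                    noise_sd=0.0)
        pulses = synth.generate_pulse_train(8.0, 30.0, 60.0)
        tr = synth.generate_entrained_lfp(cfg, pulses)
        psd = spectral.compute_psd(tr, 10.0, 20.0)
        df = psd.freqs[1] - psd.freqs[0]
        assert abs(spectral.dominant_frequency(psd) - 8.0) <= df

    def test_zero_gain_matches_spontaneous_statistics(self):
        """gain 0 leaves the stochastic clock untouched: same amplitude-CV
        and frequency spread as the spontaneous generator."""
        cvs_a, cvs_b = [], []
        for seed in range(5):
            cfg = synth.GeneratorConfig(seed=seed, duration_s=120.0,
                                        entrain_gain=0.0)
            pulses = synth.generate_pulse_train(8.0, 30.0, 120.0)
            a = theta.detect_theta_cycles(synth.generate_entrained_lfp(cfg, pulses))
            b = theta.detect_theta_cycles(synth.generate_theta_lfp(cfg))
            cvs_a.append(a.amplitude_cv())
            cvs_b.append(b.amplitude_cv())
        assert np.mean(cvs_a) == pytest.approx(np.mean(cvs_b), abs=0.05)

    def test_fidelity_increases_with_gain(self):
        grid = [0.2, 0.5, 0.9]
        means = []
        for g in grid:
            vals = []
            for seed in range(5):
                cfg = synth.GeneratorConfig(seed=seed, duration_s=60.0,
                                            entrain_gain=g)
                pulses = synth.generate_pulse_train(8.0, 30.0, 60.0)
                tr = synth.generate_entrained_lfp(cfg, pulses)
                psd = spectral.compute_psd(tr, 10.0, 20.0)
                vals.append(spectral.entrainment_fidelity(psd, 8.0))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_pulses_beyond_duration_rejected(self):
        cfg = synth.GeneratorConfig(duration_s=10.0)
        with pytest.raises(ValueError, match="beyond"):
            synth.generate_entrained_lfp(
                cfg, synth.generate_pulse_train(8.0, 30.0, 20.0))


@pytest.fixture(scope="module")
def cycles():
    cfg = synth.GeneratorConfig(seed=8, duration_s=200.0, noise_sd=0.02)
    return theta.detect_theta_cycles(synth.generate_theta_lfp(cfg))


class TestSpikes:

    def test_infinite_kappa_all_at_preferred_phase(self, cycles, rng):
        sp = synth.generate_spike_train(cycles, 90.0, np.inf, 2.0, 0.0,
                                        rng=rng)
        ph = theta.interpolated_phase(cycles, 1250.0)
        vals = ph.at(sp.spike_t)
        vals = vals[np.isfinite(vals)]
        assert resultant_length(vals) > 0.98

    def test_kappa_zero_rayleigh_uniform(self, cycles, rng):
        ps = []
        for _ in range(200):
            sp = synth.generate_spike_train(cycles, 0.0, 0.0, 0.5, 0.0,
                                            rng=rng)
            ph = 360.0 * rng.random(sp.n_spikes)  # phases uniform by design
            ps.append(rayleigh_test(ph))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0])
    def test_resultant_matches_von_mises_closed_form(self, cycles, kappa):
        """Measured R of generated spikes = I1(k)/I0(k) within 0.05."""
        ph_series = theta.interpolated_phase(cycles, 1250.0)
        rng = np.random.default_rng(kappa.__hash__() % 1000)
        rs = []
        for _ in range(4):
            sp = synth.generate_spike_train(cycles, 90.0, kappa, 5.0, 0.0,
                                            rng=rng)
            vals = ph_series.at(sp.spike_t)
            rs.append(resultant_length(vals[np.isfinite(vals)]))
        assert np.mean(rs) == pytest.approx(float(i1(kappa) / i0(kappa)),
                                            abs=0.05)

    def test_negative_expected_counts_clamped(self, cycles, rng, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="thetaloco.synth"):
            sp = synth.generate_spike_train(cycles, 0.0, 1.0, 2.0, -8.0,
                                            rng=rng)
        assert sp.n_spikes > 0
        assert any("clamped" in r.message for r in caplog.records)


class TestPositionTrack:
    def test_positions_stay_in_arena(self):
        cfg = synth.GeneratorConfig(seed=1, duration_s=120.0,
                                    speed_base_cm_s=20.0)
        trk = synth.generate_position_track(cfg, np.full(12, 0.3))
        assert trk.x.min() >= 0 and trk.x.max() <= 48.0
        assert trk.y.min() >= 0 and trk.y.max() <= 30.0

    def test_zero_gain_decouples_speed_from_amplitude_cv(self):
        from thetaloco.locomotion import instantaneous_speed

        cfg = synth.GeneratorConfig(seed=2, duration_s=1000.0,
                                    speed_amp_cv_gain=0.0)
        cvs = np.random.default_rng(0).uniform(0.05, 0.5, 100)
        trk = synth.generate_position_track(cfg, cvs)
        sp = instantaneous_speed(trk)
        meas = [np.std(s) / np.mean(s) for s in
                np.array_split(sp.speed_cm_s, 100)]
        r = np.corrcoef(cvs, meas)[0, 1]
        assert abs(r) < 0.2

    def test_positive_gain_couples_speed_cv(self):
        from thetaloco.locomotion import instantaneous_speed

        cfg = synth.GeneratorConfig(seed=2, duration_s=1000.0,
                                    speed_amp_cv_gain=1.0)
        cvs = np.random.default_rng(0).uniform(0.05, 0.5, 100)
        trk = synth.generate_position_track(cfg, cvs)
        sp = instantaneous_speed(trk)
        meas = [np.std(s) / np.mean(s) for s in
                np.array_split(sp.speed_cm_s, 100)]
        rho = stats.spearmanr(cvs, meas).statistic
        assert rho > 0.5


class TestSession:
    def test_same_seed_reproduces_bit_for_bit(self):
        cfg = synth.GeneratorConfig(seed=7, duration_s=90.0, segment_s=30.0)
        a = synth.generate_session(cfg)
        b = synth.generate_session(cfg)
        np.testing.assert_array_equal(a.lfp.data, b.lfp.data)
        np.testing.assert_array_equal(a.track.x, b.track.x)
        np.testing.assert_array_equal(a.pulses.onset_t, b.pulses.onset_t)
        for ta, tb in zip(a.spikes, b.spikes):
            np.testing.assert_array_equal(ta.spike_t, tb.spike_t)

    def test_pulses_only_in_pulsed_epochs(self):
        cfg = synth.GeneratorConfig(seed=7, duration_s=180.0, segment_s=30.0,
                                    stim_freq_hz=9.0)
        bundle = synth.generate_session(cfg)
        labels = bundle.condition_labels
        pulsed = labels[labels["condition"] != "spontaneous"]
        for onset in bundle.pulses.onset_t:
            epoch = int(onset // 10.0)
            assert epoch in set(pulsed["epoch_id"])

    def test_condition_blocks_cycle_through_protocol(self):
        cfg = synth.GeneratorConfig(seed=1, duration_s=90.0, segment_s=30.0)
        labels = synth.generate_session(cfg).condition_labels["condition"]
        assert list(labels[:3]) == ["spontaneous"] * 3
        assert all(lab.startswith("entrained") for lab in labels[3:6])
        assert list(labels[6:9]) == ["control-light"] * 3
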