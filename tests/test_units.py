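import numpy as np
import pytest
from scipy import stats

from thetaloco import synth, theta, units
from thetaloco.io import PositionTrack, SpikeTrain
from thetaloco.theta import PhaseSeries


def uniform_phase_series(duration_s: float = 100.0, rate: float = 1250.0,
                         freq: float = 8.0) -> PhaseSeries:
    t = np.arange(int(duration_s * rate)) / rate
    return PhaseSeries(t, np.mod(360.0 * freq * t, 360.0))


class TestPhaseHistogram:
    def test_uniform_events_uniform_occupancy(self, rng):
        ph = uniform_phase_series()
        events = rng.uniform(0, 100, 5000)
        h = units.normalized_phase_histogram(events, ph, n_bins=12)
        np.testing.assert_allclose(h.prob, 1 / 12, atol=0.02)
        assert h.prob.sum() == pytest.approx(1.0)

    def test_occupancy_correction_recovers_uniformity(self, rng):
        """Events drawn proportionally to a skewed phase occupancy must
        come out flat after the correction."""
        rate = 1250.0
        t = np.arange(int(200 * rate)) / rate
        # skewed dwell: oscillation spends longer on the falling half
        u = np.mod(8.0 * t, 1.0)
        phase = np.mod(np.where(u < 0.3, u / 0.3 * 180.0,
                                180.0 + (u - 0.3) / 0.7 * 180.0), 360.0)
        ph = PhaseSeries(t, phase)
        # events emitted at LFP-sample times, uniform in *time* -> their
        # phase distribution follows the skewed occupancy
        events = rng.choice(t, size=8000, replace=False)
        h = units.normalized_phase_histogram(events, ph, n_bins=12)
        # multinomial 95% band around uniform
        se = np.sqrt((1 / 12) * (1 - 1 / 12) / 8000) * 12
        assert np.all(np.abs(h.prob - 1 / 12) < 4 * se + 0.01)

    def test_fully_concentrated_events(self):
        # 6.25 Hz puts cycle starts exactly on LFP samples (200 per cycle)
        ph = uniform_phase_series(freq=6.25)
        peaks = np.arange(1, 99) * 0.16  # phase 0 at each cycle start
        h = units.normalized_phase_histogram(peaks, ph, n_bins=12)
        # float modular arithmetic can park a stray event at 360 - eps
        assert h.prob[0] > 0.98
        assert h.resultant_length > 0.99

    def test_no_events_in_defined_phase_rejected(self):
        ph = uniform_phase_series(10.0)
        with pytest.raises(ValueError):
            units.normalized_phase_histogram(np.array([500.0]), ph)


class TestClassifyUnit:
    @staticmethod
    def bursty_train(rate_hz: float, duration: float, rng) -> SpikeTrain:
        base = np.sort(rng.uniform(0, duration, int(rate_hz * duration)))
        pick = rng.random(base.size) < 0.5
        extra = base[pick] + rng.uniform(0.003, 0.008, int(pick.sum()))
        return SpikeTrain(0, np.sort(np.concatenate([base, extra])))

    def test_bursty_slow_unit_is_pyramidal(self, rng):
        tr = self.bursty_train(1.0, 600.0, rng)
        assert units.classify_unit(tr, 600.0) == "pyramidal"

    def test_fast_regular_unit_is_interneuron(self, rng):
        t = np.sort(rng.uniform(0, 100, 2000))  # 20 Hz Poisson
        assert units.classify_unit(SpikeTrain(0, t), 100.0) == \
            "fast-firing interneuron"

    def test_rate_exactly_at_bound_is_not_pyramidal(self, rng):
        # 3.5 Hz exactly: the pyramidal criterion is strict
        tr = self.bursty_train(3.5 / 1.5, 600.0, rng)
        n = tr.n_spikes
        duration = n / 3.5
        assert units.classify_unit(tr, duration) != "pyramidal"

    def test_sparse_unit_unclassified(self, rng):
        tr = SpikeTrain(0, np.sort(rng.uniform(0, 100, 30)))
        assert units.classify_unit(tr, 100.0) == "unclassified"


@pytest.fixture(scope="module")
def synthetic_cycles_phase():
    cfg = synth.GeneratorConfig(seed=21, duration_s=300.0, amp_cv=0.3,
                                noise_sd=0.02)
    tr = synth.generate_theta_lfp(cfg)
    cyc = theta.detect_theta_cycles(tr)
    ph = theta.interpolated_phase(cyc, tr.rate_hz, duration_s=tr.duration_s)
    return cyc, ph


class TestPairwiseRegression:
    def test_nine_spikes_in_a_bin_excludes_neuron(self, synthetic_cycles_phase):
        cyc, ph = synthetic_cycles_phase
        # 20 spikes at peaks, 9 at troughs
        peak_t = cyc.peak_t[5:25] + 1e-4
        trough_t = cyc.trough_t[5:14] + 1e-4
        tr = SpikeTrain(0, np.sort(np.concatenate([peak_t, trough_t])))
        res = units.pairwise_amplitude_spike_regression(tr, cyc, ph)
        assert res.excluded
        assert "trough" in res.exclusion_reason
        assert res.spikes_per_bin["trough"] == 9

    def test_positive_coupling_recovered(self, synthetic_cycles_phase):
        cyc, ph = synthetic_cycles_phase
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(10):
            sp = synth.generate_spike_train(cyc, 0.0, 1.0, 3.0, 0.6, rng=rng)
            res = units.pairwise_amplitude_spike_regression(sp, cyc, ph,
                                                            rng=rng)
            hits += (res.slope > 0) and (res.slope_p < 0.05)
        assert hits >= 7

    def test_null_not_over_rejected(self, synthetic_cycles_phase):
        cyc, ph = synthetic_cycles_phase
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(40):
            sp = synth.generate_spike_train(cyc, 0.0, 1.0, 3.0, 0.0, rng=rng)
            res = units.pairwise_amplitude_spike_regression(sp, cyc, ph,
                                                            rng=rng)
            ps.append(res.slope_p)
        assert np.mean(np.array(ps) < 0.05) <= 0.15

    def test_pair_difference_antisymmetry(self, rng):
        counts = rng.poisson(2.0, 50).astype(float)
        amps = rng.lognormal(0, 0.3, 50)
        s, a = units.enumerate_pairs(counts, amps, rng=rng)
        s2, a2 = units.enumerate_pairs(-(-counts), amps, rng=rng)
        # S(i,j) = -S(j,i): flipping the roles flips both difference signs,
        # leaving the regression slope unchanged
        slope = np.dot(a, s) / np.dot(a, a)
        slope_flipped = np.dot(-a, -s) / np.dot(a, a)
        assert slope == pytest.approx(slope_flipped)

    def test_subsampling_approximates_full_enumeration(self, rng):
        counts = rng.poisson(2.0, 400).astype(float)
        amps = rng.lognormal(0, 0.3, 400)
        s_full, a_full = units.enumerate_pairs(counts, amps,
                                               max_pairs=10**9, rng=rng)
        s_sub, a_sub = units.enumerate_pairs(counts, amps, max_pairs=20_000,
                                             rng=rng)
        assert s_sub.size == 20_000
        full = np.dot(a_full, s_full) / np.dot(a_full, a_full)
        sub = np.dot(a_sub, s_sub) / np.dot(a_sub, a_sub)
        assert sub == pytest.approx(full, abs=0.1 * max(abs(full), 0.05))


class TestFiringMaps:
    @staticmethod
    def grid_track(duration: float = 400.0, rate: float = 25.0):
        """Serpentine sweep visiting the arena uniformly."""
        n = int(duration * rate)
        t = np.arange(n) / rate
        x = 24.0 + 23.0 * np.sin(2 * np.pi * t / 40.0)
        y = 15.0 + 14.0 * np.sin(2 * np.pi * t / 7.3)
        return PositionTrack(t, x, y)

    def test_uniform_firing_gives_sparsity_one(self, rng):
        trk = self.grid_track()
        speed = np.full(trk.t.size, 10.0)
        spikes = SpikeTrain(0, np.sort(rng.uniform(0, 400.0, 4000)))
        fm = units.firing_map_stats(spikes, trk, speed)
        # rate is constant only on average; Poisson pixel noise lowers it
        assert fm.sparsity == pytest.approx(1.0, abs=0.25)

    def test_uniform_rate_map_closed_form(self):
        occ = np.ones((15, 24))
        rate = np.full((15, 24), 3.0)
        assert units.sparsity(rate, occ) == pytest.approx(1.0)

    def test_single_pixel_firing_closed_form(self):
        occ = np.ones((10, 10))
        rate = np.zeros((10, 10))
        rate[4, 7] = 5.0
        assert units.sparsity(rate, occ) == pytest.approx(1.0 / 100)

    def test_shuffled_maps_have_zero_mean_coherence(self, rng):
        zs = []
        for _ in range(100):
            rate = rng.lognormal(0, 0.5, (15, 24))
            zs.append(units.spatial_coherence_z(rate))
        assert abs(np.mean(zs)) < 0.05

    def test_smooth_map_has_positive_coherence(self):
        yy, xx = np.mgrid[0:15, 0:24]
        rate = np.exp(-((xx - 12.0) ** 2 + (yy - 7.0) ** 2) / 20.0)
        assert units.spatial_coherence_z(rate) > 1.0

    def test_immobile_spikes_excluded(self, rng):
        trk = self.grid_track()
        speed = np.full(trk.t.size, 10.0)
        speed[: trk.t.size // 2] = 0.0  # immobile first half
        spikes = SpikeTrain(0, np.sort(rng.uniform(0, 200.0, 500)))
        fm = units.firing_map_stats(spikes, trk, speed)
        assert fm.spike_count.sum() == 0

    def test_zero_running_time_rejected(self, rng):
        trk = self.grid_track(100.0)
        with pytest.raises(ValueError, match="running"):
            units.firing_map_stats(SpikeTrain(0, np.array([1.0])), trk,
                                   np.zeros(trk.t.size))
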