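import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thetaloco import locomotion as loco
from thetaloco import spectral, synth
from thetaloco.io import PositionTrack
from thetaloco.spectral import EpochMetrics


def straight_track(speed_cm_s: float, duration: float = 60.0,
                   rate: float = 25.0) -> PositionTrack:
    t = np.arange(int(duration * rate)) / rate
    return PositionTrack(t, speed_cm_s * t, np.full(t.size, 5.0))


class TestInstantaneousSpeed:
    def test_stationary_track_zero_speed(self):
        t = np.arange(250) / 25.0
        sp = loco.instantaneous_speed(PositionTrack(t, np.full(250, 3.0),
                                                    np.full(250, 4.0)))
        assert np.all(sp.speed_cm_s == 0.0)
        assert not sp.is_running.any()

    def test_straight_line_speed_recovered(self):
        sp = loco.instantaneous_speed(straight_track(10.0))
        mid = (sp.t > 2) & (sp.t < 58)
        assert np.all(np.abs(sp.speed_cm_s[mid] - 10.0) < 0.2)

    def test_head_jitter_rejected(self):
        """8 Hz 1-cm head swings dominate the raw frame speed but must be
        removed by the low-pass filter."""
        t = np.arange(int(60 * 25)) / 25.0
        trk = PositionTrack(t, 10.0 * t + np.sin(2 * np.pi * 8 * t),
                            np.full(t.size, 5.0))
        raw = np.hypot(np.diff(trk.x), np.diff(trk.y)) * 25.0
        sp = loco.instantaneous_speed(trk)
        mid = (sp.t > 5) & (sp.t < 55)
        raw_cv = raw[mid].std() / raw[mid].mean()
        filt_cv = sp.speed_cm_s[mid].std() / max(sp.speed_cm_s[mid].mean(), 1e-9)
        assert np.all(np.abs(sp.speed_cm_s[mid] - 10.0) < 1.0)
        assert raw_cv > 10 * filt_cv

    def test_duplicate_timestamps_rejected(self):
        t = np.array([0.0, 0.04, 0.04, 0.12])
        with pytest.raises(ValueError):
            loco.instantaneous_speed(PositionTrack(t, t, t))


def make_epochs(n: int) -> list[EpochMetrics]:
    return [EpochMetrics(e, e * 10.0, (e + 1) * 10.0) for e in range(n)]


class TestEpochMetrics:
    def test_constant_running(self):
        sp = loco.instantaneous_speed(straight_track(10.0, duration=30.0))
        eps = loco.epoch_locomotion_metrics(sp, make_epochs(3))
        m = eps[1]
        assert m.speed_mean_cm_s == pytest.approx(10.0, abs=0.1)
        assert m.speed_cv == pytest.approx(0.0, abs=0.01)
        assert m.frac_running == pytest.approx(1.0)
        assert m.path_length_cm == pytest.approx(100.0, rel=0.02)

    def test_half_time_running(self):
        # 0 and 10 cm/s alternating in 1-s blocks
        rate = 25.0
        t = np.arange(int(30 * rate)) / rate
        v = np.where((t // 1.0) % 2 == 0, 10.0, 0.0)
        x = np.cumsum(v) / rate
        sp = loco.SpeedSeries(t, v, v > 2.0)
        eps = loco.epoch_locomotion_metrics(sp, make_epochs(3))
        assert eps[1].frac_running == pytest.approx(0.5, abs=0.05)
        assert eps[1].speed_mean_cm_s == pytest.approx(10.0)

    def test_generator_speed_cv_recovered(self):
        cfg = synth.GeneratorConfig(seed=6, duration_s=300.0,
                                    speed_amp_cv_gain=1.0, speed_cv_base=0.0)
        trk = synth.generate_position_track(cfg, np.full(30, 0.3))
        sp = loco.instantaneous_speed(trk)
        eps = loco.epoch_locomotion_metrics(sp, make_epochs(30))
        cvs = [m.speed_cv for m in eps if np.isfinite(m.speed_cv)]
        assert np.mean(cvs) == pytest.approx(0.3, abs=0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_cv_is_scale_free(self, scale):
        rng = np.random.default_rng(0)
        t = np.arange(250) / 25.0
        v = rng.lognormal(2.0, 0.3, 250)
        a = loco.SpeedSeries(t, v, v > 2.0)
        # same running mask: the invariant concerns the CV computation
        b = loco.SpeedSeries(t, v * scale, v > 2.0)
        ea = loco.epoch_locomotion_metrics(a, make_epochs(1))[0]
        eb = loco.epoch_locomotion_metrics(b, make_epochs(1))[0]
        assert ea.speed_cv == pytest.approx(eb.speed_cv, rel=1e-6)

    def test_path_length_bounds_net_displacement(self, rng):
        cfg = synth.GeneratorConfig(seed=3, duration_s=100.0)
        trk = synth.generate_position_track(cfg, np.full(10, 0.2))
        sp = loco.instantaneous_speed(trk)
        eps = loco.epoch_locomotion_metrics(sp, make_epochs(10))
        for m in eps:
            i0 = int(m.t_start_s * 25)
            i1 = min(int(m.t_end_s * 25), trk.t.size) - 1
            net = np.hypot(trk.x[i1] - trk.x[i0], trk.y[i1] - trk.y[i0])
            if np.isfinite(m.path_length_cm):
                assert m.path_length_cm >= 0.9 * net


class TestRunInitiation:
    @staticmethod
    def speed_with_onsets(responses: dict[str, list[bool]]):
        """25 s immobility before each onset; response = 5 s of running."""
        rate = 25.0
        segs = []
        onsets = {}
        t_cursor = 0.0
        for cond, flags in responses.items():
            onsets[cond] = []
            for moved in flags:
                segs.append(np.zeros(int(25 * rate)))
                onsets[cond].append(t_cursor + 25.0)
                post = np.full(int(15 * rate), 10.0 if moved else 0.0)
                segs.append(post)
                t_cursor += 40.0
        v = np.concatenate(segs)
        t = np.arange(v.size) / rate
        return loco.SpeedSeries(t, v, v > 2.0), onsets

    def test_balanced_counts_chi2_zero(self):
        sp, onsets = self.speed_with_onsets({
            "entrained": [True] * 10 + [False] * 10,
            "control": [True] * 10 + [False] * 10,
        })
        res = loco.run_initiation_contingency(sp, onsets)
        assert res.counts.tolist() == [[10, 10], [10, 10]]
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        sp, onsets = self.speed_with_onsets({
            "entrained": [True] * 20,
            "control": [False] * 20,
        })
        res = loco.run_initiation_contingency(sp, onsets)
        assert res.chi2 == pytest.approx(40.0)
        assert res.p < 1e-9
        assert res.df == 1

    def test_onset_without_preceding_immobility_dropped(self):
        sp, onsets = self.speed_with_onsets({
            "entrained": [True] * 5,
            "control": [False] * 5,
        })
        # an extra onset in the middle of a running bout must be dropped
        onsets["entrained"] = list(onsets["entrained"]) + [30.0]
        res = loco.run_initiation_contingency(sp, onsets)
        assert res.counts.sum() == 10


class TestFrequencySpeedCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        eps = make_epochs(10)
        for m in eps:
            m.speed_mean_cm_s = 5.0 + m.epoch_id
            m.theta_freq_hz = 6.0 + 0.3 * m.epoch_id
        r, p = loco.frequency_speed_correlation(eps, "spontaneous")
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_too_few_epochs_rejected(self):
        eps = make_epochs(4)
        for m in eps:
            m.speed_mean_cm_s = 5.0
            m.theta_freq_hz = 8.0
        with pytest.raises(ValueError, match=">= 5"):
            loco.frequency_speed_correlation(eps, "spontaneous")


class TestAmplitudeVariabilityProfile:
    @staticmethod
    def epochs_with(cv_to_speed_cv, n=80, rng=None):
        rng = np.random.default_rng(1) if rng is None else rng
        eps = make_epochs(n)
        for m in eps:
            c = rng.uniform(0.05, 0.5)
            m.theta_amp_cv = c
            m.speed_cv = cv_to_speed_cv(c)
            m.speed_mean_cm_s = 8.0
        return eps

    def test_exact_quadratic_recovered(self):
        eps = self.epochs_with(lambda c: 0.1 + 0.5 * c + 0.8 * c * c)
        prof = loco.amplitude_variability_profile(eps)
        assert prof.r2_speed_cv > 0.99

    def test_single_bin_refused(self):
        eps = self.epochs_with(lambda c: 0.3)
        for m in eps:
            m.theta_amp_cv = 0.2  # all mass in one bin
        with pytest.raises(ValueError, match="fewer than 3"):
            loco.amplitude_variability_profile(eps)

    def test_too_few_epochs_rejected(self):
        eps = self.epochs_with(lambda c: 0.3, n=10)
        with pytest.raises(ValueError, match=">= 20"):
            loco.amplitude_variability_profile(eps)
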