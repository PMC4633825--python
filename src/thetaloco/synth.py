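"""Synthetic session generator.

Emulates the statistical structure the analysis pipeline assumes, so every
downstream stage can be tested against known ground truth:

* spontaneous theta: an oscillation cos(phi(t)) * A(t) whose instantaneous
  frequency follows an AR(1) process around a 5–12 Hz centre (CV
  ``freq_cv``) and whose envelope A(t) is a log-normal AR(1) with CV
  ``amp_cv`` — both stepped once per theta cycle;
* optogenetic entrainment: the cycle clock is pulled onto the laser-pulse
  phase ramp with weight ``entrain_gain`` (1 = frequency pinned to the
  pulses), and envelope variability shrinks by the same factor — higher
  gain therefore yields higher measured entrainment fidelity and a lower
  amplitude CV;
* gamma: 35–85 Hz band-limited noise whose amplitude is modulated by theta
  phase with depth ``gamma_coupling``;
* spikes: per-cycle Poisson counts whose mean scales with normalized cycle
  amplitude (slope ``amp_rate_slope``), phases von Mises around a preferred
  theta phase (concentration ``spike_kappa``);
* locomotion: a smoothed reflective random walk in the 48 × 30 cm arena
  whose per-epoch mean speed and speed CV increase with the concurrent
  theta-amplitude CV (gain ``speed_amp_cv_gain``), plus a spontaneous
  theta-frequency ↔ speed coupling (``freq_speed_gain``) so that only
  non-entrained epochs show a frequency–speed correlation.

Everything is driven by one seed through ``numpy.random.SeedSequence``
spawning, so a fixed config reproduces a session bit-for-bit.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import LfpTrace, PositionTrack, PulseTrain, SpikeTrain
from .theta import ThetaCycleTable, bandpass

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "SessionBundle",
    "generate_pulse_train",
    "generate_theta_lfp",
    "generate_entrained_lfp",
    "generate_spike_train",
    "generate_position_track",
    "generate_session",
    "truth_cycle_table",
]

ARENA_CM = (48.0, 30.0)
EPOCH_S = 10.0
STIM_FREQ_SET = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)   # the stimulation protocol set
AR1_RHO_CYCLE = 0.7        # cycle-to-cycle persistence of freq/amp processes
AR1_RHO_SPEED = 0.97       # frame-to-frame persistence of the speed process
HEADING_STEP_SD = 0.12     # rad/frame heading diffusion of the random walk
AR1_RHO_EPOCH = 0.5        # epoch-to-epoch persistence of amplitude regularity
EPOCH_CV_SPREAD = 0.4      # log-sd of the between-epoch amplitude-CV modulation


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a synthetic session.

    Units: durations s, rates Hz, amplitudes V, speeds cm/s; CVs and gains
    unitless.  ``entrain_gain`` and ``gamma_coupling`` live in [0, 1].
    """

    seed: int = 0
    duration_s: float = 300.0
    lfp_rate_hz: float = 1250.0
    theta_freq_hz: float = 8.0
    freq_cv: float = 0.05
    amp_cv: float = 0.3
    gamma_coupling: float = 0.5
    entrain_gain: float = 0.8
    spike_kappa: float = 1.0
    amp_rate_slope: float = 0.5
    speed_base_cm_s: float = 8.0
    speed_amp_cv_gain: float = 1.0
    noise_sd: float = 0.05
    # --- secondary knobs ---
    theta_amp_v: float = 1.0          # mean theta envelope
    gamma_amp_frac: float = 0.15      # gamma carrier amplitude / theta amplitude
    speed_cv_base: float = 0.15       # speed CV floor at zero amplitude-CV coupling
    freq_speed_gain: float = 0.3      # spontaneous theta-freq per relative speed
    stim_freq_hz: float = 8.0         # session stimulation frequency
    pulse_ms: float = 30.0
    segment_s: float = 60.0           # length of each condition block

    def validate(self) -> "GeneratorConfig":
        if self.duration_s <= 0 or self.lfp_rate_hz <= 0:
            raise ValueError("duration and LFP rate must be positive")
        if not (5.0 <= self.theta_freq_hz <= 12.0):
            raise ValueError("theta frequency must lie in [5, 12] Hz")
        for name in ("freq_cv", "amp_cv", "noise_sd", "speed_cv_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("entrain_gain", "gamma_coupling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.segment_s % EPOCH_S != 0:
            raise ValueError("segment length must be a multiple of 10 s")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionBundle:
    """One synthetic session: aligned LFP, spikes, pulses, tracking, labels.

    All time axes share one clock starting at 0.  ``condition_labels`` has
    one row per 10-s epoch (epoch_id, t_start_s, t_end_s, condition), with
    condition in {spontaneous, entrained@<f>Hz, control-light}.  ``truth``
    retains the generating config.
    """

    lfp: LfpTrace
    spikes: list[SpikeTrain]
    pulses: PulseTrain
    track: PositionTrack
    condition_labels: pd.DataFrame
    truth: GeneratorConfig
    truth_cycles: ThetaCycleTable | None = None


# ---------------------------------------------------------------------------
# pulse trains


def generate_pulse_train(freq_hz: float, pulse_ms: float, duration_s: float,
                         start_s: float = 0.0) -> PulseTrain:
    """Strictly periodic pulse onsets at 1/freq from ``start_s``.

    The protocol's frequency set is 2–12 Hz with 30-ms pulses; any
    combination with duty cycle < 1 is accepted.
    """
    if freq_hz <= 0 or duration_s <= 0:
        raise ValueError("frequency and duration must be positive")
    if freq_hz * pulse_ms / 1000.0 >= 1.0:
        raise ValueError(
            f"duty cycle {freq_hz * pulse_ms / 1000.0:.2f} >= 1: pulses overlap")
    n = int(math.ceil(duration_s * freq_hz - 1e-9))
    onsets = start_s + np.arange(n) / freq_hz
    return PulseTrain(onsets, pulse_ms)


# ---------------------------------------------------------------------------
# cycle-clock generation


def _gen_cycles(rng: np.random.Generator, duration_s: float,
                f0_of_t, cv_of_t, amp_mean: float, freq_cv: float,
                gain_of_t=None, grid_start: float = 0.0,
                stim_freq: float | None = None,
                rho: float = AR1_RHO_CYCLE,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate theta peak times, per-cycle amplitudes and frequencies.

    ``f0_of_t``/``cv_of_t``/``gain_of_t`` are callables t -> value, letting
    the session generator vary the centre frequency, envelope CV and
    entrainment gain per epoch.  The entrained clock blends the stochastic
    next-peak time with the nearest point of the pulse phase ramp with
    weight gain; the envelope is shrunk toward its mean by the same factor.
    """
    innov = math.sqrt(1.0 - rho * rho)
    zf = rng.standard_normal()
    za = rng.standard_normal()
    t = 0.0
    peaks, amps, freqs = [], [], []
    while t < duration_s:
        zf = rho * zf + innov * rng.standard_normal()
        za = rho * za + innov * rng.standard_normal()
        f0 = float(f0_of_t(t))
        cv = float(cv_of_t(t))
        f_int = f0 * (1.0 + freq_cv * zf)
        f_int = min(max(f_int, 4.5), 13.5)
        sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
        amp = math.exp(math.log(amp_mean) - 0.5 * sigma * sigma + sigma * za)
        g = float(gain_of_t(t)) if gain_of_t is not None else 0.0
        if g > 0.0 and stim_freq is not None:
            f_eff = g * stim_freq + (1.0 - g) * f_int
            t_free = t + 1.0 / f_eff
            k = round((t_free - grid_start) * stim_freq)
            t_grid = grid_start + k / stim_freq
            if t_grid <= t:
                t_grid += 1.0 / stim_freq
            t_next = t_free + g * (t_grid - t_free)
            if t_next <= t:
                t_next = t + 1.0 / f_eff
            amp = amp_mean + (1.0 - g) * (amp - amp_mean)
        else:
            t_next = t + 1.0 / f_int
        peaks.append(t)
        amps.append(amp)
        freqs.append(1.0 / (t_next - t))
        t = t_next
    return np.asarray(peaks), np.asarray(amps), np.asarray(freqs)


def _synth_trace(cfg: GeneratorConfig, rng: np.random.Generator,
                 peak_t: np.ndarray, amps: np.ndarray) -> LfpTrace:
    """Theta + phase-coupled gamma + broadband noise on the LFP grid."""
    n = int(round(cfg.duration_s * cfg.lfp_rate_hz))
    t = np.arange(n) / cfg.lfp_rate_hz
    cyc_idx = np.interp(t, peak_t, np.arange(peak_t.size))
    phi = 2.0 * math.pi * cyc_idx
    env = np.interp(t, peak_t, amps)
    theta = env * np.cos(phi)
    carrier = rng.standard_normal(n)
    carrier = bandpass(carrier, cfg.lfp_rate_hz, 35.0, 85.0)
    sd = carrier.std()
    if sd > 0:
        carrier /= sd
    gamma_env = cfg.gamma_amp_frac * cfg.theta_amp_v * (
        1.0 + cfg.gamma_coupling * np.cos(phi))
    x = theta + gamma_env * carrier
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, n)
    return LfpTrace(x, cfg.lfp_rate_hz)


def generate_theta_lfp(cfg: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> LfpTrace:
    """Spontaneous-theta LFP: stochastic cycle clock, no entrainment."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    peaks, amps, _ = _gen_cycles(
        rng, cfg.duration_s,
        f0_of_t=lambda t: cfg.theta_freq_hz,
        cv_of_t=lambda t: cfg.amp_cv,
        amp_mean=cfg.theta_amp_v, freq_cv=cfg.freq_cv)
    return _synth_trace(cfg, rng, peaks, amps)


def generate_entrained_lfp(cfg: GeneratorConfig, pulses: PulseTrain,
                           rng: np.random.Generator | None = None) -> LfpTrace:
    """LFP whose cycle clock is pulled onto the pulse train.

    With ``entrain_gain`` = 0 the output is statistically identical to
    :func:`generate_theta_lfp`; with gain 1 the oscillation frequency
    equals the pulse frequency exactly.  The blend applies only while
    pulses are being delivered.
    """
    cfg.validate()
    if pulses.n_pulses and pulses.onset_t[-1] > cfg.duration_s:
        raise ValueError("pulse train extends beyond the session duration")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if pulses.n_pulses >= 2:
        stim_freq = 1.0 / float(np.median(np.diff(pulses.onset_t)))
        t0, t1 = float(pulses.onset_t[0]), float(pulses.onset_t[-1]) + 1.0 / stim_freq
        gain = lambda t: cfg.entrain_gain if t0 <= t < t1 else 0.0  # noqa: E731
        grid_start = t0
    else:
        stim_freq, gain, grid_start = None, None, 0.0
    peaks, amps, _ = _gen_cycles(
        rng, cfg.duration_s,
        f0_of_t=lambda t: cfg.theta_freq_hz,
        cv_of_t=lambda t: cfg.amp_cv,
        amp_mean=cfg.theta_amp_v, freq_cv=cfg.freq_cv,
        gain_of_t=gain, grid_start=grid_start, stim_freq=stim_freq)
    return _synth_trace(cfg, rng, peaks, amps)


def truth_cycle_table(peak_t: np.ndarray, amps: np.ndarray) -> ThetaCycleTable:
    """Cycle table from generated peak times (troughs at mid-cycle)."""
    if peak_t.size < 2:
        raise ValueError("need at least 2 peaks")
    p0, p1 = peak_t[:-1], peak_t[1:]
    return ThetaCycleTable(p0, 0.5 * (p0 + p1), p1, amps[:-1],
                           1.0 / (p1 - p0))


# ---------------------------------------------------------------------------
# spikes


def generate_spike_train(cycles: ThetaCycleTable, preferred_phase_deg: float,
                         spike_kappa: float, base_rate_hz: float,
                         amp_rate_slope: float,
                         rng: np.random.Generator | None = None,
                         unit_id: int = 0,
                         burst_prob: float = 0.0) -> SpikeTrain:
    """Theta-locked spikes with amplitude-coupled per-cycle counts.

    Per cycle the spike count is Poisson with mean
    (base_rate / cycle_freq) * (1 + amp_rate_slope * a), where a is the
    cycle amplitude normalized to zero mean (A/mean(A) - 1); negative means
    are clamped to 0 (logged).  Spike phases are von Mises about the
    preferred phase (kappa = 0 -> uniform; kappa = inf -> delta) and mapped
    to times with the piecewise-linear peak->trough->peak convention.
    ``burst_prob`` optionally appends a short-latency (4–8 ms) companion
    spike, giving pyramidal-like bursty autocorrelograms.
    """
    if cycles.n_cycles == 0:
        raise ValueError("empty cycle table")
    rng = np.random.default_rng() if rng is None else rng
    a_norm = cycles.amplitude / cycles.amplitude.mean() - 1.0
    mean_counts = (base_rate_hz / cycles.freq_hz) * (
        1.0 + amp_rate_slope * a_norm)
    n_clamped = int(np.sum(mean_counts < 0))
    if n_clamped:
        logger.warning("%d cycles with negative expected count clamped to 0",
                       n_clamped)
    mean_counts = np.maximum(mean_counts, 0.0)
    counts = rng.poisson(mean_counts)
    times = []
    mu_rad = math.radians(preferred_phase_deg)
    for k in np.nonzero(counts)[0]:
        c = counts[k]
        if math.isinf(spike_kappa):
            ph = np.full(c, preferred_phase_deg)
        elif spike_kappa <= 0:
            ph = rng.uniform(0.0, 360.0, c)
        else:
            ph = np.degrees(rng.vonmises(mu_rad, spike_kappa, c)) % 360.0
        pk, tr, npk = cycles.peak_t[k], cycles.trough_t[k], cycles.next_peak_t[k]
        t_sp = np.where(
            ph < 180.0,
            pk + (ph / 180.0) * (tr - pk),
            tr + ((ph - 180.0) / 180.0) * (npk - tr),
        )
        times.append(t_sp)
    t_all = np.concatenate(times) if times else np.empty(0)
    if burst_prob > 0 and t_all.size:
        extra = t_all[rng.random(t_all.size) < burst_prob]
        t_all = np.concatenate([t_all, extra + rng.uniform(0.004, 0.008,
                                                           extra.size)])
    return SpikeTrain(unit_id, np.sort(t_all))


# ---------------------------------------------------------------------------
# locomotion


def generate_position_track(cfg: GeneratorConfig,
                            lfp_envelope_cv_series: np.ndarray,
                            rng: np.random.Generator | None = None,
                            ) -> PositionTrack:
    """Reflective smoothed random walk in the 48 × 30 cm arena at 25 Hz.

    ``lfp_envelope_cv_series`` gives the theta-amplitude CV of each 10-s
    epoch.  Per epoch, the target mean speed and speed CV both rise with
    that CV through ``speed_amp_cv_gain`` (centred on the series mean so
    the session-average speed stays at ``speed_base_cm_s``); the speed
    magnitude is a log-normal AR(1) at frame resolution, the heading a
    wrapped random walk with reflection at the walls.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    cvs = np.asarray(lfp_envelope_cv_series, dtype=float)
    rate = 25.0
    n_frames = int(round(cfg.duration_s * rate))
    c_ref = float(cvs.mean()) if cvs.size else 0.0
    innov = math.sqrt(1.0 - AR1_RHO_SPEED**2)
    z = rng.standard_normal()
    x, y = ARENA_CM[0] / 2.0, ARENA_CM[1] / 2.0
    heading = rng.uniform(0, 2 * math.pi)
    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    for i in range(n_frames):
        epoch = min(int(i / rate // EPOCH_S), max(cvs.size - 1, 0))
        c_e = cvs[epoch] if cvs.size else 0.0
        mu = cfg.speed_base_cm_s * max(
            1.0 + cfg.speed_amp_cv_gain * (c_e - c_ref), 0.1)
        cv_speed = cfg.speed_cv_base + cfg.speed_amp_cv_gain * c_e
        z = AR1_RHO_SPEED * z + innov * rng.standard_normal()
        sigma = math.sqrt(math.log(1.0 + cv_speed**2)) if cv_speed > 0 else 0.0
        s = math.exp(math.log(mu) - 0.5 * sigma * sigma + sigma * z)
        heading += rng.normal(0.0, HEADING_STEP_SD)
        x += s / rate * math.cos(heading)
        y += s / rate * math.sin(heading)
        # reflective walls
        if x < 0.5:
            x = 1.0 - x
            heading = math.pi - heading
        elif x > ARENA_CM[0] - 0.5:
            x = 2 * (ARENA_CM[0] - 0.5) - x
            heading = math.pi - heading
        if y < 0.5:
            y = 1.0 - y
            heading = -heading
        elif y > ARENA_CM[1] - 0.5:
            y = 2 * (ARENA_CM[1] - 0.5) - y
            heading = -heading
        xs[i] = x
        ys[i] = y
    t = np.arange(n_frames) / rate
    return PositionTrack(t, xs, ys)


# ---------------------------------------------------------------------------
# whole sessions


def _condition_schedule(cfg: GeneratorConfig) -> list[str]:
    """Condition label per 10-s epoch: blocks cycling through the three
    conditions, ``segment_s`` long each."""
    n_epochs = int(cfg.duration_s // EPOCH_S)
    per_seg = int(cfg.segment_s // EPOCH_S)
    order = ["spontaneous", f"entrained@{cfg.stim_freq_hz:g}Hz", "control-light"]
    labels = []
    for e in range(n_epochs):
        labels.append(order[(e // per_seg) % len(order)])
    return labels


def generate_session(cfg: GeneratorConfig) -> SessionBundle:
    """A full session alternating spontaneous, entrained and control-light
    blocks, with spikes, pulses, tracking and per-epoch truth labels.

    The generative chain per epoch e: amplitude-regularity target c_e
    (epoch-level log-AR(1) around ``amp_cv``, shrunk by (1 − entrain_gain)
    in entrained epochs) → target mean speed and speed CV (via
    ``speed_amp_cv_gain``) → spontaneous-theta centre frequency (via
    ``freq_speed_gain``).  Entrained epochs' cycle clocks are pulled onto
    the pulse ramp instead, so their frequency carries no speed signal.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_epoch, rng_lfp, rng_spk, rng_trk = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    labels = _condition_schedule(cfg)
    n_epochs = len(labels)
    entrained = np.array([lab.startswith("entrained") for lab in labels])
    pulsed = np.array([lab != "spontaneous" for lab in labels])

    # epoch-level amplitude-regularity targets
    innov = math.sqrt(1.0 - AR1_RHO_EPOCH**2)
    u = np.empty(n_epochs)
    z = rng_epoch.standard_normal()
    for e in range(n_epochs):
        z = AR1_RHO_EPOCH * z + innov * rng_epoch.standard_normal()
        u[e] = z
    c_epoch = cfg.amp_cv * np.exp(EPOCH_CV_SPREAD * u - EPOCH_CV_SPREAD**2 / 2)
    c_epoch[entrained] *= (1.0 - cfg.entrain_gain)

    # locomotion targets and spontaneous frequency coupling
    c_ref = float(c_epoch.mean())
    mu_epoch = cfg.speed_base_cm_s * np.maximum(
        1.0 + cfg.speed_amp_cv_gain * (c_epoch - c_ref), 0.1)
    f_epoch = cfg.theta_freq_hz * (
        1.0 + cfg.freq_speed_gain * (mu_epoch / cfg.speed_base_cm_s - 1.0))
    f_epoch = np.clip(f_epoch, 5.0, 12.0)
    f_epoch[entrained] = cfg.theta_freq_hz

    def epoch_of(t: float) -> int:
        return min(int(t // EPOCH_S), n_epochs - 1)

    peaks, amps, _ = _gen_cycles(
        rng_lfp, cfg.duration_s,
        f0_of_t=lambda t: f_epoch[epoch_of(t)],
        cv_of_t=lambda t: c_epoch[epoch_of(t)],
        amp_mean=cfg.theta_amp_v, freq_cv=cfg.freq_cv,
        gain_of_t=lambda t: cfg.entrain_gain if entrained[epoch_of(t)] else 0.0,
        grid_start=0.0, stim_freq=cfg.stim_freq_hz)
    lfp = _synth_trace(cfg, rng_lfp, peaks, amps)
    cycles = truth_cycle_table(peaks, amps)

    # pulses inside entrained and control-light epochs only
    onsets = []
    for e in range(n_epochs):
        if pulsed[e]:
            tr = generate_pulse_train(cfg.stim_freq_hz, cfg.pulse_ms,
                                      EPOCH_S, start_s=e * EPOCH_S)
            onsets.append(tr.onset_t)
    pulses = PulseTrain(np.concatenate(onsets) if onsets else np.empty(0),
                        cfg.pulse_ms)

    # units: 4 pyramidal-like (bursty, amplitude-coupled) + 2 fast-firing
    spikes = []
    pyram = [(0, 0.0, 1.2), (1, 30.0, 1.8), (2, 180.0, 2.4), (3, 210.0, 1.5)]
    for uid, pref, rate in pyram:
        spikes.append(generate_spike_train(
            cycles, pref, cfg.spike_kappa, rate, cfg.amp_rate_slope,
            rng=rng_spk, unit_id=uid, burst_prob=0.25))
    for uid, pref, rate in [(4, 120.0, 15.0), (5, 300.0, 20.0)]:
        spikes.append(generate_spike_train(
            cycles, pref, 0.3 * cfg.spike_kappa, rate, 0.0,
            rng=rng_spk, unit_id=uid))

    track = generate_position_track(cfg, c_epoch, rng=rng_trk)

    cond = pd.DataFrame({
        "epoch_id": np.arange(n_epochs),
        "t_start_s": np.arange(n_epochs) * EPOCH_S,
        "t_end_s": (np.arange(n_epochs) + 1) * EPOCH_S,
        "condition": labels,
    })
    return SessionBundle(lfp, spikes, pulses, track, cond, cfg,
                         truth_cycles=cycles)
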