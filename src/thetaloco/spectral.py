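"""Epoch-wise spectral analysis of the LFP.

Implements the multitaper power spectral density used throughout (Slepian
tapers, time-halfbandwidth product 3, window 8,192 samples), the optogenetic
entrainment-fidelity statistic — the fraction of 5–12 Hz power concentrated
within ±0.5 Hz of the stimulation frequency — the theta/delta power-ratio
gate, the epoch inclusion rules, and two-signal magnitude-squared coherence.

Band conventions (volts², Hz):
    delta 1–4 Hz (the ratio's denominator band; the literature varies, this
    package fixes 1–4), theta 5–10 Hz for the theta/delta ratio (matching
    the Hilbert filtering band) and 5–12 Hz for the fidelity denominator.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

from .io import LfpTrace, PulseTrain

logger = logging.getLogger(__name__)

__all__ = [
    "PowerSpectrum",
    "EpochMetrics",
    "CoherenceSpectrum",
    "compute_psd",
    "multitaper_psd",
    "band_power",
    "entrainment_fidelity",
    "theta_delta_ratio",
    "dominant_frequency",
    "select_epochs",
    "lfp_coherence",
    "EPOCH_S",
    "REASON_DOMINANT_LE_5HZ",
    "REASON_LOW_FIDELITY",
    "REASON_LOW_THETA_DELTA",
    "REASON_NO_THETA_POWER",
]

EPOCH_S = 10.0
WINDOW_SAMPLES = 8192
NW = 3.0
FIDELITY_HALFWIDTH_HZ = 0.5
FIDELITY_BAND = (5.0, 12.0)
THETA_BAND = (5.0, 10.0)
DELTA_BAND = (1.0, 4.0)
DOMINANT_SEARCH_BAND = (1.0, 20.0)
FIDELITY_MIN = 0.3
THETA_DELTA_MIN = 6.0

REASON_DOMINANT_LE_5HZ = "dominant_peak_le_5hz"
REASON_LOW_FIDELITY = "fidelity_below_0.3"
REASON_LOW_THETA_DELTA = "theta_delta_ratio_below_6"
REASON_NO_THETA_POWER = "no_theta_band_power"


@dataclass
class PowerSpectrum:
    freqs: np.ndarray          # Hz, 0 .. Nyquist, strictly increasing
    power: np.ndarray          # V^2/Hz, one-sided
    epoch_id: int = -1
    params: dict = field(default_factory=dict)


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    coherence: np.ndarray      # in [0, 1]


@dataclass
class EpochMetrics:
    """One 10-s epoch of the session, with every gate's outcome recorded.

    LFP-derived fields are filled by :func:`select_epochs`; the theta-cycle
    and locomotion fields by the theta_phase and locomotion modules.
    ``included`` is False iff a hard exclusion rule fired; ``pac_eligible``
    additionally requires theta/delta >= 6.  ``reasons`` is the
    machine-readable list of every rule that fired.
    """

    epoch_id: int
    t_start_s: float
    t_end_s: float
    condition: str = "spontaneous"
    stim_freq_hz: float = math.nan
    fidelity: float = math.nan
    dominant_freq_hz: float = math.nan
    theta_freq_hz: float = math.nan   # mean detected-cycle frequency (finer
                                      # than the PSD-grid dominant peak)
    theta_delta_ratio: float = math.nan
    theta_amp_mean: float = math.nan
    theta_amp_cv: float = math.nan
    speed_mean_cm_s: float = math.nan
    speed_cv: float = math.nan
    frac_running: float = math.nan
    run_duration_s: float = math.nan
    path_length_cm: float = math.nan
    included: bool = True
    pac_eligible: bool = True
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# multitaper machinery


def _taper_bank(n: int, nw: float = NW) -> np.ndarray:
    """Unit-energy Slepian tapers; K = 2*NW - 1 tapers (the usual choice)."""
    k = int(2 * nw - 1)
    tapers = dpss(n, nw, Kmax=k)
    return tapers


def multitaper_psd(
    x: np.ndarray,
    rate_hz: float,
    window: int = WINDOW_SAMPLES,
    nw: float = NW,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided multitaper PSD averaged over overlapping windows.

    Returns (freqs, power).  Power is scaled so that the trapezoidal
    integral over frequency approximates the signal variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    if x.size < window:
        raise ValueError(
            f"signal of {x.size} samples shorter than the required window of "
            f"{window} samples ({window / rate_hz:.2f} s at {rate_hz:g} Hz)"
        )
    tapers = _taper_bank(window, nw)
    step = max(1, int(window * (1.0 - overlap)))
    starts = range(0, x.size - window + 1, step)
    freqs = np.fft.rfftfreq(window, d=1.0 / rate_hz)
    acc = np.zeros(freqs.size)
    n_seg = 0
    for s in starts:
        seg = x[s : s + window]
        spec = np.fft.rfft(tapers * seg[None, :], axis=1)
        p = (np.abs(spec) ** 2).mean(axis=0) / rate_hz
        p[1:] *= 2.0
        if window % 2 == 0:
            p[-1] /= 2.0
        acc += p
        n_seg += 1
    return freqs, acc / n_seg


def compute_psd(
    trace: LfpTrace, t_start: float, t_end: float, epoch_id: int = -1
) -> PowerSpectrum:
    """Multitaper PSD of one epoch (the paper-style 10-s epoch)."""
    seg = trace.slice(t_start, t_end)
    freqs, power = multitaper_psd(seg.data, trace.rate_hz)
    return PowerSpectrum(
        freqs,
        power,
        epoch_id=epoch_id,
        params={
            "nw": NW,
            "window": WINDOW_SAMPLES,
            "rate_hz": trace.rate_hz,
            "t_start_s": t_start,
            "t_end_s": t_end,
        },
    )


def band_power(
    freqs: np.ndarray, power: np.ndarray, lo: float, hi: float
) -> float:
    """Trapezoidal integral of power over [lo, hi] Hz.

    Band edges rarely fall on the frequency grid; the integrand is linearly
    interpolated at the edges so that flat spectra integrate to exactly
    (hi - lo) * level regardless of grid alignment.
    """
    if hi <= lo:
        return 0.0
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = (freqs > lo) & (freqs < hi)
    f = np.concatenate(([lo], freqs[inner], [hi]))
    p = np.concatenate(
        ([np.interp(lo, freqs, power)], power[inner], [np.interp(hi, freqs, power)])
    )
    return float(np.trapezoid(p, f))


# ---------------------------------------------------------------------------
# the entrainment-fidelity statistic and gates


def entrainment_fidelity(psd: PowerSpectrum, stim_freq_hz: float) -> float:
    """Fraction of 5–12 Hz power within ±0.5 Hz of the stimulation frequency.

    The numerator band is intersected with [5, 12] Hz, so the ratio is in
    [0, 1] by construction.  NaN (with a log record) when the 5–12 Hz band
    carries no power at all — the epoch is then unusable.
    """
    if not (FIDELITY_BAND[0] <= stim_freq_hz <= FIDELITY_BAND[1]):
        raise ValueError(
            f"stimulation frequency {stim_freq_hz} Hz outside the theta band "
            f"{FIDELITY_BAND} over which fidelity is defined"
        )
    denom = band_power(psd.freqs, psd.power, *FIDELITY_BAND)
    if denom <= 0:
        logger.warning("epoch %d: no 5-12 Hz power, fidelity undefined",
                       psd.epoch_id)
        return math.nan
    lo = max(stim_freq_hz - FIDELITY_HALFWIDTH_HZ, FIDELITY_BAND[0])
    hi = min(stim_freq_hz + FIDELITY_HALFWIDTH_HZ, FIDELITY_BAND[1])
    num = band_power(psd.freqs, psd.power, lo, hi)
    return min(num / denom, 1.0)


def theta_delta_ratio(psd: PowerSpectrum) -> float:
    """Theta (5–10 Hz) over delta (1–4 Hz) integrated power.

    +inf when the delta band is exactly empty (the >= 6 gate then passes).
    """
    theta = band_power(psd.freqs, psd.power, *THETA_BAND)
    delta = band_power(psd.freqs, psd.power, *DELTA_BAND)
    if delta <= 0:
        return math.inf
    return theta / delta


def dominant_frequency(psd: PowerSpectrum,
                       band: tuple[float, float] = DOMINANT_SEARCH_BAND) -> float:
    """Frequency of the PSD maximum within ``band`` (default 1–20 Hz)."""
    sel = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not np.any(sel):
        return math.nan
    idx = int(np.argmax(psd.power[sel]))
    return float(psd.freqs[sel][idx])


def _stim_freq_in_epoch(
    pulses: PulseTrain | None, t0: float, t1: float
) -> float:
    """Median pulse rate of onsets inside [t0, t1); NaN when < 3 pulses."""
    if pulses is None or pulses.n_pulses < 3:
        return math.nan
    sel = (pulses.onset_t >= t0) & (pulses.onset_t < t1)
    if sel.sum() < 3:
        return math.nan
    ioi = np.diff(pulses.onset_t[sel])
    return 1.0 / float(np.median(ioi))


def select_epochs(
    trace: LfpTrace,
    pulses: PulseTrain | None = None,
    stim_freq_hz: float | None = None,
    conditions: list[str] | None = None,
) -> list[EpochMetrics]:
    """Cut the trace into consecutive 10-s epochs and apply the gates.

    Per epoch: multitaper PSD, dominant frequency over 1–20 Hz, theta/delta
    ratio, and — for epochs carrying theta-band stimulation — entrainment
    fidelity.  Exclusion rules: dominant peak <= 5 Hz; stimulation epoch with
    fidelity < 0.3.  Theta/delta < 6 leaves the epoch included but PAC-
    ineligible.  A session where no epoch survives raises, never returns an
    empty success.

    ``stim_freq_hz`` is the session's reference stimulation frequency: when
    given, fidelity is computed for every epoch against it (as in the
    protocol's control recordings), but the fidelity < 0.3 gate still fires
    only for epochs actually carrying theta-band pulses (and never for
    control-light epochs, whose light cannot entrain).  ``conditions``
    optionally labels epochs (one label per epoch).
    """
    n_epochs = int(trace.duration_s // EPOCH_S)
    if n_epochs < 1:
        raise ValueError(
            f"trace of {trace.duration_s:.1f} s shorter than one "
            f"{EPOCH_S:.0f}-s epoch"
        )
    out: list[EpochMetrics] = []
    for e in range(n_epochs):
        t0, t1 = e * EPOCH_S, (e + 1) * EPOCH_S
        psd = compute_psd(trace, t0, t1, epoch_id=e)
        m = EpochMetrics(epoch_id=e, t_start_s=t0, t_end_s=t1)
        if conditions is not None:
            m.condition = conditions[e]
        m.dominant_freq_hz = dominant_frequency(psd)
        m.theta_delta_ratio = theta_delta_ratio(psd)
        f_pulse = _stim_freq_in_epoch(pulses, t0, t1)
        f_ref = f_pulse if math.isfinite(f_pulse) else (
            stim_freq_hz if stim_freq_hz is not None else math.nan)
        m.stim_freq_hz = f_pulse
        is_stim_epoch = (
            math.isfinite(f_pulse)
            and FIDELITY_BAND[0] <= f_pulse <= FIDELITY_BAND[1]
            and m.condition != "control-light"
        )
        if math.isfinite(f_ref) and FIDELITY_BAND[0] <= f_ref <= FIDELITY_BAND[1]:
            m.fidelity = entrainment_fidelity(psd, f_ref)
        if m.dominant_freq_hz <= 5.0:
            m.included = False
            m.reasons.append(REASON_DOMINANT_LE_5HZ)
        if is_stim_epoch:
            if math.isnan(m.fidelity):
                m.included = False
                m.reasons.append(REASON_NO_THETA_POWER)
            elif m.fidelity < FIDELITY_MIN:
                m.included = False
                m.reasons.append(REASON_LOW_FIDELITY)
        if m.theta_delta_ratio < THETA_DELTA_MIN:
            m.pac_eligible = False
            m.reasons.append(REASON_LOW_THETA_DELTA)
        m.pac_eligible = m.pac_eligible and m.included
        if not m.included:
            logger.warning("epoch %d excluded: %s", e, ",".join(m.reasons))
        out.append(m)
    if not any(m.included for m in out):
        raise RuntimeError(
            "no epoch survived the inclusion rules "
            f"({'; '.join(','.join(m.reasons) for m in out)})"
        )
    return out


# ---------------------------------------------------------------------------
# two-signal coherence


def lfp_coherence(
    a: LfpTrace,
    b: LfpTrace,
    window: int = WINDOW_SAMPLES,
    nw: float = NW,
    overlap: float = 0.5,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence via multitaper cross-spectra.

    Auto- and cross-spectra are averaged over tapers and over overlapping
    windows of the whole recording before forming |Sab|^2 / (Saa Sbb).
    """
    if a.n_samples != b.n_samples or a.rate_hz != b.rate_hz:
        raise ValueError("coherence requires equal length and sampling rate")
    x = np.asarray(a.data, dtype=float)
    y = np.asarray(b.data, dtype=float)
    if x.size < window:
        raise ValueError("signals shorter than one analysis window")
    tapers = _taper_bank(window, nw)
    step = max(1, int(window * (1.0 - overlap)))
    freqs = np.fft.rfftfreq(window, d=1.0 / a.rate_hz)
    sxx = np.zeros(freqs.size)
    syy = np.zeros(freqs.size)
    sxy = np.zeros(freqs.size, dtype=complex)
    for s in range(0, x.size - window + 1, step):
        fx = np.fft.rfft(tapers * x[s : s + window][None, :], axis=1)
        fy = np.fft.rfft(tapers * y[s : s + window][None, :], axis=1)
        sxx += (np.abs(fx) ** 2).sum(axis=0)
        syy += (np.abs(fy) ** 2).sum(axis=0)
        sxy += (fx * np.conj(fy)).sum(axis=0)
    denom = sxx * syy
    coh = np.zeros(freqs.size)
    ok = denom > 0
    coh[ok] = np.abs(sxy[ok]) ** 2 / denom[ok]
    return CoherenceSpectrum(freqs, np.clip(coh, 0.0, 1.0))
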