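"""Locomotion: speed from 25 Hz head tracking, epoch-wise running metrics,
the run-initiation contingency test, and the speed ↔ theta coupling
analyses (frequency–speed correlation; theta-amplitude-variability binning).

Running is speed > 2 cm/s throughout.  Raw frame-to-frame speed is
contaminated by rhythmic head movement, so it is zero-phase low-pass
filtered (4th order Butterworth, 2 Hz cutoff) before thresholding: the
cutoff sits well below the 5–12 Hz head-swing band while preserving
second-scale locomotor dynamics.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import butter, sosfiltfilt

from .io import PositionTrack
from .spectral import EpochMetrics

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedSeries",
    "ContingencyResult",
    "instantaneous_speed",
    "epoch_locomotion_metrics",
    "run_initiation_contingency",
    "frequency_speed_correlation",
    "amplitude_variability_profile",
    "RUNNING_THRESHOLD_CM_S",
]

RUNNING_THRESHOLD_CM_S = 2.0
SPEED_LP_CUTOFF_HZ = 2.0
SPEED_LP_ORDER = 4
RUN_SUSTAIN_S = 1.0           # "moved": > 2 cm/s sustained for >= 1 s
PRE_ONSET_IMMOBILE_S = 20.0
POST_ONSET_WINDOW_S = 15.0


@dataclass
class SpeedSeries:
    t: np.ndarray
    speed_cm_s: np.ndarray
    is_running: np.ndarray

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class ContingencyResult:
    """2×2 counts (condition × {Run, Imm.}) with the chi-square test."""

    counts: np.ndarray
    chi2: float
    df: int
    p: float
    low_expected_warning: bool = False


def instantaneous_speed(track: PositionTrack,
                        cutoff_hz: float = SPEED_LP_CUTOFF_HZ,
                        threshold: float = RUNNING_THRESHOLD_CM_S) -> SpeedSeries:
    """Euclidean frame displacement × frame rate, low-pass filtered.

    The velocity *components* are zero-phase low-pass filtered before
    taking the magnitude: rhythmic head swings (5–12 Hz) average out in the
    components, whereas filtering the rectified magnitude would leave their
    DC-shifted power in place.  Speed is assigned to the later frame of
    each displacement; the series is one sample shorter than the track.
    """
    if track.t.size < 2:
        raise ValueError("need at least 2 tracking samples")
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing tracking timestamps")
    vx = np.diff(track.x) / dt
    vy = np.diff(track.y) / dt
    rate = 1.0 / float(np.median(dt))
    if vx.size > 3 * (SPEED_LP_ORDER + 1):
        sos = butter(SPEED_LP_ORDER, cutoff_hz, btype="low", fs=rate,
                     output="sos")
        vx = sosfiltfilt(sos, vx)
        vy = sosfiltfilt(sos, vy)
    speed = np.hypot(vx, vy)
    return SpeedSeries(track.t[1:], speed, speed > threshold)


def _epoch_slice(speed: SpeedSeries, t0: float, t1: float) -> np.ndarray:
    return (speed.t >= t0) & (speed.t < t1)


def _longest_run_s(is_running: np.ndarray, rate_hz: float) -> float:
    best = cur = 0
    for flag in is_running:
        cur = cur + 1 if flag else 0
        best = max(best, cur)
    return best / rate_hz


def epoch_locomotion_metrics(speed: SpeedSeries,
                             epochs: list[EpochMetrics]) -> list[EpochMetrics]:
    """Fill the per-epoch locomotion fields, over running samples only.

    Mean speed and its CV use samples above the 2 cm/s threshold; the
    fraction of time running, longest continuous bout and running path
    length are also recorded.  Epochs with no running samples keep NaN
    locomotion fields and are flagged (but not excluded — the LFP gates own
    inclusion).
    """
    rate = speed.rate_hz
    for m in epochs:
        sel = _epoch_slice(speed, m.t_start_s, m.t_end_s)
        if not sel.any():
            m.reasons.append("no_tracking_samples")
            continue
        s = speed.speed_cm_s[sel]
        run = speed.is_running[sel]
        m.frac_running = float(run.mean())
        m.run_duration_s = _longest_run_s(run, rate)
        if not run.any():
            m.reasons.append("no_running_samples")
            logger.warning("epoch %d: no running samples", m.epoch_id)
            continue
        rs = s[run]
        m.speed_mean_cm_s = float(rs.mean())
        m.speed_cv = float(rs.std() / rs.mean()) if rs.mean() > 0 else math.nan
        m.path_length_cm = float(np.sum(rs) / rate)
    return epochs


def run_initiation_contingency(speed: SpeedSeries,
                               onsets_by_condition: dict[str, np.ndarray],
                               threshold: float = RUNNING_THRESHOLD_CM_S,
                               ) -> ContingencyResult:
    """Did stimulation from immobility trigger running?  2×2 chi-square.

    Each onset must be preceded by 20 s of immobility (onsets violating
    this are dropped with a log record).  An onset counts as "Run" when
    speed exceeds the threshold continuously for >= 1 s within the 15 s
    after onset, else "Imm.".  Chi-square with df = 1, no continuity
    correction; a warning flag is set when any expected cell count is < 5.
    """
    if len(onsets_by_condition) != 2:
        raise ValueError("contingency test expects exactly two conditions")
    rate = speed.rate_hz
    sustain = int(round(RUN_SUSTAIN_S * rate))
    counts = np.zeros((2, 2), dtype=int)
    for row, (cond, onsets) in enumerate(sorted(onsets_by_condition.items())):
        for onset in np.asarray(onsets, dtype=float):
            pre = _epoch_slice(speed, onset - PRE_ONSET_IMMOBILE_S, onset)
            if not pre.any() or np.mean(speed.is_running[pre]) > 0.1:
                logger.warning(
                    "%s onset at %.1f s dropped: not preceded by %.0f s of "
                    "immobility", cond, onset, PRE_ONSET_IMMOBILE_S)
                continue
            post = _epoch_slice(speed, onset, onset + POST_ONSET_WINDOW_S)
            moved = _longest_run_s(speed.speed_cm_s[post] > threshold,
                                   rate) >= RUN_SUSTAIN_S if post.any() else False
            counts[row, 0 if moved else 1] += 1
    total = counts.sum()
    if total == 0 or counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
        # degenerate margin: no association measurable
        return ContingencyResult(counts, 0.0, 1, 1.0,
                                 low_expected_warning=True)
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    low = bool((expected < 5).any())
    if low:
        logger.warning("chi-square expected cell count below 5")
    return ContingencyResult(counts, float(chi2), int(df), float(p),
                             low_expected_warning=low)


def frequency_speed_correlation(epochs: list[EpochMetrics],
                                condition: str) -> tuple[float, float]:
    """Pearson r (and two-sided p) of epoch theta frequency vs mean speed.

    Uses included epochs of the given condition with defined speed; needs
    at least 5 of them.  Frequency is the epoch's mean detected-cycle
    frequency where available (the PSD-grid dominant peak is quantized at
    ~0.15 Hz, which degenerates when stimulation pins the rhythm), falling
    back to the dominant peak otherwise.  The emulated contrast:
    spontaneous theta frequency tracks running speed, optogenetically
    pinned frequency does not.
    """
    sel = [m for m in epochs
           if m.condition == condition and m.included
           and math.isfinite(m.speed_mean_cm_s)
           and (math.isfinite(m.theta_freq_hz)
                or math.isfinite(m.dominant_freq_hz))]
    if len(sel) < 5:
        raise ValueError(
            f"frequency-speed correlation needs >= 5 epochs, got {len(sel)}")
    f = np.array([m.theta_freq_hz if math.isfinite(m.theta_freq_hz)
                  else m.dominant_freq_hz for m in sel])
    s = np.array([m.speed_mean_cm_s for m in sel])
    if f.std() == 0 or s.std() == 0:
        logger.warning("zero variance in frequency or speed; r undefined")
        return math.nan, math.nan
    r, p = stats.pearsonr(f, s)
    return float(r), float(p)


@dataclass
class AmplitudeVariabilityProfile:
    """Epochs binned by theta-amplitude CV, with speed summaries per bin."""

    bin_centers: np.ndarray
    n_epochs: np.ndarray
    speed_mean: np.ndarray
    speed_sem: np.ndarray
    speed_cv_mean: np.ndarray
    speed_cv_sem: np.ndarray
    fit_coeffs_speed_cv: np.ndarray   # quadratic, highest power first
    r2_speed_cv: float
    fit_coeffs_speed: np.ndarray
    r2_speed: float
    dropped_bins: int


def _poly_r2(x: np.ndarray, y: np.ndarray, deg: int = 2
             ) -> tuple[np.ndarray, float]:
    coeffs = np.polyfit(x, y, deg)
    pred = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return coeffs, r2


def amplitude_variability_profile(epochs: list[EpochMetrics],
                                  n_bins: int = 8,
                                  min_epochs_per_bin: int = 3,
                                  ) -> AmplitudeVariabilityProfile:
    """Bin epochs by theta-amplitude CV; summarize speed and speed CV per bin.

    Fixed-width bins over the observed CV range; bins holding fewer than 3
    epochs are dropped from the quadratic fit.  Needs >= 20 usable epochs
    and >= 3 surviving bins.
    """
    sel = [m for m in epochs if m.included
           and math.isfinite(m.theta_amp_cv)
           and math.isfinite(m.speed_cv)
           and math.isfinite(m.speed_mean_cm_s)]
    if len(sel) < 20:
        raise ValueError(
            f"amplitude-variability profile needs >= 20 epochs, got {len(sel)}")
    cv = np.array([m.theta_amp_cv for m in sel])
    sp = np.array([m.speed_mean_cm_s for m in sel])
    scv = np.array([m.speed_cv for m in sel])
    edges = np.linspace(cv.min(), cv.max(), n_bins + 1)
    which = np.clip(np.digitize(cv, edges) - 1, 0, n_bins - 1)

    centers, ns = [], []
    sp_m, sp_se, scv_m, scv_se = [], [], [], []
    dropped = 0
    for b in range(n_bins):
        mask = which == b
        n = int(mask.sum())
        if n < min_epochs_per_bin:
            dropped += 1
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        ns.append(n)
        sp_m.append(float(sp[mask].mean()))
        sp_se.append(float(sp[mask].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0)
        scv_m.append(float(scv[mask].mean()))
        scv_se.append(float(scv[mask].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0)
    if len(centers) < 3:
        raise ValueError(
            "quadratic fit refused: fewer than 3 occupied amplitude-CV bins")
    centers = np.asarray(centers)
    c_cv, r2_cv = _poly_r2(centers, np.asarray(scv_m))
    c_sp, r2_sp = _poly_r2(centers, np.asarray(sp_m))
    return AmplitudeVariabilityProfile(
        centers, np.asarray(ns),
        np.asarray(sp_m), np.asarray(sp_se),
        np.asarray(scv_m), np.asarray(scv_se),
        c_cv, r2_cv, c_sp, r2_sp, dropped)
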