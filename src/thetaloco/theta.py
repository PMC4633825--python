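"""Theta cycle detection, phase extraction, and theta–gamma coupling.

Two phase definitions are provided and kept deliberately distinct:

* the *interpolated* phase — linear ramps between detected wave peaks and
  troughs of the 5–15 Hz band-passed signal (peak = 0°, trough = 180°);
* the *Hilbert* phase — analytic-signal angle of the 5–10 Hz band-passed
  signal, same convention.

They coincide on symmetric stationary oscillations and diverge on
asymmetric waves, which is exactly why both exist in the field.

Phase–amplitude coupling: gamma (35–85 Hz) oscillation peaks are local
maxima of the band-passed signal; each carries its theta phase and the
amplitude of the concurrent theta cycle.  The modulation coefficient of a
set of gamma peaks is (max − min)/(max + min) of the phase-binned mean
gamma peak amplitude — a scale-invariant depth measure in [0, 1].
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt

from .io import LfpTrace

logger = logging.getLogger(__name__)

__all__ = [
    "ThetaCycleTable",
    "PhaseSeries",
    "PacProfile",
    "bandpass",
    "detect_theta_cycles",
    "interpolated_phase",
    "hilbert_phase",
    "write_phase_series",
    "read_phase_series",
    "detect_gamma_peaks",
    "modulation_coefficient",
    "pac_profile",
    "pac_shuffle_null",
]

CYCLE_BAND = (5.0, 15.0)      # detection band; wide enough for 12 Hz entrainment
HILBERT_BAND = (5.0, 10.0)
GAMMA_BAND = (35.0, 85.0)
CYCLE_FREQ_ACCEPT = (4.0, 14.0)
PAC_PHASE_BINS = 18           # 20 deg bins
PAC_AMP_BINS = 5              # quantile bins
PAC_MIN_PEAKS = 50


def bandpass(x: np.ndarray, rate_hz: float, lo: float, hi: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    sos = butter(order, [lo, hi], btype="band", fs=rate_hz, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


@dataclass
class ThetaCycleTable:
    """Per-cycle anchors: a cycle runs peak -> trough -> next peak.

    amplitude is the band-passed value at the peak (the "amplitude of theta
    peaks" convention, not peak-to-trough); freq_hz the reciprocal of the
    peak-to-peak interval.
    """

    peak_t: np.ndarray
    trough_t: np.ndarray
    next_peak_t: np.ndarray
    amplitude: np.ndarray
    freq_hz: np.ndarray

    def __post_init__(self) -> None:
        for name in ("peak_t", "trough_t", "next_peak_t", "amplitude", "freq_hz"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.n_cycles:
            if not (np.all(self.peak_t < self.trough_t)
                    and np.all(self.trough_t < self.next_peak_t)):
                raise ValueError("cycle anchors must satisfy peak < trough < next peak")

    @property
    def n_cycles(self) -> int:
        return self.peak_t.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cycle_id": np.arange(self.n_cycles),
                "peak_t": self.peak_t,
                "trough_t": self.trough_t,
                "next_peak_t": self.next_peak_t,
                "amplitude": self.amplitude,
                "freq_hz": self.freq_hz,
            }
        )

    def amplitude_cv(self) -> float:
        if self.n_cycles < 2:
            return math.nan
        m = float(np.mean(self.amplitude))
        return float(np.std(self.amplitude) / m) if m > 0 else math.nan


@dataclass
class PhaseSeries:
    """Theta phase on the LFP time grid, degrees in [0, 360), NaN where
    undefined (outside detected cycles / filter edges)."""

    t: np.ndarray
    phase_deg: np.ndarray
    method: str = "interpolated"

    def at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary event times (nearest-sample lookup)."""
        rate = 1.0 / (self.t[1] - self.t[0])
        idx = np.round((np.asarray(times) - self.t[0]) * rate).astype(int)
        ok = (idx >= 0) & (idx < self.t.size)
        out = np.full(np.shape(times), np.nan)
        out[ok] = self.phase_deg[idx[ok]]
        return out


def write_phase_series(phase: PhaseSeries, path) -> None:
    """Store a phase series as a little-endian float32 stream (degrees,
    NaN where undefined) with a JSON sidecar next to it."""
    import json
    from pathlib import Path

    path = Path(path)
    phase.phase_deg.astype("<f4").tofile(path)
    rate = 1.0 / float(phase.t[1] - phase.t[0])
    path.with_suffix(".json").write_text(json.dumps({
        "rate_hz": rate, "t0_s": float(phase.t[0]),
        "n_samples": int(phase.t.size), "method": phase.method,
        "units": "degrees", "dtype": "float32-le",
    }, indent=1, sort_keys=True))


def read_phase_series(path) -> PhaseSeries:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    vals = np.fromfile(path, dtype="<f4").astype(float)
    if vals.size != int(meta["n_samples"]):
        raise ValueError(f"{path}: payload does not match sidecar")
    t = meta["t0_s"] + np.arange(vals.size) / float(meta["rate_hz"])
    return PhaseSeries(t, vals, method=meta.get("method", "interpolated"))


def detect_theta_cycles(trace: LfpTrace,
                        band: tuple[float, float] = CYCLE_BAND,
                        accept_hz: tuple[float, float] = CYCLE_FREQ_ACCEPT,
                        ) -> ThetaCycleTable:
    """Detect theta cycles from peaks/troughs of the band-passed signal.

    Local maxima and minima of the 5–15 Hz zero-phase filtered trace are
    paired into peak -> trough -> next-peak triplets (alternation enforced);
    cycles whose implied frequency falls outside 4–14 Hz are rejected.
    """
    if trace.duration_s < 1.0:
        raise ValueError("cycle detection needs at least 1 s of signal")
    x = bandpass(trace.data, trace.rate_hz, *band)
    raw_sd = float(np.std(trace.data))
    if raw_sd == 0 or float(np.std(x)) < 0.05 * raw_sd:
        # theta band carries <0.25% of the variance: nothing but filter
        # ripple to detect
        logger.warning("no appreciable %g-%g Hz power; no cycles detected",
                       *band)
        e = np.empty(0)
        return ThetaCycleTable(e, e, e, e, e)
    min_dist = int(trace.rate_hz / accept_hz[1])
    peaks, _ = find_peaks(x, distance=min_dist)
    troughs, _ = find_peaks(-x, distance=min_dist)
    if peaks.size < 2 or troughs.size < 1:
        logger.warning("no theta cycles detected")
        e = np.empty(0)
        return ThetaCycleTable(e, e, e, e, e)

    pk_t, tr_t, npk_t, amp, freq = [], [], [], [], []
    t = trace.times()
    ti = 0
    for k in range(peaks.size - 1):
        p0, p1 = peaks[k], peaks[k + 1]
        # single trough strictly between the two peaks
        while ti < troughs.size and troughs[ti] <= p0:
            ti += 1
        if ti >= troughs.size or troughs[ti] >= p1:
            continue
        if ti + 1 < troughs.size and troughs[ti + 1] < p1:
            continue  # alternation broken: two troughs between peaks
        f = trace.rate_hz / (p1 - p0)
        if not (accept_hz[0] <= f <= accept_hz[1]):
            continue
        pk_t.append(t[p0])
        tr_t.append(t[troughs[ti]])
        npk_t.append(t[p1])
        amp.append(x[p0])
        freq.append(f)
    if not pk_t:
        logger.warning("no theta cycles in the accepted 4-14 Hz range")
        e = np.empty(0)
        return ThetaCycleTable(e, e, e, e, e)
    return ThetaCycleTable(
        np.array(pk_t), np.array(tr_t), np.array(npk_t),
        np.array(amp), np.array(freq),
    )


def interpolated_phase(cycles: ThetaCycleTable, rate_hz: float,
                       duration_s: float | None = None) -> PhaseSeries:
    """Piecewise-linear phase: 0°→180° peak→trough, 180°→360° trough→next peak.

    Defined only inside detected cycles; NaN elsewhere.
    """
    if cycles.n_cycles == 0:
        raise ValueError("cannot build a phase series from an empty cycle table")
    if duration_s is None:
        duration_s = float(cycles.next_peak_t[-1])
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    phase = np.full(n, np.nan)
    for pk, tr, npk in zip(cycles.peak_t, cycles.trough_t, cycles.next_peak_t):
        i0 = int(np.ceil(pk * rate_hz))
        im = int(np.ceil(tr * rate_hz))
        i1 = min(int(np.ceil(npk * rate_hz)), n)
        if i0 >= n:
            break
        im = min(im, n)
        phase[i0:im] = 180.0 * (t[i0:im] - pk) / (tr - pk)
        if im < i1:
            phase[im:i1] = 180.0 + 180.0 * (t[im:i1] - tr) / (npk - tr)
    return PhaseSeries(t, np.mod(phase, 360.0), method="interpolated")


def hilbert_phase(trace: LfpTrace,
                  band: tuple[float, float] = HILBERT_BAND) -> PhaseSeries:
    """Analytic-signal phase of the 5–10 Hz filtered trace, peak = 0°."""
    if trace.duration_s < 1.0:
        raise ValueError("hilbert phase needs at least 1 s of signal")
    x = bandpass(trace.data, trace.rate_hz, *band)
    # cos convention: angle(hilbert) = 0 at local maxima of the filtered wave
    ph = np.degrees(np.angle(hilbert(x)))
    return PhaseSeries(trace.times(), np.mod(ph, 360.0), method="hilbert")


# ---------------------------------------------------------------------------
# phase-amplitude coupling


def detect_gamma_peaks(trace: LfpTrace,
                       band: tuple[float, float] = GAMMA_BAND,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Times and amplitudes of local maxima of the gamma band-passed signal."""
    g = bandpass(trace.data, trace.rate_hz, *band)
    min_dist = max(1, int(trace.rate_hz / band[1]))
    idx, _ = find_peaks(g, distance=min_dist)
    idx = idx[g[idx] > 0]
    return idx / trace.rate_hz, g[idx]


def modulation_coefficient(phases_deg: np.ndarray, amps: np.ndarray,
                           n_phase_bins: int = PAC_PHASE_BINS) -> float:
    """(max − min)/(max + min) of phase-binned mean amplitude.

    0 for a constant amplitude profile; 1 when some phase bin's mean
    amplitude is zero.  NaN when any phase bin is empty.
    """
    phases = np.mod(np.asarray(phases_deg, dtype=float), 360.0)
    amps = np.asarray(amps, dtype=float)
    edges = np.linspace(0.0, 360.0, n_phase_bins + 1)
    which = np.clip(np.digitize(phases, edges) - 1, 0, n_phase_bins - 1)
    sums = np.bincount(which, weights=amps, minlength=n_phase_bins)
    counts = np.bincount(which, minlength=n_phase_bins)
    if np.any(counts == 0):
        return math.nan
    means = sums / counts
    hi, lo = float(means.max()), float(means.min())
    if hi + lo == 0:
        return 0.0
    coeff = (hi - lo) / (hi + lo)
    # constant profiles must come out exactly 0, not at rounding residue
    return 0.0 if coeff < 1e-12 else coeff


@dataclass
class PacProfile:
    """Theta-phase / gamma-amplitude coupling, per theta-amplitude bin."""

    phase_bin_edges: np.ndarray
    amp_bin_edges: np.ndarray           # standardized theta-amplitude quantile edges
    mean_gamma_amp: np.ndarray          # (n_amp_bins, n_phase_bins), NaN if sparse
    modulation_coefficient: np.ndarray  # per amp bin, NaN where undefined
    overall_coefficient: float
    n_gamma_peaks: int
    flags: list[str] = field(default_factory=list)


def _standardized_cycle_amp(cycles: ThetaCycleTable,
                            intervals: list[tuple[float, float]],
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Z-score cycle amplitudes within each eligible interval and pool.

    Returns (cycle mid-times, standardized amplitudes) for cycles whose peak
    falls inside one of the intervals.  Standardizing per epoch removes
    slow between-epoch amplitude drifts before amplitude binning.
    """
    ts, zs = [], []
    for (t0, t1) in intervals:
        sel = (cycles.peak_t >= t0) & (cycles.peak_t < t1)
        if sel.sum() < 3:
            continue
        a = cycles.amplitude[sel]
        sd = a.std()
        z = (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)
        ts.append(cycles.peak_t[sel])
        zs.append(z)
    if not ts:
        return np.empty(0), np.empty(0)
    return np.concatenate(ts), np.concatenate(zs)


def pac_profile(trace: LfpTrace,
                intervals: list[tuple[float, float]],
                cycles: ThetaCycleTable | None = None,
                n_phase_bins: int = PAC_PHASE_BINS,
                n_amp_bins: int = PAC_AMP_BINS,
                min_peaks: int = PAC_MIN_PEAKS) -> PacProfile:
    """Theta–gamma PAC over the eligible (theta/delta >= 6) intervals.

    Gamma peaks inside the intervals are assigned a Hilbert theta phase and
    the standardized amplitude of the concurrent theta cycle; peaks are
    binned by theta amplitude (quantile bins) and by phase (20° bins), and a
    modulation coefficient is computed per amplitude bin.  Amplitude bins
    with fewer than ``min_peaks`` gamma peaks are flagged and left NaN.
    """
    if not intervals:
        raise ValueError("PAC requires at least one eligible epoch")
    if cycles is None:
        cycles = detect_theta_cycles(trace)
    if cycles.n_cycles == 0:
        raise ValueError("PAC requires detected theta cycles")
    ph = hilbert_phase(trace)
    gt, ga = detect_gamma_peaks(trace)

    in_any = np.zeros(gt.size, dtype=bool)
    for (t0, t1) in intervals:
        in_any |= (gt >= t0) & (gt < t1)
    gt, ga = gt[in_any], ga[in_any]
    gphase = ph.at(gt)

    cyc_t, cyc_z = _standardized_cycle_amp(cycles, intervals)
    if cyc_t.size == 0:
        raise ValueError("no theta cycles inside the eligible intervals")
    # concurrent cycle: the one whose peak most recently precedes the gamma peak
    idx = np.clip(np.searchsorted(cyc_t, gt, side="right") - 1, 0, cyc_t.size - 1)
    gz = cyc_z[idx]

    ok = np.isfinite(gphase)
    gphase, ga, gz = gphase[ok], ga[ok], gz[ok]

    qs = np.linspace(0, 1, n_amp_bins + 1)
    amp_edges = np.quantile(gz, qs) if gz.size else np.zeros(n_amp_bins + 1)
    phase_edges = np.linspace(0.0, 360.0, n_phase_bins + 1)
    mean_amp = np.full((n_amp_bins, n_phase_bins), np.nan)
    coeffs = np.full(n_amp_bins, np.nan)
    flags: list[str] = []
    for b in range(n_amp_bins):
        lo, hi = amp_edges[b], amp_edges[b + 1]
        sel = (gz >= lo) & (gz <= hi if b == n_amp_bins - 1 else gz < hi)
        if sel.sum() < min_peaks:
            flags.append(f"amp_bin_{b}_below_min_peaks")
            continue
        pb = np.clip(np.digitize(np.mod(gphase[sel], 360.0), phase_edges) - 1,
                     0, n_phase_bins - 1)
        sums = np.bincount(pb, weights=ga[sel], minlength=n_phase_bins)
        counts = np.bincount(pb, minlength=n_phase_bins)
        with np.errstate(invalid="ignore"):
            mean_amp[b] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        coeffs[b] = modulation_coefficient(gphase[sel], ga[sel], n_phase_bins)
    overall = (modulation_coefficient(gphase, ga, n_phase_bins)
               if gphase.size >= min_peaks else math.nan)
    return PacProfile(phase_edges, amp_edges, mean_amp, coeffs, overall,
                      n_gamma_peaks=int(gphase.size), flags=flags)


def pac_shuffle_null(phases_deg: np.ndarray, amps: np.ndarray,
                     n_shuffles: int = 200,
                     rng: np.random.Generator | None = None,
                     n_phase_bins: int = PAC_PHASE_BINS) -> np.ndarray:
    """Null distribution of the modulation coefficient under phase permutation.

    Shuffling the pairing of gamma-peak amplitudes with theta phases
    destroys any coupling while preserving both marginals.
    """
    rng = np.random.default_rng() if rng is None else rng
    amps = np.asarray(amps, dtype=float)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = modulation_coefficient(
            phases_deg, rng.permutation(amps), n_phase_bins)
    return out
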