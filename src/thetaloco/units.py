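"""Single-unit analyses: spike-phase statistics, unit classification, the
pairwise theta-cycle amplitude / spike-count regression, and spatial firing
maps with coherence and sparsity.

The pairwise analysis asks whether a neuron's spike output near theta peaks
(or troughs — phase bins of comparable excitability) tracks cycle-to-cycle
amplitude fluctuations: for every pair of theta cycles (i, j) the spike-count
difference S = S_i − S_j within a ±30° phase bin is regressed on the
amplitude difference A = A_i − A_j.  Over all pairs, the OLS slope of S on A
is algebraically identical to the within-bin-centered cycle-level regression
slope, which is how it is computed here (O(n) instead of O(n²)); the p-value
uses the cycle-level degrees of freedom, since pairwise differences are not
independent observations.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circstats import circular_stats
from .io import PositionTrack, SpikeTrain
from .theta import PhaseSeries, ThetaCycleTable

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseHistogram",
    "PairwiseCycleComparison",
    "FiringMap",
    "normalized_phase_histogram",
    "classify_unit",
    "burst_index",
    "assign_spike_cycles",
    "phase_bin_counts",
    "enumerate_pairs",
    "pairwise_amplitude_spike_regression",
    "firing_map_stats",
    "spatial_coherence_z",
    "sparsity",
]

PYRAMIDAL_MAX_RATE_HZ = 3.5       # strict: rate must be < 3.5 Hz
INTERNEURON_MIN_RATE_HZ = 10.0
BURST_INDEX_THRESHOLD = 1.5
MIN_SPIKES_CLASSIFY = 50
PHASE_BIN_HALFWIDTH_DEG = 30.0    # ±30° around peak (0°) and trough (180°)
MIN_SPIKES_PER_BIN = 10
MAX_PAIRS = 1_000_000
PIXEL_CM = 2.0
RUNNING_THRESHOLD_CM_S = 2.0


# ---------------------------------------------------------------------------
# occupancy-normalized phase histograms


@dataclass
class PhaseHistogram:
    """Occupancy-corrected event-phase histogram with circular summaries.

    ``prob`` sums to 1 over defined bins.  The correction divides event
    counts by the relative time the LFP phase spent in each bin, so a bin
    over-represented merely because the oscillation dwells there is not
    mistaken for phase preference.  Applies identically to spike trains and
    laser-pulse trains.
    """

    bin_edges: np.ndarray
    prob: np.ndarray
    n_events: int
    resultant_length: float
    mean_phase_deg: float
    rayleigh_p: float
    undefined_bins: np.ndarray = field(default_factory=lambda: np.empty(0, bool))


def normalized_phase_histogram(event_t: np.ndarray, phase: PhaseSeries,
                               n_bins: int = 12) -> PhaseHistogram:
    """Phase histogram of events, corrected for phase-occupancy bias.

    Counts per bin are divided by the occupancy of that bin relative to
    uniform, then renormalized to sum 1.  Bins the phase series never
    visits are undefined (NaN) and flagged.
    """
    event_phase = phase.at(np.asarray(event_t, dtype=float))
    event_phase = event_phase[np.isfinite(event_phase)]
    if event_phase.size < 1:
        raise ValueError("no events fall inside phase-defined time")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(np.mod(event_phase, 360.0), bins=edges)

    samp = phase.phase_deg[np.isfinite(phase.phase_deg)]
    occ, _ = np.histogram(np.mod(samp, 360.0), bins=edges)
    occ_rel = occ / occ.sum() * n_bins      # 1.0 everywhere for uniform dwell
    undefined = occ == 0
    if undefined.any():
        logger.warning("%d phase bins with zero occupancy", int(undefined.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(undefined, np.nan, counts / occ_rel)
    total = np.nansum(corrected)
    prob = corrected / total if total > 0 else corrected
    if event_phase.size >= 2:
        r, mu, p = circular_stats(event_phase)
    else:
        r, mu, p = 1.0, float(event_phase[0]), math.nan
    return PhaseHistogram(edges, prob, int(event_phase.size), r, mu, p,
                          undefined_bins=undefined)


# ---------------------------------------------------------------------------
# unit classification


def burst_index(spike_t: np.ndarray, burst_lags_ms=(2.0, 10.0),
                baseline_lags_ms=(40.0, 50.0)) -> float:
    """Autocorrelogram burst index: counts in 2–10 ms lags over 40–50 ms lags.

    Large for complex-spike-bursting pyramidal cells, near or below 1 for
    tonically firing cells.  Infinite when the baseline window is empty.
    """
    t = np.asarray(spike_t, dtype=float)
    max_lag = baseline_lags_ms[1] / 1000.0
    n_burst = n_base = 0
    hi = np.searchsorted(t, t + max_lag, side="right")
    for i in range(t.size):
        lags = (t[i + 1 : hi[i]] - t[i]) * 1000.0
        n_burst += int(np.sum((lags >= burst_lags_ms[0]) & (lags <= burst_lags_ms[1])))
        n_base += int(np.sum((lags >= baseline_lags_ms[0]) & (lags <= baseline_lags_ms[1])))
    if n_base == 0:
        return math.inf if n_burst > 0 else 0.0
    return n_burst / n_base


def classify_unit(train: SpikeTrain, session_duration_s: float) -> str:
    """pyramidal | fast-firing interneuron | unclassified.

    Pyramidal: mean rate strictly below 3.5 Hz and a bursty autocorrelogram
    (burst index > 1.5).  Fast-firing interneuron: rate >= 10 Hz.  Units
    with fewer than 50 spikes stay unclassified.
    """
    if train.n_spikes < MIN_SPIKES_CLASSIFY:
        logger.info("unit %d: only %d spikes, left unclassified",
                    train.unit_id, train.n_spikes)
        return "unclassified"
    rate = train.n_spikes / session_duration_s
    if rate >= INTERNEURON_MIN_RATE_HZ:
        return "fast-firing interneuron"
    if rate < PYRAMIDAL_MAX_RATE_HZ and burst_index(train.spike_t) > BURST_INDEX_THRESHOLD:
        return "pyramidal"
    return "unclassified"


# ---------------------------------------------------------------------------
# pairwise cycle-amplitude / spike-count regression


@dataclass
class PairwiseCycleComparison:
    """Per-neuron result of the cycle-pair spike-count/amplitude regression."""

    unit_id: int
    slope: float
    intercept: float
    slope_p: float
    n_cycles: int
    n_pairs: int
    spikes_per_bin: dict          # {"peak": n, "trough": n}
    excluded: bool
    exclusion_reason: str = ""
    # paper-style summary: mean S per bin of A differences
    a_bin_centers: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_s_per_a_bin: np.ndarray = field(default_factory=lambda: np.empty(0))


def assign_spike_cycles(spike_t: np.ndarray, cycles: ThetaCycleTable) -> np.ndarray:
    """Index of the concurrent theta cycle per spike; -1 outside any cycle."""
    t = np.asarray(spike_t, dtype=float)
    idx = np.searchsorted(cycles.peak_t, t, side="right") - 1
    idx = np.clip(idx, 0, cycles.n_cycles - 1)
    inside = (t >= cycles.peak_t[idx]) & (t < cycles.next_peak_t[idx])
    return np.where(inside, idx, -1)


def phase_bin_counts(spike_t: np.ndarray, cycles: ThetaCycleTable,
                     phase: PhaseSeries, center_deg: float,
                     halfwidth_deg: float = PHASE_BIN_HALFWIDTH_DEG,
                     ) -> np.ndarray:
    """Per-cycle spike counts within ±halfwidth of ``center_deg``."""
    sp_phase = phase.at(spike_t)
    d = np.abs(np.mod(sp_phase - center_deg + 180.0, 360.0) - 180.0)
    in_bin = np.isfinite(sp_phase) & (d <= halfwidth_deg)
    cyc = assign_spike_cycles(np.asarray(spike_t)[in_bin], cycles)
    counts = np.zeros(cycles.n_cycles, dtype=float)
    valid = cyc >= 0
    np.add.at(counts, cyc[valid], 1.0)
    return counts


def enumerate_pairs(counts: np.ndarray, amps: np.ndarray,
                    max_pairs: int = MAX_PAIRS,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """All (i < j) pair differences S_i−S_j, A_i−A_j, subsampled beyond
    ``max_pairs`` with a fixed-seed generator for tractability."""
    n = counts.size
    total = n * (n - 1) // 2
    rng = np.random.default_rng(0) if rng is None else rng
    if total <= max_pairs:
        i, j = np.triu_indices(n, k=1)
    else:
        flat = rng.choice(total, size=max_pairs, replace=False)
        # invert the (i, j) -> flat triangular index mapping
        i = (n - 2 - np.floor(
            np.sqrt(-8.0 * flat + 4 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(int)
        j = (flat + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    return counts[i] - counts[j], amps[i] - amps[j]


def _centered(counts: np.ndarray, amps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return counts - counts.mean(), amps - amps.mean()


def pairwise_amplitude_spike_regression(
    train: SpikeTrain,
    cycles: ThetaCycleTable,
    phase: PhaseSeries,
    min_spikes_per_bin: int = MIN_SPIKES_PER_BIN,
    n_a_bins: int = 8,
    max_pairs: int = MAX_PAIRS,
    rng: np.random.Generator | None = None,
) -> PairwiseCycleComparison:
    """Regress pairwise spike-count differences on cycle-amplitude differences.

    Spikes outside the ±30° peak and trough bins are discarded; a neuron
    with fewer than 10 spikes in either phase bin is excluded (with its bin
    counts reported).  Pairs from the peak and trough bins are pooled; the
    slope is the exact all-pairs OLS slope (computed via the centered
    cycle-level identity), the p-value a two-sided t-test at cycle-level
    degrees of freedom.  The A-binned mean-S profile is built from an
    explicit (possibly subsampled) pair enumeration.
    """
    if cycles.n_cycles < 3:
        raise ValueError("need at least 3 theta cycles")
    rng = np.random.default_rng(0) if rng is None else rng
    bins = {"peak": 0.0, "trough": 180.0}
    per_bin_counts = {
        name: phase_bin_counts(train.spike_t, cycles, phase, center)
        for name, center in bins.items()
    }
    spikes_per_bin = {k: int(v.sum()) for k, v in per_bin_counts.items()}
    lacking = [k for k, v in spikes_per_bin.items() if v < min_spikes_per_bin]
    if lacking:
        reason = "fewer than {} spikes in {} bin(s)".format(
            min_spikes_per_bin, "/".join(lacking))
        logger.warning("unit %d excluded: %s (counts %s)",
                       train.unit_id, reason, spikes_per_bin)
        return PairwiseCycleComparison(
            train.unit_id, math.nan, math.nan, math.nan,
            cycles.n_cycles, 0, spikes_per_bin, excluded=True,
            exclusion_reason=reason)

    # exact all-pairs slope via within-bin centering
    sc_parts, ac_parts = [], []
    s_pairs, a_pairs = [], []
    n_pairs_total = 0
    for name in bins:
        c, a = per_bin_counts[name], cycles.amplitude
        cc, ca = _centered(c, a)
        sc_parts.append(cc)
        ac_parts.append(ca)
        sp, ap = enumerate_pairs(c, a, max_pairs=max_pairs // 2, rng=rng)
        s_pairs.append(sp)
        a_pairs.append(ap)
        n_pairs_total += sp.size
    sc = np.concatenate(sc_parts)
    ac = np.concatenate(ac_parts)
    sxx = float(np.dot(ac, ac))
    if sxx == 0:
        raise ValueError("zero amplitude variance across cycles")
    slope = float(np.dot(ac, sc)) / sxx
    # intercept of the pairwise regression (0 by antisymmetry up to subsampling)
    sp_all = np.concatenate(s_pairs)
    ap_all = np.concatenate(a_pairs)
    intercept = float(sp_all.mean() - slope * ap_all.mean())
    # p-value at cycle-level dof: residuals of the centered regression
    dof = sc.size - 2
    resid = sc - slope * ac
    se = math.sqrt(float(np.dot(resid, resid)) / dof / sxx)
    tval = slope / se if se > 0 else math.inf
    slope_p = 2.0 * float(stats.t.sf(abs(tval), dof))

    # paper-style summary profile: mean S per A-difference bin
    edges = np.linspace(ap_all.min(), ap_all.max(), n_a_bins + 1)
    which = np.clip(np.digitize(ap_all, edges) - 1, 0, n_a_bins - 1)
    sums = np.bincount(which, weights=sp_all, minlength=n_a_bins)
    counts = np.bincount(which, minlength=n_a_bins)
    with np.errstate(invalid="ignore"):
        mean_s = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PairwiseCycleComparison(
        train.unit_id, slope, intercept, slope_p,
        cycles.n_cycles, n_pairs_total, spikes_per_bin, excluded=False,
        a_bin_centers=centers, mean_s_per_a_bin=mean_s)


# ---------------------------------------------------------------------------
# spatial firing maps


@dataclass
class FiringMap:
    """2 × 2 cm rate map with occupancy, spatial coherence and sparsity."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    spike_count: np.ndarray
    occupancy_s: np.ndarray
    rate_hz: np.ndarray           # NaN where never visited
    coherence_z: float
    sparsity: float
    low_coverage: bool = False


def spatial_coherence_z(rate: np.ndarray) -> float:
    """Fisher z of the correlation between pixel rate and its 8-neighbour mean.

    Only visited pixels (finite rate) enter; neighbour means use visited
    neighbours only.
    """
    visited = np.isfinite(rate)
    ny, nx = rate.shape
    center, neigh = [], []
    for iy in range(ny):
        for ix in range(nx):
            if not visited[iy, ix]:
                continue
            vals = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dy == dx == 0:
                        continue
                    jy, jx = iy + dy, ix + dx
                    if 0 <= jy < ny and 0 <= jx < nx and visited[jy, jx]:
                        vals.append(rate[jy, jx])
            if vals:
                center.append(rate[iy, ix])
                neigh.append(float(np.mean(vals)))
    if len(center) < 3:
        return math.nan
    center = np.asarray(center)
    neigh = np.asarray(neigh)
    if center.std() == 0 or neigh.std() == 0:
        return math.nan
    r = float(np.corrcoef(center, neigh)[0, 1])
    r = min(max(r, -0.999999), 0.999999)
    return math.atanh(r)


def sparsity(rate: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs sparsity (sum p_i r_i)^2 / sum p_i r_i^2 over visited pixels.

    1 for spatially uniform firing, 1/N when all firing is confined to one
    of N equally occupied pixels.
    """
    visited = np.isfinite(rate) & (occupancy > 0)
    p = occupancy[visited] / occupancy[visited].sum()
    r = rate[visited]
    denom = float(np.sum(p * r**2))
    if denom == 0:
        return math.nan
    return float(np.sum(p * r) ** 2 / denom)


def firing_map_stats(train: SpikeTrain, track: PositionTrack,
                     speed_cm_s: np.ndarray,
                     arena_cm: tuple[float, float] = (48.0, 30.0),
                     pixel_cm: float = PIXEL_CM,
                     running_threshold: float = RUNNING_THRESHOLD_CM_S,
                     min_coverage: float = 0.5) -> FiringMap:
    """Spatial rate map of a unit during running.

    Immobility samples (speed <= 2 cm/s) and the spikes emitted during them
    are excluded.  Spike positions come from linear interpolation of the
    track at spike times.  Rate = count / occupancy per visited pixel.
    """
    speed = np.asarray(speed_cm_s, dtype=float)
    if speed.size != track.t.size:
        raise ValueError("speed series must align with the track samples")
    running = speed > running_threshold
    if not running.any():
        raise ValueError("zero running time: firing map undefined")
    dt = float(np.median(np.diff(track.t)))
    x_edges = np.arange(0.0, arena_cm[0] + pixel_cm, pixel_cm)
    y_edges = np.arange(0.0, arena_cm[1] + pixel_cm, pixel_cm)
    occ, _, _ = np.histogram2d(track.y[running], track.x[running],
                               bins=[y_edges, x_edges])
    occ = occ * dt

    sp_x = np.interp(train.spike_t, track.t, track.x)
    sp_y = np.interp(train.spike_t, track.t, track.y)
    frame = np.clip(np.searchsorted(track.t, train.spike_t), 0, track.t.size - 1)
    sp_run = running[frame]
    cnt, _, _ = np.histogram2d(sp_y[sp_run], sp_x[sp_run],
                               bins=[y_edges, x_edges])
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occ > 0, cnt / np.where(occ > 0, occ, 1.0), np.nan)
    coverage = float((occ > 0).mean())
    low = coverage < min_coverage
    if low:
        logger.warning("unit %d: only %.0f%% of pixels visited",
                       train.unit_id, 100 * coverage)
    return FiringMap(x_edges, y_edges, cnt, occ, rate,
                     coherence_z=spatial_coherence_z(rate),
                     sparsity=sparsity(rate, occ),
                     low_coverage=low)
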