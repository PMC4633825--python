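"""Pipeline orchestration: simulate -> analyze -> report.

Owns the on-disk session layout and the report file formats:

    session dir:  lfp.dat + lfp.json, spikes.csv, pulses.csv, positions.csv,
                  conditions.csv, truth.yaml, manifest.json (checksums)
    report dir:   epochs.csv, units_phase.csv, units_pairwise.csv, maps.csv,
                  pac.csv, summary.json

Every analysis constant is surfaced on :class:`AnalysisConfig`; defaults
are the study's stated values where one exists (fidelity gate 0.3,
theta/delta gate 6, running threshold 2 cm/s, pyramidal rate bound 3.5 Hz,
±30° phase bins, 10-spike bin minimum).  Reports are regenerable
bit-identically from the same inputs and config (fixed permutation seeds).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, locomotion, spectral, theta, units
from .synth import GeneratorConfig, SessionBundle, generate_session

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "SessionReport",
    "run_simulation",
    "load_session",
    "run_analysis",
    "write_report",
]

SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """All tunables of the analysis, with the study defaults."""

    session_dir: str = "."
    out_dir: str = "report"
    epoch_s: float = 10.0
    fidelity_min: float = 0.3
    theta_delta_min: float = 6.0
    running_threshold_cm_s: float = 2.0
    speed_lp_cutoff_hz: float = 2.0
    pyramidal_max_rate_hz: float = 3.5
    phase_bin_halfwidth_deg: float = 30.0
    min_spikes_per_bin: int = 10
    phase_hist_bins: int = 12
    pac_phase_bins: int = 18
    pac_amp_bins: int = 5
    pac_min_peaks: int = 50
    pixel_cm: float = 2.0
    max_pairs: int = 1_000_000
    n_permutations: int = 1000
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SessionReport:
    epochs: pd.DataFrame
    units_phase: pd.DataFrame
    units_pairwise: pd.DataFrame
    maps: pd.DataFrame
    pac: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# simulate


def run_simulation(cfg: GeneratorConfig, out_dir: str | Path) -> Path:
    """Generate a session and write every session file plus a manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    bundle = generate_session(cfg)
    io.write_lfp(bundle.lfp, out / "lfp.dat")
    io.write_spikes(bundle.spikes, out / "spikes.csv")
    io.write_pulses(bundle.pulses, out / "pulses.csv")
    io.write_positions(bundle.track, out / "positions.csv")
    bundle.condition_labels.to_csv(out / "conditions.csv", index=False)
    (out / "truth.yaml").write_text(yaml.safe_dump(cfg.to_dict(),
                                                   sort_keys=True))
    files = ["lfp.dat", "lfp.json", "spikes.csv", "pulses.csv",
             "positions.csv", "conditions.csv", "truth.yaml"]
    manifest = {name: _sha256(out / name) for name in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    logger.info("session written to %s", out)
    return out


def load_session(session_dir: str | Path) -> SessionBundle:
    """Read a session directory back into memory (truth optional)."""
    d = Path(session_dir)
    for name in ("lfp.dat", "spikes.csv", "pulses.csv", "positions.csv",
                 "conditions.csv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing session file {d / name}")
    lfp = io.read_lfp(d / "lfp.dat")
    spikes = io.read_spikes(d / "spikes.csv")
    pulses = io.read_pulses(d / "pulses.csv")
    track = io.read_positions(d / "positions.csv")
    cond = pd.read_csv(d / "conditions.csv")
    truth_path = d / "truth.yaml"
    truth = (GeneratorConfig(**yaml.safe_load(truth_path.read_text()))
             if truth_path.exists() else GeneratorConfig())
    # shared-clock sanity: events must fall inside the LFP span
    span = lfp.duration_s
    for tr in spikes:
        if tr.n_spikes and (tr.spike_t[0] < 0 or tr.spike_t[-1] > span + 1.0):
            raise ValueError(
                f"unit {tr.unit_id}: spikes outside the LFP clock span")
    if pulses.n_pulses and pulses.onset_t[-1] > span + 1.0:
        raise ValueError("pulses outside the LFP clock span")
    return SessionBundle(lfp, spikes, pulses, track, cond, truth)


# ---------------------------------------------------------------------------
# analyze


def _epoch_theta_metrics(epochs, cycles):
    for m in epochs:
        sel = (cycles.peak_t >= m.t_start_s) & (cycles.peak_t < m.t_end_s)
        if sel.sum() >= 3:
            a = cycles.amplitude[sel]
            m.theta_amp_mean = float(a.mean())
            m.theta_amp_cv = float(a.std() / a.mean()) if a.mean() > 0 else math.nan
            m.theta_freq_hz = float(cycles.freq_hz[sel].mean())


def _epochs_frame(epochs) -> pd.DataFrame:
    rows = []
    for m in epochs:
        d = dataclasses.asdict(m)
        d["reasons"] = ";".join(m.reasons)
        rows.append(d)
    return pd.DataFrame(rows)


def _condition_contrast(df: pd.DataFrame) -> dict:
    """Entrained-vs-spontaneous means of the headline epoch metrics."""
    out = {}
    inc = df[df["included"]]
    ent = inc[inc["condition"].str.startswith("entrained")]
    spo = inc[inc["condition"] == "spontaneous"]
    for name in ("fidelity", "theta_amp_cv", "speed_mean_cm_s", "speed_cv"):
        out[f"entrained_{name}"] = float(ent[name].mean()) if len(ent) else math.nan
        out[f"spontaneous_{name}"] = float(spo[name].mean()) if len(spo) else math.nan
    return out


def run_analysis(cfg: AnalysisConfig) -> SessionReport:
    """Run spectral -> theta phase -> unit -> locomotion on one session."""
    bundle = load_session(cfg.session_dir)
    lfp = bundle.lfp.channel(0)
    cond_df = bundle.condition_labels
    labels = list(cond_df["condition"])
    n_epochs = int(lfp.duration_s // cfg.epoch_s)
    if len(labels) < n_epochs:
        raise ValueError("conditions.csv does not cover the whole recording")

    session_stim = None
    if bundle.pulses.n_pulses >= 3:
        session_stim = 1.0 / float(np.median(np.diff(bundle.pulses.onset_t)))
        if not (5.0 <= session_stim <= 12.0):
            session_stim = None
    epochs = spectral.select_epochs(lfp, bundle.pulses,
                                    stim_freq_hz=session_stim,
                                    conditions=labels[:n_epochs])
    cycles = theta.detect_theta_cycles(lfp)
    if cycles.n_cycles == 0:
        raise RuntimeError("no theta cycles detected in this session")
    _epoch_theta_metrics(epochs, cycles)
    phase = theta.interpolated_phase(cycles, lfp.rate_hz,
                                     duration_s=lfp.duration_s)

    speed = locomotion.instantaneous_speed(bundle.track,
                                           cutoff_hz=cfg.speed_lp_cutoff_hz,
                                           threshold=cfg.running_threshold_cm_s)
    locomotion.epoch_locomotion_metrics(speed, epochs)

    # PAC over eligible epochs
    pac_rows = []
    eligible = [(m.t_start_s, m.t_end_s) for m in epochs if m.pac_eligible]
    if eligible:
        prof = theta.pac_profile(lfp, eligible, cycles=cycles,
                                 n_phase_bins=cfg.pac_phase_bins,
                                 n_amp_bins=cfg.pac_amp_bins,
                                 min_peaks=cfg.pac_min_peaks)
        for b in range(cfg.pac_amp_bins):
            pac_rows.append({
                "amp_bin": b,
                "amp_lo": prof.amp_bin_edges[b],
                "amp_hi": prof.amp_bin_edges[b + 1],
                "modulation_coefficient": prof.modulation_coefficient[b],
            })
        pac_rows.append({"amp_bin": -1, "amp_lo": math.nan, "amp_hi": math.nan,
                         "modulation_coefficient": prof.overall_coefficient})
    pac_df = pd.DataFrame(pac_rows)

    # per-unit analyses
    rng = np.random.default_rng(cfg.seed)
    phase_rows, pair_rows, map_rows = [], [], []
    duration = lfp.duration_s
    for tr in bundle.spikes:
        klass = units.classify_unit(tr, duration)
        try:
            h = units.normalized_phase_histogram(tr.spike_t, phase,
                                                 n_bins=cfg.phase_hist_bins)
            phase_rows.append({
                "unit_id": tr.unit_id, "unit_class": klass,
                "n_spikes": h.n_events,
                "resultant_length": h.resultant_length,
                "mean_phase_deg": h.mean_phase_deg,
                "rayleigh_p": h.rayleigh_p,
            })
        except ValueError as exc:
            logger.warning("unit %d phase histogram skipped: %s",
                           tr.unit_id, exc)
        pw = units.pairwise_amplitude_spike_regression(
            tr, cycles, phase,
            min_spikes_per_bin=cfg.min_spikes_per_bin,
            max_pairs=cfg.max_pairs, rng=rng)
        pair_rows.append({
            "unit_id": tr.unit_id, "unit_class": klass,
            "slope": pw.slope, "intercept": pw.intercept,
            "slope_p": pw.slope_p, "n_pairs": pw.n_pairs,
            "spikes_peak_bin": pw.spikes_per_bin.get("peak", 0),
            "spikes_trough_bin": pw.spikes_per_bin.get("trough", 0),
            "excluded": pw.excluded, "exclusion_reason": pw.exclusion_reason,
        })
        try:
            fm = units.firing_map_stats(
                tr, bundle.track,
                np.concatenate([[0.0], speed.speed_cm_s]),
                pixel_cm=cfg.pixel_cm,
                running_threshold=cfg.running_threshold_cm_s)
            map_rows.append({
                "unit_id": tr.unit_id, "unit_class": klass,
                "coherence_z": fm.coherence_z, "sparsity": fm.sparsity,
                "low_coverage": fm.low_coverage,
            })
        except ValueError as exc:
            logger.warning("unit %d firing map skipped: %s", tr.unit_id, exc)

    epochs_df = _epochs_frame(epochs)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "n_epochs": len(epochs),
        "n_included_epochs": int(epochs_df["included"].sum()),
        "n_units": len(bundle.spikes),
        "contrast": _condition_contrast(epochs_df),
    }
    # frequency-speed correlations per condition, where enough epochs exist
    for cond in sorted(set(labels[:n_epochs])):
        try:
            r, p = locomotion.frequency_speed_correlation(epochs, cond)
            summary[f"freq_speed_r[{cond}]"] = r
            summary[f"freq_speed_p[{cond}]"] = p
        except ValueError:
            pass
    try:
        prof = locomotion.amplitude_variability_profile(epochs)
        summary["amp_cv_profile"] = {
            "bin_centers": prof.bin_centers.tolist(),
            "speed_cv_mean": prof.speed_cv_mean.tolist(),
            "speed_mean": prof.speed_mean.tolist(),
            "r2_speed_cv": prof.r2_speed_cv,
            "r2_speed": prof.r2_speed,
        }
    except ValueError as exc:
        logger.info("amplitude-variability profile skipped: %s", exc)

    return SessionReport(
        epochs=epochs_df,
        units_phase=pd.DataFrame(phase_rows),
        units_pairwise=pd.DataFrame(pair_rows),
        maps=pd.DataFrame(map_rows),
        pac=pac_df,
        summary=summary,
    )


def write_report(report: SessionReport, out_dir: str | Path) -> Path:
    """Write the report tables and JSON summary with stable names/order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.epochs.to_csv(out / "epochs.csv", index=False)
    report.units_phase.to_csv(out / "units_phase.csv", index=False)
    report.units_pairwise.to_csv(out / "units_pairwise.csv", index=False)
    report.maps.to_csv(out / "maps.csv", index=False)
    report.pac.to_csv(out / "pac.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(report.summary, indent=1, sort_keys=True,
                   default=float))
    logger.info("report written to %s", out)
    return out
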