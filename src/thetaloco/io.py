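"""Session file formats.

LFP traces live on disk as flat binary signed 16-bit little-endian samples
(interleaved when multi-channel) with a JSON sidecar carrying the sampling
rate, channel count and volts-per-unit scaling — the ``.dat`` convention of
the NDManager ecosystem.  Event tables (spikes, laser pulses) and position
tracking are plain CSV with headers; all times are seconds on one session
clock starting at 0.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LfpTrace",
    "PulseTrain",
    "SpikeTrain",
    "PositionTrack",
    "write_lfp",
    "read_lfp",
    "write_spikes",
    "read_spikes",
    "write_pulses",
    "read_pulses",
    "write_positions",
    "read_positions",
]


@dataclass
class LfpTrace:
    """A regularly sampled voltage series.

    data : (n_samples,) or (n_samples, n_channels) float array, volts.
    rate_hz : sampling rate.  The analyses here assume the paper-style
        1,250 Hz down-sampled LFP but nothing in the code requires it.
    """

    data: np.ndarray
    rate_hz: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim not in (1, 2):
            raise ValueError("LFP data must be 1-D or 2-D (samples x channels)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 1 else self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def channel(self, idx: int) -> "LfpTrace":
        """Single-channel view (returns self for 1-D data and idx 0)."""
        if self.data.ndim == 1:
            if idx != 0:
                raise IndexError("trace has a single channel")
            return self
        return LfpTrace(self.data[:, idx], self.rate_hz)

    def slice(self, t_start: float, t_end: float) -> "LfpTrace":
        i0 = int(round(t_start * self.rate_hz))
        i1 = int(round(t_end * self.rate_hz))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(
                f"slice [{t_start}, {t_end}] s outside trace of "
                f"{self.duration_s:.2f} s"
            )
        return LfpTrace(self.data[i0:i1], self.rate_hz)


@dataclass
class PulseTrain:
    """Laser pulse onsets (s) with a common pulse duration (ms)."""

    onset_t: np.ndarray
    pulse_ms: float = 30.0

    def __post_init__(self) -> None:
        self.onset_t = np.asarray(self.onset_t, dtype=float)
        if np.any(np.diff(self.onset_t) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")

    @property
    def n_pulses(self) -> int:
        return self.onset_t.size


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit."""

    unit_id: int
    spike_t: np.ndarray
    unit_class: str = "unclassified"

    def __post_init__(self) -> None:
        self.spike_t = np.asarray(self.spike_t, dtype=float)
        if np.any(np.diff(self.spike_t) < 0):
            raise ValueError("spike times must be non-decreasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_t.size


@dataclass
class PositionTrack:
    """Head-tracking positions, nominally 25 Hz, cm coordinates."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")


# ---------------------------------------------------------------------------
# flat-binary LFP + JSON sidecar


def write_lfp(trace: LfpTrace, dat_path: str | Path) -> Path:
    """Write int16 LE flat binary + ``.json`` sidecar next to it.

    Scaling (volts per int unit) is chosen so the absolute maximum maps to
    30000 counts, and is recorded in the sidecar for lossless-enough
    round-tripping.
    """
    dat_path = Path(dat_path)
    data = np.atleast_2d(trace.data.T).T  # (n, ch)
    peak = float(np.max(np.abs(data))) if data.size else 0.0
    volts_per_unit = peak / 30000.0 if peak > 0 else 1.0
    ints = np.round(data / volts_per_unit).astype("<i2")
    ints.tofile(dat_path)
    sidecar = {
        "rate_hz": trace.rate_hz,
        "n_channels": trace.n_channels,
        "n_samples": trace.n_samples,
        "volts_per_unit": volts_per_unit,
        "dtype": "int16-le",
        "channel_names": trace.channel_names,
    }
    side_path = dat_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return dat_path


def read_lfp(dat_path: str | Path) -> LfpTrace:
    dat_path = Path(dat_path)
    side_path = dat_path.with_suffix(".json")
    if not side_path.exists():
        raise FileNotFoundError(f"missing LFP sidecar {side_path}")
    meta = json.loads(side_path.read_text())
    raw = np.fromfile(dat_path, dtype="<i2")
    n_ch = int(meta["n_channels"])
    if raw.size != int(meta["n_samples"]) * n_ch:
        raise ValueError(
            f"{dat_path}: payload {raw.size} int16 does not match sidecar "
            f"({meta['n_samples']} samples x {n_ch} channels)"
        )
    data = raw.astype(float) * float(meta["volts_per_unit"])
    if n_ch > 1:
        data = data.reshape(-1, n_ch)
    return LfpTrace(data, float(meta["rate_hz"]),
                    list(meta.get("channel_names", [])))


# ---------------------------------------------------------------------------
# CSV event/position tables


def write_spikes(trains: list[SpikeTrain], path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame({"time_s": tr.spike_t, "unit_id": tr.unit_id})
        for tr in trains
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["time_s", "unit_id"])
    )
    df = df.sort_values(["time_s", "unit_id"], kind="stable")
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_spikes(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        trains.append(SpikeTrain(int(uid), np.sort(grp["time_s"].to_numpy())))
    return trains


def write_pulses(pulses: PulseTrain, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"onset_s": pulses.onset_t, "pulse_ms": pulses.pulse_ms}
    ).to_csv(path, index=False, float_format="%.6f")
    return path


def read_pulses(path: str | Path) -> PulseTrain:
    df = pd.read_csv(path)
    if df.empty:
        return PulseTrain(np.empty(0), 30.0)
    return PulseTrain(df["onset_s"].to_numpy(), float(df["pulse_ms"].iloc[0]))


def write_positions(track: PositionTrack, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_s": track.t, "x_cm": track.x, "y_cm": track.y}).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def read_positions(path: str | Path) -> PositionTrack:
    df = pd.read_csv(path)
    return PositionTrack(
        df["t_s"].to_numpy(), df["x_cm"].to_numpy(), df["y_cm"].to_numpy()
    )
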