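"""Recording IO and signal preprocessing.

Raw recordings are stored as one CSV per limb sensor (columns
``t,ax,ay,az,gx,gy,gz``; time in seconds, acceleration in m/s^2, angular
velocity in deg/s) plus a ``meta.yaml`` with subject id, corrected age and
the sensor -> file map.

Preprocessing follows the pipeline: linear interpolation of the received
packets onto a common ideal 52 Hz time base, removal of the per-channel
gyroscope bias, seven-tap median smoothing, and slicing into 120-sample
(~2.3 s) frames with 50% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import median_filter

from .simulate import SimRecording
from .taxonomy import FRAME_HOP, FRAME_LEN, SAMPLE_RATE, SENSORS

CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


@dataclass
class RawPacketStream:
    """Timestamped packets from one limb sensor."""

    sensor_id: str
    packets: np.ndarray  # [n, 7] = (t, ax, ay, az, gx, gy, gz)

    def __post_init__(self):
        p = np.asarray(self.packets, float)
        if p.ndim != 2 or p.shape[1] != 7:
            raise ValueError("packets must be [n, 7] (t + 6 channels)")
        if not np.all(np.isfinite(p)):
            raise ValueError(f"non-finite values in stream {self.sensor_id!r}")
        if np.any(np.diff(p[:, 0]) < 0):
            raise ValueError(f"timestamps not non-decreasing in {self.sensor_id!r}")
        self.packets = p


@dataclass
class UniformSignal:
    """24-channel signal on the ideal uniform time base.

    Channel order: (left_arm, right_arm, left_leg, right_leg) x
    (ax, ay, az, gx, gy, gz).
    """

    data: np.ndarray  # [n_samples, 24]
    t0: float
    rate: float = SAMPLE_RATE

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[1] != 24:
            raise ValueError("UniformSignal requires exactly 24 channels")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    #: boolean mask of gyro channels within the 24-channel layout
    GYRO_MASK = np.tile([False] * 3 + [True] * 3, 4)


@dataclass
class FrameArray:
    """Overlapping analysis frames: [n_frames, 120, 24], hop 60 samples."""

    frames: np.ndarray
    frame_times: np.ndarray  # center time of each frame (s)
    t0: float
    rate: float = SAMPLE_RATE
    hop: int = FRAME_HOP

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


# --------------------------------------------------------------------------
# Reading and writing
# --------------------------------------------------------------------------

def write_recording(rec: SimRecording, path) -> Path:
    """Write a recording as per-sensor CSVs + meta.yaml (+ ground-truth
    annotations when present)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sensor_files = {}
    for sensor, packets in rec.streams.items():
        fname = f"{sensor}.csv"
        pd.DataFrame(packets, columns=CSV_COLUMNS).to_csv(
            path / fname, index=False, float_format="%.6f")
        sensor_files[sensor] = fname
    meta = dict(rec.metadata)
    meta["sensors"] = sensor_files
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    if rec.ground_truth is not None:
        from .annotations import AnnotationSet, write_annotations
        ann = AnnotationSet(
            raters=["truth"],
            data={
                "posture": rec.ground_truth.posture[None, :],
                "movement": rec.ground_truth.movement[None, :],
                "carrying": rec.ground_truth.carrying[None, :],
            })
        write_annotations(ann, path / "ground_truth.csv")
    return path


def read_recording(path):
    """Read a recording directory -> ({sensor: RawPacketStream}, metadata).

    Raises with the missing sensor ids if any of the four limb-sensor
    files is absent, and with the offending file on malformed rows.
    """
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing meta.yaml in {path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    sensor_files = meta.get("sensors", {s: f"{s}.csv" for s in SENSORS})
    missing = [s for s in SENSORS
               if s not in sensor_files or not (path / sensor_files[s]).exists()]
    if missing:
        raise FileNotFoundError(f"missing sensor file(s) for: {', '.join(missing)}")
    streams = {}
    for sensor in SENSORS:
        fpath = path / sensor_files[sensor]
        try:
            df = pd.read_csv(fpath, usecols=CSV_COLUMNS)
        except ValueError as exc:
            raise ValueError(f"malformed sensor file {fpath}: {exc}") from exc
        streams[sensor] = RawPacketStream(sensor_id=sensor,
                                          packets=df[CSV_COLUMNS].to_numpy(float))
    return streams, meta


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def regularize_timestamps(stream: RawPacketStream, rate: float = SAMPLE_RATE,
                          t0: float | None = None,
                          t_end: float | None = None) -> tuple[np.ndarray, float]:
    """Linearly interpolate packets onto the ideal uniform time base.

    Returns ``(values [n, 6], t0)``. The output grid is ``t0 + i/rate``
    and never extrapolates beyond the packet span.
    """
    p = stream.packets
    if p.shape[0] < 2:
        raise ValueError(f"stream {stream.sensor_id!r} has fewer than 2 packets")
    span_lo = p[0, 0] if t0 is None else max(p[0, 0], t0)
    span_hi = p[-1, 0] if t_end is None else min(p[-1, 0], t_end)
    if span_hi - span_lo < 1.0 / rate:
        raise ValueError("packet span shorter than one sample period")
    # first grid point at or after span_lo, on the t0-anchored grid
    anchor = span_lo if t0 is None else t0
    k0 = int(np.ceil(round((span_lo - anchor) * rate, 9)))
    grid_t0 = anchor + k0 / rate
    n = int(np.floor(round((span_hi - grid_t0) * rate, 9))) + 1
    grid = grid_t0 + np.arange(n) / rate
    out = np.empty((n, 6))
    for c in range(6):
        out[:, c] = np.interp(grid, p[:, 0], p[:, c + 1])
    return out, grid_t0


def build_uniform_signal(streams: dict[str, RawPacketStream],
                         rate: float = SAMPLE_RATE) -> UniformSignal:
    """Fuse the four per-sensor streams into one 24-channel uniform signal.

    The common time base starts at the latest sensor start and ends at the
    earliest sensor end, so every channel is defined everywhere.
    """
    missing = [s for s in SENSORS if s not in streams]
    if missing:
        raise ValueError(f"missing sensor stream(s): {', '.join(missing)}")
    t0 = max(streams[s].packets[0, 0] for s in SENSORS)
    t_end = min(streams[s].packets[-1, 0] for s in SENSORS)
    parts = []
    for s in SENSORS:
        vals, _ = regularize_timestamps(streams[s], rate, t0=t0, t_end=t_end)
        parts.append(vals)
    n = min(v.shape[0] for v in parts)
    data = np.concatenate([v[:n] for v in parts], axis=1)
    return UniformSignal(data=data, t0=t0, rate=rate)


def estimate_gyro_bias(signal: UniformSignal) -> np.ndarray:
    """Estimate the per-channel gyroscope bias from low-motion windows.

    One-second windows are ranked by their total gyro variance (per
    sensor); the bias of each gyro channel is the median of its window
    means over the lowest-motion decile.
    """
    win = int(signal.rate)
    n_win = signal.n_samples // win
    if n_win < 1:
        raise ValueError("signal shorter than one second")
    gyro_cols = np.flatnonzero(UniformSignal.GYRO_MASK)
    bias = np.zeros(24)
    x = signal.data[:n_win * win]
    for si in range(4):
        cols = gyro_cols[3 * si:3 * si + 3]
        g = x[:, cols].reshape(n_win, win, 3)
        motion = g.var(axis=1).sum(axis=1)
        k = max(1, n_win // 10)
        quiet = np.argsort(motion)[:k]
        bias[cols] = np.median(g[quiet].mean(axis=1), axis=0)
    return bias


def remove_gyro_bias(signal: UniformSignal) -> UniformSignal:
    """Subtract the estimated per-channel gyro bias; accelerometer
    channels are untouched."""
    bias = estimate_gyro_bias(signal)
    data = signal.data - bias[None, :]
    return UniformSignal(data=data, t0=signal.t0, rate=signal.rate)


def median_filter7(signal: UniformSignal) -> UniformSignal:
    """Per-channel seven-tap running median (reflect padding at edges)."""
    if signal.n_samples < 7:
        raise ValueError("median filter requires at least 7 samples")
    data = median_filter(signal.data, size=(7, 1), mode="reflect")
    return UniformSignal(data=data, t0=signal.t0, rate=signal.rate)


def make_frames(signal: UniformSignal, frame_len: int = FRAME_LEN,
                hop: int = FRAME_HOP) -> FrameArray:
    """Slice the uniform signal into 120-sample frames with 50% overlap.

    Frame ``i`` covers samples ``[hop*i, hop*i + frame_len)``; a trailing
    partial window is discarded.
    """
    n = signal.n_samples
    if n < frame_len:
        raise ValueError(f"need >= {frame_len} samples, got {n}")
    n_frames = (n - frame_len) // hop + 1
    sw = np.lib.stride_tricks.sliding_window_view(signal.data, frame_len, axis=0)
    frames = np.ascontiguousarray(sw[::hop][:n_frames].transpose(0, 2, 1))
    centers = signal.t0 + (np.arange(n_frames) * hop + frame_len / 2.0) / signal.rate
    return FrameArray(frames=frames, frame_times=centers, t0=signal.t0,
                      rate=signal.rate, hop=hop)


def preprocess(streams: dict[str, RawPacketStream], bias_removal: bool = True,
               rate: float = SAMPLE_RATE) -> FrameArray:
    """Full preprocessing pipeline: regularize -> de-bias -> median filter
    -> frame."""
    sig = build_uniform_signal(streams, rate=rate)
    if bias_removal:
        sig = remove_gyro_bias(sig)
    sig = median_filter7(sig)
    return make_frames(sig)
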