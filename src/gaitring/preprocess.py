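"""IMU recording I/O, band-pass filtering and the time-frequency representation.

A recording holds six synchronized channels from a lower-back (L5) inertial
measurement unit: three accelerations and three angular velocities, mapped
onto the anatomical axes — craniocaudal (CC, head-to-foot), mediolateral
(ML, left-right) and anteroposterior (AP, front-back).

Two channels drive the change-point segmentation: the craniocaudal angular
velocity ``gyr_cc`` (sensitive to turns) and the anteroposterior acceleration
``acc_ap`` (sensitive to gait onsets/offsets).  Each is standardized over the
whole recording and passed through a magnitude short-time Fourier transform
(3 s window, 0.1 s hop); the bins strictly inside (0, 5) Hz of both channels
are concatenated, giving a 28-dimensional frame vector (14 bins per channel
at 100 Hz: the 300-sample window has a 1/3 Hz bin spacing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: anatomical channel names, in canonical order
CHANNELS = ("acc_cc", "acc_ml", "acc_ap", "gyr_cc", "gyr_ml", "gyr_ap")

DEFAULT_AXIS_MAP = {"cc": "-y", "ml": "x", "ap": "z"}

STFT_WINDOW_S = 3.0
STFT_HOP_S = 0.1
BAND_HZ = (0.0, 5.0)  # open interval


@dataclass
class ImuRecording:
    """Six synchronized IMU channels in anatomical axes.

    Accelerations in g, angular velocities in deg/s.
    """

    sampling_rate_hz: float
    acc_cc: np.ndarray
    acc_ml: np.ndarray
    acc_ap: np.ndarray
    gyr_cc: np.ndarray
    gyr_ml: np.ndarray
    gyr_ap: np.ndarray
    t0: float = 0.0
    axis_map: dict = field(default_factory=lambda: dict(DEFAULT_AXIS_MAP))

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = {len(getattr(self, c)) for c in CHANNELS}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        for c in CHANNELS:
            setattr(self, c, np.asarray(getattr(self, c), dtype=float))

    @property
    def n_samples(self) -> int:
        return len(self.acc_cc)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channels(self) -> dict:
        return {c: getattr(self, c) for c in CHANNELS}

    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate_hz

    def slice_seconds(self, start_s: float, end_s: float) -> "ImuRecording":
        """Half-open [start_s, end_s) slice, relative to t0."""
        fs = self.sampling_rate_hz
        i0 = int(round(start_s * fs))
        i1 = int(round(end_s * fs))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError(f"empty slice [{start_s}, {end_s})")
        kw = {c: getattr(self, c)[i0:i1] for c in CHANNELS}
        return ImuRecording(
            sampling_rate_hz=fs, t0=self.t0 + i0 / fs, axis_map=dict(self.axis_map), **kw
        )


@dataclass
class SpectralSeries:
    """STFT magnitude frames consumed by the change-point solver.

    ``frames`` is an (n, d) matrix with d = 28: the first 14 columns come from
    the standardized craniocaudal angular velocity, the last 14 from the
    standardized anteroposterior acceleration.  ``frame_times_s`` maps each
    frame to the center time of its analysis window.
    """

    frames: np.ndarray
    frame_times_s: np.ndarray
    window_s: float = STFT_WINDOW_S
    hop_s: float = STFT_HOP_S
    band_hz: tuple = BAND_HZ

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be 2-D")
        if len(self.frame_times_s) != self.frames.shape[0]:
            raise ValueError("frame_times_s length mismatch")
        if np.any(self.frames < 0):
            raise ValueError("STFT magnitudes must be non-negative")

    @property
    def n(self) -> int:
        return self.frames.shape[0]

    @property
    def d(self) -> int:
        return self.frames.shape[1]


def _signed_column(df: pd.DataFrame, kind: str, spec: str) -> np.ndarray:
    sign = 1.0
    axis = spec
    if spec.startswith("-"):
        sign, axis = -1.0, spec[1:]
    elif spec.startswith("+"):
        axis = spec[1:]
    col = f"{kind}_{axis}"
    if col not in df.columns:
        raise ValueError(f"missing column {col!r}")
    return sign * df[col].to_numpy(dtype=float)


def read_imu_csv(path, axis_map: dict | None = None) -> ImuRecording:
    """Read a raw IMU CSV (columns time_s, acc_x..z, gyr_x..z).

    ``axis_map`` maps anatomical axes to signed device axes, e.g.
    ``{"cc": "-y", "ml": "x", "ap": "z"}``.  The sampling rate is inferred
    from the median time step and validated: all steps must lie within 1 %
    of the median.
    """
    axis_map = dict(axis_map or DEFAULT_AXIS_MAP)
    df = pd.read_csv(path)
    required = {"time_s", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column is not strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise ValueError("irregular sampling: time steps deviate >1% from median")
    kw = {}
    for anat in ("cc", "ml", "ap"):
        kw[f"acc_{anat}"] = _signed_column(df, "acc", axis_map[anat])
        kw[f"gyr_{anat}"] = _signed_column(df, "gyr", axis_map[anat])
    return ImuRecording(sampling_rate_hz=1.0 / med, t0=float(t[0]), axis_map=axis_map, **kw)


def write_imu_csv(rec: ImuRecording, path) -> None:
    """Inverse of :func:`read_imu_csv` under the recording's own axis map."""
    t = rec.times_s()
    cols = {"time_s": t}
    inv = {}  # device axis -> (sign, anatomical)
    for anat, spec in rec.axis_map.items():
        sign = -1.0 if spec.startswith("-") else 1.0
        axis = spec.lstrip("+-")
        inv[axis] = (sign, anat)
    for axis in ("x", "y", "z"):
        sign, anat = inv[axis]
        cols[f"acc_{axis}"] = sign * getattr(rec, f"acc_{anat}")
        cols[f"gyr_{axis}"] = sign * getattr(rec, f"gyr_{anat}")
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9f")


def bandpass(
    rec: ImuRecording, low_hz: float = 0.5, high_hz: float = 5.0, order: int = 4
) -> ImuRecording:
    """Zero-phase Butterworth band-pass of all six channels.

    The 4th-order filter is applied forward and backward (effective magnitude
    order 8, zero phase) so that autocorrelation peak lags downstream are not
    phase-distorted.
    """
    nyq = rec.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate_hz, output="sos")
    kw = {c: sps.sosfiltfilt(sos, getattr(rec, c)) for c in CHANNELS}
    return ImuRecording(
        sampling_rate_hz=rec.sampling_rate_hz, t0=rec.t0, axis_map=dict(rec.axis_map), **kw
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sd = x.std()
    if sd == 0:
        logger.warning("zero-variance channel: normalization skipped (zero-mean only)")
        return x - mu
    return (x - mu) / sd


def spectral_series(rec: ImuRecording) -> SpectralSeries:
    """Build the d=28 magnitude-STFT frame matrix from gCC and aAP.

    Each channel is standardized over the whole recording, windowed (Hann,
    3 s), hopped by 0.1 s, and reduced to the 14 bins with 0 < f < 5 Hz.
    Frame i covers samples [i*hop, i*hop + window); its time stamp is the
    window center, i*hop_s + window_s/2.
    """
    fs = rec.sampling_rate_hz
    win = int(round(STFT_WINDOW_S * fs))
    hop = int(round(STFT_HOP_S * fs))
    if rec.n_samples < win:
        raise ValueError(f"recording shorter than one {STFT_WINDOW_S} s window")
    n_frames = (rec.n_samples - win) // hop + 1
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    keep = (freqs > BAND_HZ[0]) & (freqs < BAND_HZ[1])
    window = sps.get_window("hann", win, fftbins=True)
    blocks = []
    for x in (rec.gyr_cc, rec.acc_ap):
        z = _standardize(np.asarray(x, dtype=float))
        idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
        segs = z[idx] * window[None, :]
        mag = np.abs(np.fft.rfft(segs, axis=1))[:, keep]
        blocks.append(mag)
    frames = np.concatenate(blocks, axis=1)
    times = STFT_WINDOW_S / 2.0 + STFT_HOP_S * np.arange(n_frames)
    return SpectralSeries(frames=frames, frame_times_s=times)


__all__ = [
    "CHANNELS",
    "DEFAULT_AXIS_MAP",
    "ImuRecording",
    "SpectralSeries",
    "read_imu_csv",
    "write_imu_csv",
    "bandpass",
    "spectral_series",
]
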