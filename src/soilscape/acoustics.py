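"""Spectrograms and the adapted Acoustic Complexity Index (ACI) for soil audio.

The ACI variant implemented here follows the adaptation used for buried
contact-microphone recordings: a magnitude spectrogram with rectangular,
non-overlapping windows; per frequency band and per 1-s "clump" the summed
absolute difference of adjacent frame intensities is divided by the summed
intensity; and the band x clump ratios are *averaged* (not summed, as in
Pieretti's original index), which bounds the result. Pure stationary noise
sits near ``2 - sqrt(2) ~ 0.586``; values below 0.55 are indistinguishable
from the amplifier noise floor and values above 0.90 are dominated by rain
or irrigation hitting the sensors, so only the 0.55-0.90 range is treated
as informative biophony.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import hilbert

__all__ = [
    "Recording",
    "Spectrogram",
    "AciResult",
    "read_wav",
    "write_wav",
    "compute_spectrogram",
    "compute_aci",
    "aci_of_recording",
    "filter_aci",
    "aggregate_aci",
    "compute_pretest_indices",
]


@dataclass
class Recording:
    """One timestamped mono audio clip from one sensor.

    ``samples`` are float amplitudes in [-1, 1]; ``rate`` in samples/second.
    """

    samples: np.ndarray
    rate: int
    start_time: pd.Timestamp
    sensor_id: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Recording must be mono (1-D samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Spectrogram:
    """Nonnegative band x frame intensity matrix with window/rate metadata."""

    intensity: np.ndarray  # (n_bands, n_frames), magnitudes >= 0
    band_hz: np.ndarray
    frame_times: np.ndarray
    window: int
    rate: int

    @property
    def n_bands(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]


@dataclass
class AciResult:
    """Per-clump ACI ratios and their average for one recording."""

    per_clump: np.ndarray  # (n_bands, n_clumps) of D / sum(I) ratios
    value: float
    valid: bool | None = None
    start_time: pd.Timestamp | None = None
    sensor_id: str | None = None


_WAV_NAME = re.compile(r"(?P<sensor>.+)_(?P<time>\d{8}T\d{6})\.wav$")


def write_wav(rec: Recording, directory: Path | str) -> Path:
    """Write a recording as 16-bit PCM mono WAV named ``<sensor>_<ISO8601>.wav``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stamp = rec.start_time.strftime("%Y%m%dT%H%M%S")
    path = directory / f"{rec.sensor_id}_{stamp}.wav"
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, int(rec.rate), pcm)
    return path


def read_wav(path: Path | str, sensor_id: str | None = None,
             start_time: pd.Timestamp | None = None) -> Recording:
    """Read a mono PCM WAV; sensor/time parsed from the filename if not given."""
    path = Path(path)
    m = _WAV_NAME.match(path.name)
    if sensor_id is None or start_time is None:
        if m is None:
            raise ValueError(
                f"cannot parse sensor/time from {path.name!r}; "
                "pass sensor_id and start_time explicitly")
        sensor_id = sensor_id or m.group("sensor")
        start_time = start_time or pd.Timestamp(m.group("time"))
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV is supported")
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        info = np.iinfo(data.dtype)
        samples = data.astype(float) / max(abs(info.min), info.max)
    return Recording(samples=samples, rate=rate,
                     start_time=start_time, sensor_id=sensor_id)


def compute_spectrogram(rec: Recording, window: int = 512) -> Spectrogram:
    """Magnitude spectrogram on non-overlapping rectangular windows.

    The DC bin is dropped so the band count is ``window / 2`` (Nyquist bin
    retained); a trailing partial window is discarded.  A 20.6848-s clip at
    50 kHz with the default window therefore yields 256 bands x 2020 frames.
    """
    if window < 2 or window & (window - 1):
        raise ValueError("window must be a power of two >= 2")
    n = len(rec.samples)
    if n < window:
        raise ValueError(f"recording ({n} samples) shorter than one window ({window})")
    n_frames = n // window
    frames = rec.samples[: n_frames * window].reshape(n_frames, window)
    spec = np.abs(np.fft.rfft(frames, axis=1))[:, 1:]  # drop DC
    freqs = np.fft.rfftfreq(window, d=1.0 / rec.rate)[1:]
    frame_times = (np.arange(n_frames) + 0.5) * window / rec.rate
    return Spectrogram(intensity=spec.T, band_hz=freqs,
                       frame_times=frame_times, window=window, rate=rec.rate)


def compute_aci(spec: Spectrogram, clump_seconds: float = 1.0) -> AciResult:
    """Averaged ACI over band x clump cells of a spectrogram.

    Per band k and clump c (``floor(clump_seconds * rate / window)`` frames,
    trailing short clump discarded)::

        d_j   = |I_j - I_{j+1}|          adjacent frames within the clump
        D     = sum_j d_j
        ratio = D / sum_j I_j            (0 when the clump-band is silent)

    The index is the arithmetic mean of all ratios, which replaces the
    summation of the original formulation and bounds the result in [0, 2).
    """
    frames_per_clump = int(clump_seconds * spec.rate) // spec.window
    if frames_per_clump < 2:
        raise ValueError("need at least 2 frames per clump; "
                         "increase clump_seconds or recording rate")
    n_clumps = spec.n_frames // frames_per_clump
    if n_clumps < 1:
        raise ValueError("spectrogram shorter than one clump")
    used = spec.intensity[:, : n_clumps * frames_per_clump]
    cells = used.reshape(spec.n_bands, n_clumps, frames_per_clump)
    d = np.abs(np.diff(cells, axis=2)).sum(axis=2)
    total = cells.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, d / np.where(total > 0, total, 1.0), 0.0)
    return AciResult(per_clump=ratio, value=float(ratio.mean()))


def aci_of_recording(rec: Recording, window: int = 512,
                     clump_seconds: float = 1.0) -> AciResult:
    """Spectrogram + ACI in one step, carrying sensor/time metadata."""
    res = compute_aci(compute_spectrogram(rec, window=window), clump_seconds)
    res.start_time = rec.start_time
    res.sensor_id = rec.sensor_id
    return res


def filter_aci(series: pd.DataFrame, low: float = 0.55,
               high: float = 0.90) -> pd.DataFrame:
    """Flag ACI records as valid when ``low <= aci <= high`` (inclusive).

    Values below ``low`` sit in the amplifier noise floor; values above
    ``high`` are rain/irrigation hitting the sensor. Expects columns
    ``sensor_id, time, aci``; returns a copy with a boolean ``valid`` column.
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    out = series.copy()
    if len(out) == 0:
        out["valid"] = pd.Series(dtype=bool)
        return out
    out["valid"] = (out["aci"] >= low) & (out["aci"] <= high)
    return out


def aggregate_aci(series: pd.DataFrame, hours: int = 6) -> pd.DataFrame:
    """Mean of valid ACI values per sensor per ``hours``-long interval.

    Intervals are anchored at midnight local time ([00-06), [06-12), ... for
    the default). Intervals with no valid record are absent from the output.
    """
    df = series.copy()
    if "valid" not in df.columns:
        df["valid"] = True
    df = df[df["valid"]]
    if len(df) == 0:
        return pd.DataFrame(columns=["sensor_id", "time", "aci", "n"])
    df = df.sort_values(["sensor_id", "time"])
    interval = pd.to_datetime(df["time"]).dt.floor(f"{hours}h")
    grouped = (df.assign(time=interval)
                 .groupby(["sensor_id", "time"], as_index=False)
                 .agg(aci=("aci", "mean"), n=("aci", "size")))
    return grouped


# ---------------------------------------------------------------------------
# Pre-test indices (used to select ACI in the first place)


def _gini(x: np.ndarray) -> float:
    """Gini coefficient of a nonnegative vector (0 = even, ->1 = concentrated)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    s = x.sum()
    if s == 0:
        return 0.0
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / s).sum()) / n)


def _envelope(rec: Recording) -> np.ndarray:
    return np.abs(hilbert(rec.samples))


def _temporal_entropy(env: np.ndarray) -> float:
    p = env / env.sum() if env.sum() > 0 else None
    if p is None:
        return 0.0
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(len(env)))


def compute_pretest_indices(recordings: Sequence[Recording],
                            db_threshold: float = -50.0,
                            max_freq: float = 10_000.0,
                            n_freq_bands: int = 10,
                            window: int = 512) -> pd.DataFrame:
    """AEI, AR and M for a batch of recordings.

    M is the median of the absolute amplitude envelope; AEI the Gini
    coefficient of per-band spectrogram occupancy above ``db_threshold``
    (relative to the clip maximum) over ``n_freq_bands`` equal bands up to
    ``max_freq``; AR the rank product of M and temporal entropy normalised
    by the squared batch size.  AR is rank-based, so it needs >= 2 clips.
    """
    recs = list(recordings)
    if len(recs) < 2:
        raise ValueError("AR is rank-based and needs at least 2 recordings")
    rows = []
    for rec in recs:
        env = _envelope(rec)
        m = float(np.median(env))
        ht = _temporal_entropy(env)
        spec = compute_spectrogram(rec, window=window)
        ref = spec.intensity.max()
        occupancy = np.zeros(n_freq_bands)
        if ref > 0:
            db = 20.0 * np.log10(np.maximum(spec.intensity, 1e-12) / ref)
            edges = np.linspace(0, max_freq, n_freq_bands + 1)
            idx = np.clip(np.digitize(spec.band_hz, edges) - 1, 0, n_freq_bands - 1)
            in_range = spec.band_hz <= max_freq
            for b in range(n_freq_bands):
                mask = in_range & (idx == b)
                occupancy[b] = (db[mask] > db_threshold).mean() if mask.any() else 0.0
        rows.append({"sensor_id": rec.sensor_id, "time": rec.start_time,
                     "M": m, "Ht": ht, "AEI": _gini(occupancy)})
    df = pd.DataFrame(rows)
    n = len(df)
    rank_m = df["M"].rank(method="average")
    rank_ht = df["Ht"].rank(method="average")
    df["AR"] = rank_m * rank_ht / n**2
    return df
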