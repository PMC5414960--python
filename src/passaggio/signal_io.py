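"""Input/output, core sampled-signal containers, config and logging.

All external data enters and leaves the pipeline through this module: WAV
files holding the time-synchronised acoustic and electroglottographic (EGG)
channels, CSV files holding the glottal area waveform (GAW) and the
medio-lateral displacement field extracted from segmented high-speed video,
and the perceptual rating table.

Conventions (fixed here, relied on everywhere else):

* CSV dialect: comma separator, ``.`` decimal, UTF-8, one header line.
* Frame/sample indices are 0-based; time of sample ``i`` is ``i / fs + t0``.
* EGG polarity: larger value = greater vocal-fold contact area. Files with
  inverted polarity are flipped on load (auto-detected from the skewness of
  the first difference: contacting is faster than de-contacting, so the
  derivative of a correctly polarised EGG is positively skewed).
* Displacement CSV: first column ``frame``, remaining columns glottal width
  per anterior-posterior position, anterior first (index 0).
"""

from __future__ import annotations

import logging
import sys
import uuid
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile
from scipy.stats import skew

__all__ = [
    "FormatError",
    "ChannelCountError",
    "SampledSignal",
    "EGGSignal",
    "GAWSeries",
    "DisplacementField",
    "RatingTable",
    "read_wav",
    "write_wav",
    "read_gaw_csv",
    "write_gaw_csv",
    "read_displacement_csv",
    "write_displacement_csv",
    "read_ratings_csv",
    "write_ratings_csv",
    "load_config",
    "setup_logging",
]

log = logging.getLogger("passaggio")


class FormatError(ValueError):
    """A file does not match the documented external format."""


class ChannelCountError(FormatError):
    """A WAV file has fewer channels than requested."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SampledSignal:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Signal values, arbitrary units.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Start-time offset in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs + self.t0


@dataclass
class EGGSignal(SampledSignal):
    """EGG contact signal; larger value = greater vocal-fold contact area.

    ``polarity_flipped`` records whether the raw file had inverted polarity
    and was flipped on load.
    """

    polarity_flipped: bool = False


@dataclass
class GAWSeries:
    """Glottal area waveform: projected glottal area per video frame."""

    area: np.ndarray
    fs_video: float
    t0: float = 0.0
    n_clipped: int = 0  # negative input samples clipped to 0 on load

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        if self.fs_video <= 0:
            raise ValueError("fs_video must be positive")
        if np.any(self.area < 0):
            raise ValueError("glottal area must be non-negative")

    @property
    def duration(self) -> float:
        return self.area.size / self.fs_video

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.area.size) / self.fs_video + self.t0

    def as_signal(self) -> SampledSignal:
        return SampledSignal(self.area, self.fs_video, self.t0)


@dataclass
class DisplacementField:
    """Glottal width as a function of (video frame, anterior-posterior position).

    ``width[f, p]`` is the medio-lateral glottal width (pixels) at frame ``f``
    and A-P position ``p``; position 0 is anterior.
    """

    width: np.ndarray
    fs_video: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.width = np.asarray(self.width, dtype=float)
        if self.width.ndim != 2:
            raise ValueError("width must be a (frame x position) matrix")
        if self.width.shape[1] < 3:
            raise ValueError("need at least 3 A-P positions")
        if np.any(self.width < 0):
            raise ValueError("glottal width must be non-negative")
        if self.fs_video <= 0:
            raise ValueError("fs_video must be positive")

    @property
    def n_positions(self) -> int:
        return self.width.shape[1]

    @property
    def n_frames(self) -> int:
        return self.width.shape[0]

    def gaw(self) -> GAWSeries:
        """Row-sum of the width field: the implied glottal area waveform."""
        return GAWSeries(self.width.sum(axis=1), self.fs_video, self.t0)


@dataclass
class RatingTable:
    """Perceptual register-event ratings: raters x stimuli, integers 1-5."""

    scores: pd.DataFrame  # index = rater ids, columns = stimulus labels

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if np.any(pd.isna(vals)):
            raise ValueError("rating table must have no missing cells")
        vals = vals.astype(float)
        if not np.allclose(vals, np.round(vals)) or vals.min() < 1 or vals.max() > 5:
            raise ValueError("ratings must be integers in 1..5")

    @property
    def n_raters(self) -> int:
        return self.scores.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------


def read_wav(
    path,
    egg_channel_index: int = 1,
    audio_channel_index: int = 0,
    normalize_polarity: bool = True,
) -> tuple[SampledSignal, EGGSignal]:
    """Read a time-synchronised acoustic + EGG recording from one WAV file.

    Both channels share the file's sampling rate and length. The EGG channel
    polarity is normalised so that vocal-fold contacting appears as positive
    peaks of the first derivative (auto-detected, see module docstring).
    """
    fs, data = wavfile.read(path)
    if fs <= 0:
        raise FormatError(f"{path}: non-positive sampling rate {fs}")
    data = np.atleast_2d(np.asarray(data).T).T  # (n_samples, n_channels)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    n_channels = data.shape[1]
    needed = max(egg_channel_index, audio_channel_index) + 1
    if n_channels < needed:
        raise ChannelCountError(
            f"{path}: has {n_channels} channel(s), need at least {needed}"
        )
    audio = SampledSignal(data[:, audio_channel_index], float(fs))
    egg_samples = data[:, egg_channel_index]
    flipped = False
    if normalize_polarity:
        d = np.diff(egg_samples)
        if d.any() and skew(d) < 0:
            egg_samples = -egg_samples
            flipped = True
            log.info("EGG polarity flipped on load (derivative skew < 0)")
    egg = EGGSignal(egg_samples, float(fs), polarity_flipped=flipped)
    return audio, egg


def write_wav(path, signals, fs: float) -> None:
    """Write one or more equally long signals as a float32 multichannel WAV."""
    arrays = [np.asarray(s, dtype=np.float32) for s in np.atleast_2d(signals)]
    data = np.stack(arrays, axis=1) if len(arrays) > 1 else arrays[0]
    wavfile.write(path, int(fs), data)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_gaw_csv(path) -> GAWSeries:
    """Read a glottal area waveform from a two-column CSV.

    Accepted headers: ``time_s,area`` or ``frame,area``. Sampling must be
    uniform (max jitter below half the frame period). Negative areas are
    clipped to 0 and counted in ``n_clipped``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    first = df.columns[0].strip().lower()
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    area = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise FormatError(f"{path}: {first} column must be strictly increasing")
    steps = np.diff(axis)
    dt = np.median(steps)
    if np.max(np.abs(steps - dt)) > 0.5 * dt:
        raise FormatError(f"{path}: non-uniform sampling (jitter > half period)")
    if first == "time_s":
        fs_video = 1.0 / dt
        t0 = axis[0]
    elif first == "frame":
        # frame-indexed files carry no rate; assume unit spacing = one frame
        fs_video = 1.0 / dt
        t0 = axis[0] * dt
        log.warning("%s: frame-indexed GAW, fs_video taken as 1/frame-step", path)
    else:
        raise FormatError(f"{path}: first column must be 'time_s' or 'frame'")
    n_clipped = int(np.sum(area < 0))
    if n_clipped:
        log.warning("%s: clipped %d negative area samples to 0", path, n_clipped)
        area = np.clip(area, 0.0, None)
    return GAWSeries(area, fs_video, t0=t0, n_clipped=n_clipped)


def write_gaw_csv(path, gaw: GAWSeries) -> None:
    pd.DataFrame({"time_s": gaw.times, "area": gaw.area}).to_csv(path, index=False)


def read_displacement_csv(path, fs_video: float | None = None) -> DisplacementField:
    """Read a medio-lateral displacement field CSV.

    First column ``frame`` (0-based), remaining columns widths at A-P
    positions anterior (index 0) to posterior. ``fs_video`` may be given in a
    ``# fs_video: <Hz>`` comment line (written by :func:`write_displacement_csv`)
    or passed explicitly.
    """
    header_fs = None
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "fs_video" in line:
                header_fs = float(line.split(":", 1)[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise FormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows (missing cells)")
    if df.columns[0].strip().lower() != "frame":
        raise FormatError(f"{path}: first column must be 'frame'")
    width = df.iloc[:, 1:].to_numpy(dtype=float)
    fs = fs_video if fs_video is not None else header_fs
    if fs is None:
        raise FormatError(f"{path}: fs_video not given and not in file header")
    return DisplacementField(width, float(fs))


def write_displacement_csv(path, field: DisplacementField) -> None:
    cols = [f"ap{p:03d}" for p in range(field.n_positions)]
    df = pd.DataFrame(field.width, columns=cols)
    df.insert(0, "frame", np.arange(field.n_frames))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs_video: {field.fs_video!r}\n")
        fh.write("# orientation: anterior = ap000\n")
        df.to_csv(fh, index=False)


def read_ratings_csv(path) -> RatingTable:
    """Read a rater x stimulus score table (first column = rater id)."""
    df = pd.read_csv(path, index_col=0)
    return RatingTable(df)


def write_ratings_csv(path, table: RatingTable) -> None:
    table.scores.to_csv(path, index_label="rater")


# ---------------------------------------------------------------------------
# Config & logging
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "fo_min": 150.0,
    "fo_max": 1200.0,
    "highpass_hz": 20.0,
    "degg_smooth_ms": 0.5,
    "n_resample": 64,
    "normalization": "pp",
    "sampen_m": 2,
    "sampen_r": 0.2,
    "sampen_r_floor": 0.05,
    "block_len": 40,
    "window_len": 0.025,
    "open_threshold_frac": 0.02,
    "open_threshold_px": 0.5,
    "wavegram_rows": 256,
    "icc_form": "ICC2k",
}


def load_config(path=None) -> dict:
    """Read a YAML config file once per run; unknown keys are rejected."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def setup_logging(level: int = logging.INFO, run_id: str | None = None) -> str:
    """Configure structured logging to stderr, tagged with a run id."""
    rid = run_id or uuid.uuid4().hex[:8]
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter(f"%(asctime)s [{rid}] %(name)s %(levelname)s: %(message)s")
    )
    root = logging.getLogger("passaggio")
    root.handlers[:] = [handler]
    root.setLevel(level)
    return rid
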