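"""Glottal-cycle detection from the EGG signal via its first derivative (dEGG).

The positive peaks of the dEGG mark vocal-fold contacting events, the
standard landmark for separating the EGG into glottal cycles. The resulting
:class:`CycleSegmentation` is the backbone every cycle-based measure hangs
on: Fourier-descriptor sample entropy, wavegrams, and the window alignment
shared with the glottal-area analysis.

Processing choices (the underlying physiology fixes none of these exactly):

* The EGG is high-pass filtered at 20 Hz (4th-order Butterworth, zero phase)
  to remove electrode drift before differentiation.
* Peak candidates must exceed 20% of the 95th-percentile dEGG amplitude in a
  50 ms neighbourhood, which keeps detection robust across the 4x fo sweep
  of a one-second pitch glide. For detection the dEGG is usually
  moving-average smoothed (~0.5 ms) — differentiation amplifies measurement
  noise by fs, and peak *position* accuracy does not depend on it (below).
* Boundary positions are refined to sub-sample precision: parabolic
  interpolation of the dEGG peak (plus the half-sample offset of the forward
  difference), then — when the EGG itself is supplied — the upward crossing
  of the local amplitude midline on the contacting flank. The crossing lies
  where the slope is steepest, so its position is nearly immune to sampling
  phase and noise; this keeps per-cycle resampling phase-stable and shape
  descriptors of a shape-constant signal constant to interpolation error.
* A frame-wise normalized-autocorrelation voicing gate rejects aperiodic
  input (e.g. white noise, silence) that amplitude and spacing rules alone
  cannot distinguish from phonation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .signal_io import EGGSignal, SampledSignal

__all__ = [
    "UnvoicedError",
    "DEGGSignal",
    "CycleSegmentation",
    "precondition_egg",
    "compute_degg",
    "detect_cycles",
    "extract_cycles",
]


class UnvoicedError(RuntimeError):
    """The signal contains no (or too little) periodic phonation."""


@dataclass
class DEGGSignal(SampledSignal):
    """First derivative of the (optionally smoothed) EGG, scaled by fs.

    One sample shorter than its source EGG; sample ``i`` sits between source
    samples ``i`` and ``i+1``.
    """


@dataclass
class CycleSegmentation:
    """Cycle-start boundaries (vocal-fold contacting events) and per-cycle fo.

    ``boundaries`` are sample positions (float, sub-sample precision) in the
    source signal; cycle ``i`` spans ``[boundaries[i], boundaries[i+1])``.
    ``valid`` flags cycles whose fo lies within the configured bounds; all
    downstream cycle-based measures use valid cycles only.
    """

    boundaries: np.ndarray
    source_fs: float
    t0: float = 0.0
    fo_min: float = 150.0
    fo_max: float = 1200.0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.valid is None:
            fo = self.fo_per_cycle_raw
            self.valid = (fo >= self.fo_min) & (fo <= self.fo_max)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    @property
    def fo_per_cycle_raw(self) -> np.ndarray:
        """fs / period for every inter-boundary interval, valid or not."""
        return self.source_fs / np.diff(self.boundaries)

    @property
    def fo_per_cycle(self) -> np.ndarray:
        """fo of the valid cycles only."""
        return self.fo_per_cycle_raw[self.valid]

    @property
    def starts(self) -> np.ndarray:
        return self.boundaries[:-1][self.valid]

    @property
    def ends(self) -> np.ndarray:
        return self.boundaries[1:][self.valid]

    @property
    def midpoint_times(self) -> np.ndarray:
        """Midpoint time (s) of each valid cycle."""
        return (self.starts + self.ends) / 2.0 / self.source_fs + self.t0

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def precondition_egg(egg: EGGSignal, highpass_hz: float = 20.0, order: int = 4) -> EGGSignal:
    """High-pass filter the EGG (zero-phase Butterworth) to remove drift.

    Uses even-reflection padding over ~3 filter time constants: the default
    odd reflection inverts the contact pulses in the padding, and the
    resulting low-frequency edge transient bleeds into the first/last cycles'
    shapes.
    """
    sos = butter(order, highpass_hz, btype="highpass", fs=egg.fs, output="sos")
    padlen = min(egg.samples.size - 1, int(3 * egg.fs / highpass_hz))
    filtered = sosfiltfilt(sos, egg.samples, padtype="even", padlen=padlen)
    return EGGSignal(filtered, egg.fs, egg.t0,
                     polarity_flipped=egg.polarity_flipped)


def compute_degg(egg: EGGSignal, smoothing_len: int = 1) -> DEGGSignal:
    """First difference of the (moving-average smoothed) EGG, scaled by fs.

    ``smoothing_len`` must be odd and >= 1; 1 means no smoothing. Contacting
    events appear as positive peaks under the normalised polarity.
    """
    if smoothing_len < 1 or smoothing_len % 2 == 0:
        raise ValueError("smoothing_len must be odd and >= 1")
    x = egg.samples
    if x.size <= smoothing_len:
        raise ValueError("signal shorter than smoothing window")
    if smoothing_len > 1:
        kernel = np.full(smoothing_len, 1.0 / smoothing_len)
        x = np.convolve(x, kernel, mode="same")
    d = np.diff(x) * egg.fs
    return DEGGSignal(d, egg.fs, egg.t0)


# ---------------------------------------------------------------------------
# Voicing gate
# ---------------------------------------------------------------------------


def _voiced_mask(
    x: np.ndarray,
    fs: float,
    fo_min: float,
    fo_max: float,
    frame_len_s: float = 0.05,
    hop_s: float = 0.0125,
    r_threshold: float = 0.5,
) -> np.ndarray:
    """Per-sample boolean mask of locally periodic regions.

    A frame is voiced when the maximum of its normalized autocorrelation over
    lags [fs/fo_max, fs/fo_min] exceeds ``r_threshold`` and the frame carries
    non-negligible energy relative to the whole signal.
    """
    n = x.size
    flen = max(int(frame_len_s * fs), int(2.5 * fs / fo_min))
    hop = max(int(hop_s * fs), 1)
    lag_lo = max(int(fs / fo_max), 1)
    lag_hi = min(int(np.ceil(fs / fo_min)), flen - 2)
    global_rms = np.sqrt(np.mean(x**2))
    mask = np.zeros(n, dtype=bool)
    starts = list(range(0, max(n - flen, 0) + 1, hop))
    if starts and starts[-1] != n - flen:
        starts.append(n - flen)  # keep the tail covered
    for start in starts:
        frame = x[start : start + flen]
        frame = frame - frame.mean()
        e = np.sqrt(np.mean(frame**2))
        if e < 0.05 * global_rms or e == 0.0:
            continue
        ac = np.correlate(frame, frame, mode="full")[flen - 1 :]
        denom = ac[0]
        if denom <= 0:
            continue
        r = ac[lag_lo : lag_hi + 1] / denom
        if r.size and r.max() > r_threshold:
            mask[start : start + flen] = True
    return mask


def _parabolic_refine(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample peak positions by fitting a parabola through 3 points."""
    idx = np.asarray(idx)
    pos = idx.astype(float)
    inner = (idx > 0) & (idx < x.size - 1)
    i = idx[inner]
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    shift = np.zeros(i.size)
    ok = denom < 0  # genuine local maximum
    shift[ok] = 0.5 * (x[i - 1] - x[i + 1])[ok] / denom[ok]
    pos[inner] += np.clip(shift, -0.5, 0.5)
    return pos


def adaptive_positive_peaks(
    x: np.ndarray,
    fs: float,
    fo_min: float,
    fo_max: float,
    rel_threshold: float = 0.2,
    neighbourhood_s: float = 0.05,
) -> np.ndarray:
    """Positive peaks exceeding ``rel_threshold`` x local 95th percentile.

    Candidates closer than one period at ``fo_max`` are resolved by
    ``find_peaks``'s distance rule, which keeps the larger peak.
    """
    min_dist = max(int(fs / fo_max), 1)
    peaks, _ = find_peaks(x, distance=min_dist)
    if peaks.size == 0:
        return peaks
    half = max(int(neighbourhood_s * fs / 2), 1)
    local95 = np.array(
        [np.percentile(x[max(p - half, 0) : p + half + 1], 95) for p in peaks]
    )
    return peaks[(x[peaks] > 0) & (x[peaks] > rel_threshold * local95)]


def _crossing_refine(egg_samples: np.ndarray, peaks: np.ndarray,
                     boundaries: np.ndarray) -> np.ndarray:
    """Refine boundaries to the EGG midline crossing on the contacting flank.

    For each contacting event, the EGG crosses the midpoint between its local
    minimum and maximum (within slightly less than half a period on either
    side) while rising at maximum slope; linear interpolation of that
    crossing locates the event far more precisely than the broad dEGG peak.
    Events without an upward crossing keep their dEGG-peak position.
    """
    e = egg_samples
    out = boundaries.copy()
    gaps = np.diff(peaks)
    if gaps.size == 0:
        return out
    for k, p in enumerate(peaks):
        left = gaps[k - 1] if k > 0 else gaps[0]
        right = gaps[k] if k < gaps.size else gaps[-1]
        h = max(int(0.45 * min(left, right)), 2)
        lo, hi = max(p - h, 0), min(p + h + 1, e.size)
        win = e[lo:hi]
        level = 0.5 * (win.min() + win.max())
        up = np.flatnonzero((win[:-1] < level) & (win[1:] >= level))
        if up.size:
            i = up[np.argmin(np.abs(up + lo - p))]
            out[k] = lo + i + (level - win[i]) / (win[i + 1] - win[i])
    return out


def detect_cycles(
    degg: DEGGSignal,
    fo_min: float = 150.0,
    fo_max: float = 1200.0,
    egg: EGGSignal | None = None,
) -> CycleSegmentation:
    """Detect cycle boundaries as positive dEGG peaks (contacting events).

    When the source EGG is supplied, boundary positions are refined to the
    midline crossing of the contacting flank (noise- and sampling-robust).
    Raises :class:`UnvoicedError` when the signal is aperiodic or yields
    fewer than 3 cycles with fo inside ``[fo_min, fo_max]``.
    """
    if not 20 < fo_min < fo_max < 2000:
        raise ValueError("need 20 < fo_min < fo_max < 2000 Hz")
    x = degg.samples
    voiced = _voiced_mask(x, degg.fs, fo_min, fo_max)
    if not voiced.any():
        raise UnvoicedError("no periodic phonation found")
    peaks = adaptive_positive_peaks(x, degg.fs, fo_min, fo_max)
    peaks = peaks[voiced[peaks]]
    if peaks.size >= 2:
        # edge events whose refinement window would be truncated by the
        # signal boundary carry unreliable sub-sample positions; drop them
        gap0, gap1 = peaks[1] - peaks[0], peaks[-1] - peaks[-2]
        keep = (peaks >= 0.5 * gap0) & (peaks <= x.size - 1 - 0.5 * gap1)
        peaks = peaks[keep]
    if peaks.size < 4:
        raise UnvoicedError(f"only {peaks.size} contacting events detected")
    # +0.5: the forward difference estimates the derivative between samples
    boundaries = _parabolic_refine(x, peaks) + 0.5
    if egg is not None:
        boundaries = _crossing_refine(egg.samples, peaks, boundaries)
    seg = CycleSegmentation(boundaries, degg.fs, degg.t0, fo_min=fo_min, fo_max=fo_max)
    if seg.n_valid < 3:
        raise UnvoicedError(
            f"only {seg.n_valid} cycles with fo in [{fo_min}, {fo_max}] Hz"
        )
    return seg


def extract_cycles(
    egg: EGGSignal,
    seg: CycleSegmentation,
    n_resample: int = 64,
    normalization: str = "pp",
) -> np.ndarray:
    """Resample each valid cycle to ``n_resample`` points and normalise it.

    Normalisation modes: ``"pp"`` (zero mean, unit peak-to-peak — the
    default, making downstream descriptors shape-only), ``"zscore"``, or
    ``"none"``. Resampling uses a cubic spline (linear interpolation leaves
    an fo-dependent shape bias that masquerades as cycle-shape change).
    Returns a (n_valid_cycles, n_resample) matrix.
    """
    if n_resample < 16:
        raise ValueError("n_resample must be >= 16")
    if normalization not in ("pp", "zscore", "none"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    from scipy.interpolate import CubicSpline

    x = egg.samples
    spline = CubicSpline(np.arange(x.size, dtype=float), x)
    out = np.empty((seg.n_valid, n_resample))
    # sample at n_resample points across [start, end), cycle-periodic grid
    frac = np.arange(n_resample) / n_resample
    for row, (s, e) in enumerate(zip(seg.starts, seg.ends)):
        cyc = spline(s + frac * (e - s))
        if normalization == "pp":
            pp = cyc.max() - cyc.min()
            cyc = (cyc - cyc.mean()) / pp if pp > 0 else cyc - cyc.mean()
        elif normalization == "zscore":
            sd = cyc.std()
            cyc = (cyc - cyc.mean()) / sd if sd > 0 else cyc - cyc.mean()
        out[row] = cyc
    return out
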