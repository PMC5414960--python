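"""Fourier-descriptor sample entropy of the cycle-separated EGG signal.

Each normalised EGG cycle is compressed into a "Fourier Descriptor": the
first two DFT components (real and imaginary parts, a 4-D real vector). A
shape-stable voice yields a near-constant descriptor sequence; register
events perturb it. Sample entropy of the descriptor sequence — the negative
natural log of the conditional probability that sequences similar for ``m``
points remain similar at point ``m+1``, self-matches excluded, max-norm
similarity — quantifies that instability per cycle (FDSE_c). Averaging the
per-cycle values over consecutive 25 ms segments gives the window-based
FDSE_w, whose global maximum anchors the 11-window (-5..+5) alignment used
by every per-window measure in the pipeline.

Because the descriptors are computed on cycle-normalised waveforms, the
measure is insensitive to fo changes per se: a pitch glide with a fixed
cycle shape scores (numerically) zero entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .egg_cycles import CycleSegmentation

__all__ = [
    "FDSeries",
    "SampleEntropyParams",
    "EntropyTrace",
    "WindowSet",
    "fourier_descriptors",
    "sample_entropy",
    "fdse_cycle_trace",
    "fdse_windows",
    "max_fdse_w",
]

N_WINDOWS = 11  # windows -5 .. +5
HALF_SPAN = 5


@dataclass
class FDSeries:
    """Per-cycle Fourier descriptors (re1, im1, re2, im2) and cycle midpoints."""

    descriptors: np.ndarray  # (n_cycles, 4)
    cycle_times: np.ndarray  # (n_cycles,) seconds

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        self.cycle_times = np.asarray(self.cycle_times, dtype=float)
        if self.descriptors.shape[0] != self.cycle_times.shape[0]:
            raise ValueError("descriptor count must equal cycle-time count")
        if not np.all(np.isfinite(self.descriptors)):
            raise ValueError("descriptors must be finite")


@dataclass
class SampleEntropyParams:
    """Sample-entropy settings.

    m : embedding length (template points).
    r : tolerance as a fraction of the per-component SD of the series.
    r_floor : absolute tolerance floor as a fraction of the RMS descriptor
        magnitude. Guards against spurious entropy when the series is
        essentially constant and its SD is dominated by numerical
        (resampling/quantisation) jitter rather than signal change.
    """

    m: int = 2
    r: float = 0.2
    r_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.r < 1:
            raise ValueError("r must be in (0, 1)")
        if self.r_floor < 0:
            raise ValueError("r_floor must be >= 0")


@dataclass
class EntropyTrace:
    """Cycle-based sample entropy over a sliding block of cycles (FDSE_c).

    ``values[i]`` is the sample entropy of descriptors
    ``i .. i+block_len-1``, assigned to the block-centre cycle whose midpoint
    is ``times[i]``. Undefined entries (no template matches) are NaN.
    """

    values: np.ndarray
    times: np.ndarray
    block_len: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.nanmin(v, initial=0.0) < 0:
            raise ValueError("sample entropy cannot be negative")
        self.values = v
        self.times = np.asarray(self.times, dtype=float)


@dataclass
class WindowSet:
    """Eleven aligned 25 ms analysis windows centred on maximum FDSE_w.

    ``indices`` run -5..+5; window ``i`` spans
    ``[starts[i], starts[i] + window_len)``. ``missing`` flags windows that
    fell outside the phonation (alignment clamped at an edge) or contained no
    defined entropy values. The full scan grid is kept for diagnostics.
    """

    window_len: float
    starts: np.ndarray  # (11,)
    fdse_w: np.ndarray  # (11,), NaN where missing
    missing: np.ndarray  # (11,) bool
    center_grid_index: int  # index of window 0 in the full segment grid
    grid_starts: np.ndarray = field(repr=False, default=None)  # type: ignore
    grid_values: np.ndarray = field(repr=False, default=None)  # type: ignore
    indices: np.ndarray = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.indices is None:
            self.indices = np.arange(-HALF_SPAN, HALF_SPAN + 1)
        if len(self.starts) != N_WINDOWS or len(self.fdse_w) != N_WINDOWS:
            raise ValueError(f"a WindowSet has exactly {N_WINDOWS} windows")

    @property
    def center_time(self) -> float:
        """Start time (s) of window 0."""
        return float(self.starts[HALF_SPAN])

    def interval(self, index: int) -> tuple[float, float]:
        """Half-open [t_start, t_end) of window ``index`` (-5..+5)."""
        s = float(self.starts[index + HALF_SPAN])
        return s, s + self.window_len


def fourier_descriptors(
    cycles: np.ndarray, cycle_times: np.ndarray, phase_normalize: bool = True
) -> FDSeries:
    """First two DFT components of each normalised cycle.

    The DFT is scaled by 1/n so a cycle ``cos(2*pi*t/T)`` maps to the
    descriptor (0.5, 0, 0, 0); the DC term is dropped (cycles are zero-mean
    by construction).

    By default the descriptors are phase-normalised: both components are
    rotated by the first harmonic's phase (component k by k times it), the
    standard rotation-invariant Fourier-descriptor form. This makes the
    descriptor exactly invariant to where within the cycle the boundary
    landmark sits, so residual sub-sample jitter of cycle detection cannot
    masquerade as shape change; the relative phase between the two harmonics
    — the shape information — is fully retained in components 3 and 4
    (component 2 becomes identically 0).
    """
    cycles = np.asarray(cycles, dtype=float)
    spec = np.fft.rfft(cycles, axis=1) / cycles.shape[1]
    x1, x2 = spec[:, 1], spec[:, 2]
    if phase_normalize:
        phi = np.angle(x1)
        x1 = x1 * np.exp(-1j * phi)
        x2 = x2 * np.exp(-2j * phi)
    fd = np.column_stack([x1.real, x1.imag, x2.real, x2.imag])
    return FDSeries(fd, cycle_times)


def _tolerances(x: np.ndarray, params: SampleEntropyParams) -> np.ndarray:
    """Per-component similarity tolerances: max(r * SD, floor)."""
    sd = x.std(axis=0)
    scale = np.sqrt(np.mean(x**2))
    tol = np.maximum(params.r * sd, params.r_floor * scale)
    return np.where(tol > 0, tol, np.finfo(float).tiny)


def sample_entropy(series: np.ndarray, params: SampleEntropyParams) -> float:
    """Sample entropy of a (possibly vector-valued) series.

    -ln(A/B) with B the number of template pairs (i < j) similar over m
    consecutive points and A those still similar at point m+1; self-matches
    excluded; similarity is the max-norm over components and offsets with
    per-component tolerance r x SD (floored, see
    :class:`SampleEntropyParams`). Returns NaN (undefined) when no template
    pair matches (B = 0) or no match survives extension (A = 0).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    m = params.m
    if n <= m + 1:
        return float("nan")
    tol = _tolerances(x, params)
    # point-similarity matrix under per-component tolerance
    sim = np.all(np.abs(x[:, None, :] - x[None, :, :]) <= tol, axis=2)
    nt = n - m  # number of templates of length m that can be extended
    match_m = np.ones((nt, nt), dtype=bool)
    for a in range(m):
        match_m &= sim[a : a + nt, a : a + nt]
    match_m1 = match_m & sim[m : m + nt, m : m + nt]
    iu = np.triu_indices(nt, k=1)
    b = int(match_m[iu].sum())
    a_cnt = int(match_m1[iu].sum())
    if b == 0 or a_cnt == 0:
        return float("nan")
    return float(-np.log(a_cnt / b))


def fdse_cycle_trace(
    fds: FDSeries, params: SampleEntropyParams, block_len: int = 40
) -> EntropyTrace:
    """FDSE_c: sample entropy over a sliding block of descriptor vectors.

    ``block_len`` consecutive descriptors per block, hop 1; the value is
    assigned to the block-centre cycle. Trace length is
    ``n_cycles - block_len + 1``; undefined blocks propagate as NaN.
    """
    if block_len <= params.m + 1:
        raise ValueError("block_len must exceed m + 1")
    n = fds.descriptors.shape[0]
    n_blocks = n - block_len + 1
    if n_blocks < 1:
        raise ValueError(f"need at least {block_len} cycles, got {n}")
    values = np.empty(n_blocks)
    for i in range(n_blocks):
        values[i] = sample_entropy(fds.descriptors[i : i + block_len], params)
    centre = block_len // 2
    times = fds.cycle_times[centre : centre + n_blocks]
    return EntropyTrace(values, times, block_len)


def fdse_windows(
    trace: EntropyTrace,
    seg: CycleSegmentation,
    window_len: float = 0.025,
) -> WindowSet:
    """Mean FDSE_c over consecutive ``window_len`` segments; align 11 windows.

    The whole phonation is divided into consecutive segments anchored at the
    signal start; FDSE_w of a segment is the mean of the defined (non-NaN)
    FDSE_c values of cycles whose midpoints fall inside it. The segment with
    the global maximum (earliest on ties) becomes window 0; the 5 segments on
    either side complete the -5..+5 window set. Windows clamped off either
    edge of the phonation are flagged missing.
    """
    t_start = seg.t0
    duration = seg.boundaries[-1] / seg.source_fs + seg.t0 - t_start
    n_seg = int(np.ceil(duration / window_len - 1e-9))  # partial tail counts
    if n_seg < 1:
        raise ValueError("phonation shorter than one analysis window")
    grid_starts = t_start + np.arange(n_seg) * window_len
    which = np.floor((trace.times - t_start) / window_len).astype(int)
    grid_values = np.full(n_seg, np.nan)
    for s in range(n_seg):
        vals = trace.values[which == s]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            grid_values[s] = vals.mean()
    if not np.any(np.isfinite(grid_values)):
        raise ValueError("no segment has a defined FDSE_w value")
    centre = int(np.nanargmax(grid_values))  # earliest max on ties
    idx = centre + np.arange(-HALF_SPAN, HALF_SPAN + 1)
    inside = (idx >= 0) & (idx < n_seg)
    starts = t_start + idx * window_len  # defined even when clamped
    fdse_w = np.full(N_WINDOWS, np.nan)
    fdse_w[inside] = grid_values[idx[inside]]
    missing = ~inside | ~np.isfinite(fdse_w)
    return WindowSet(
        window_len=window_len,
        starts=starts,
        fdse_w=fdse_w,
        missing=missing,
        center_grid_index=centre,
        grid_starts=grid_starts,
        grid_values=grid_values,
    )


def max_fdse_w(ws: WindowSet) -> float:
    """The maximum window-based entropy: FDSE_w at window 0."""
    return float(ws.fdse_w[HALF_SPAN])
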