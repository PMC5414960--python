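"""Open-quotient statistics from the glottal area waveform (GAW).

The open quotient (OQ) of a glottal cycle is the time-normalised fraction of
the cycle during which the glottis is open. Here it is computed from the
segmented-video GAW: a sample counts as open when the area exceeds the cycle
minimum by a small fraction of the cycle's peak-to-peak range (segmentation
noise makes exact zero unreliable; the baseline is per-cycle because
endoscope drift moves the apparent closed-glottis area).

The per-window statistics reuse the 11-window alignment derived from the EGG
entropy analysis: mean OQ per window, the ten between-window differences
(delta OQ), and their standard deviation — the scalar summarising how
unevenly a singer's glottal configuration moves through the passaggio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .egg_cycles import CycleSegmentation, UnvoicedError, adaptive_positive_peaks
from .fdse import HALF_SPAN, N_WINDOWS, WindowSet
from .signal_io import GAWSeries

__all__ = ["OQTrace", "gaw_cycles", "open_quotient", "window_oq"]


@dataclass
class OQTrace:
    """Per-cycle and (after :func:`window_oq`) per-window open quotients."""

    oq_per_cycle: np.ndarray  # in [0, 1], NaN for degenerate cycles
    cycle_times: np.ndarray  # cycle midpoints, s
    oq_per_window: Optional[np.ndarray] = None  # (11,), NaN = missing
    delta_oq: Optional[np.ndarray] = None  # (10,) between-window differences
    sd_delta_oq: Optional[float] = None

    def __post_init__(self) -> None:
        oq = np.asarray(self.oq_per_cycle, dtype=float)
        defined = np.isfinite(oq)
        if np.any((oq[defined] < 0) | (oq[defined] > 1)):
            raise ValueError("open quotient must lie in [0, 1]")
        self.oq_per_cycle = oq


def gaw_cycles(
    gaw: GAWSeries, fo_min: float = 150.0, fo_max: float = 1200.0
) -> CycleSegmentation:
    """Cycle segmentation native to the GAW (video clock).

    Boundaries are placed at the area minimum preceding each opening: the
    last frame of the closed plateau (area within 2% of the inter-peak
    minimum) before the next area peak, so each cycle starts just before its
    opening and every closure falls strictly inside its cycle. Same fo
    bounds and conflict rules as the EGG-based detector. Used when the video
    and EGG clocks are not shared.
    """
    if not 20 < fo_min < fo_max < 2000:
        raise ValueError("need 20 < fo_min < fo_max < 2000 Hz")
    x = gaw.area
    peaks = adaptive_positive_peaks(x - x.mean(), gaw.fs_video, fo_min, fo_max)
    if peaks.size < 4:
        raise UnvoicedError(f"only {peaks.size} area peaks detected")
    boundaries = np.empty(peaks.size - 1)
    for i in range(peaks.size - 1):
        lo, hi = peaks[i], peaks[i + 1]
        seg_x = x[lo:hi]
        level = seg_x.min() + 0.02 * (seg_x.max() - seg_x.min())
        boundaries[i] = lo + int(np.flatnonzero(seg_x <= level)[-1])
    seg = CycleSegmentation(
        boundaries, gaw.fs_video, gaw.t0, fo_min=fo_min, fo_max=fo_max
    )
    if seg.n_valid < 3:
        raise UnvoicedError(
            f"only {seg.n_valid} cycles with fo in [{fo_min}, {fo_max}] Hz"
        )
    return seg


def open_quotient(
    gaw: GAWSeries,
    seg: CycleSegmentation,
    open_threshold_frac: float = 0.02,
) -> OQTrace:
    """Per-cycle open quotient of the GAW.

    ``OQ = (# samples with area > baseline + frac * peak-to-peak) / cycle
    length``, baseline = cycle minimum. Degenerate cycles (zero peak-to-peak)
    yield NaN.
    """
    if not 0 <= open_threshold_frac < 0.2:
        raise ValueError("open_threshold_frac must lie in [0, 0.2)")
    x = gaw.area
    oq = np.empty(seg.n_valid)
    for i, (s, e) in enumerate(zip(seg.starts, seg.ends)):
        lo, hi = int(np.round(s)), int(np.round(e))
        cyc = x[lo:hi]
        base = cyc.min()
        pp = cyc.max() - base
        if pp <= 0:
            oq[i] = np.nan
        else:
            oq[i] = np.mean(cyc > base + open_threshold_frac * pp)
    return OQTrace(oq, seg.midpoint_times)


def window_oq(oq: OQTrace, ws: WindowSet) -> OQTrace:
    """Per-window mean OQ over the 11 aligned windows, deltas and their SD.

    A cycle contributes to the window containing its midpoint (the same rule
    the entropy windows use). Windows without cycles — or flagged missing by
    the alignment — stay NaN; deltas touching a missing window are NaN and
    excluded pairwise from the standard deviation (sample SD, ddof = 1).
    """
    per_window = np.full(N_WINDOWS, np.nan)
    for k in range(N_WINDOWS):
        if ws.missing[k]:
            continue
        t0, t1 = ws.interval(k - HALF_SPAN)
        sel = (oq.cycle_times >= t0) & (oq.cycle_times < t1)
        vals = oq.oq_per_cycle[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            per_window[k] = vals.mean()
    delta = np.diff(per_window)
    defined = np.isfinite(delta)
    sd = float(np.std(delta[defined], ddof=1)) if defined.sum() >= 2 else float("nan")
    return OQTrace(
        oq.oq_per_cycle,
        oq.cycle_times,
        oq_per_window=per_window,
        delta_oq=delta,
        sd_delta_oq=sd,
    )
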