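"""Spatio-temporal glottal opening/closing contours.

For every position along the anterior-posterior (A-P) glottal midline, the
local medio-lateral width trajectory leaves zero when that part of the
glottis opens and returns to zero when it closes. Collecting these two
instants per cycle and position, normalising them by the cycle duration, and
averaging them per analysis window yields two contours across the A-P axis:
the (earlier) opening contour and the (later) closing contour. Together they
summarise how the glottal opening travels along the folds — e.g. a "zipper"
opening shows as a sloped opening contour.

"Zero" is operationalised as width <= a small pixel threshold (segmentation
quantisation makes exact zero unreliable). Positions that never open in a
cycle contribute a missing pair; positions open throughout contribute (0, 1)
with a never-closed flag. Missing pairs are skipped, never interpolated, and
per-position coverage is reported so sparse positions stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .egg_cycles import CycleSegmentation
from .fdse import HALF_SPAN, N_WINDOWS, WindowSet
from .signal_io import DisplacementField

__all__ = [
    "OpenCloseInstants",
    "ContourPair",
    "local_open_close_instants",
    "normalize_and_average",
    "contour_summary_metrics",
]


@dataclass
class OpenCloseInstants:
    """Per-cycle, per-position opening/closing instants, in frames.

    ``open_frames[c, p]`` / ``close_frames[c, p]`` are frame offsets from the
    start of cycle ``c`` (NaN where the position never opened);
    ``never_closed[c, p]`` marks positions open at the cycle end.
    ``cycle_len`` holds each cycle's duration in frames.
    """

    open_frames: np.ndarray
    close_frames: np.ndarray
    never_closed: np.ndarray
    cycle_len: np.ndarray
    cycle_times: np.ndarray  # cycle midpoints, s


@dataclass
class ContourPair:
    """Averaged normalised opening/closing contours for one analysis window."""

    positions: np.ndarray
    open_contour: np.ndarray  # normalised intra-cycle time, NaN = missing
    close_contour: np.ndarray
    coverage: np.ndarray  # cycles contributing per position
    never_closed_rate: np.ndarray  # fraction of contributing cycles flagged
    window_index: int  # -5 .. +5

    def __post_init__(self) -> None:
        both = np.isfinite(self.open_contour) & np.isfinite(self.close_contour)
        o, c = self.open_contour[both], self.close_contour[both]
        if np.any(o < 0) or np.any(c > 1) or np.any(o > c):
            raise ValueError("need 0 <= open <= close <= 1 wherever defined")


def local_open_close_instants(
    field: DisplacementField,
    seg: CycleSegmentation,
    open_threshold: float = 0.5,
) -> OpenCloseInstants:
    """First crossing of the width above/below ``open_threshold`` per cycle.

    Opening instant: first frame of the cycle with width > threshold;
    closing instant: first subsequent frame with width <= threshold (= cycle
    length, flagged never-closed, if none). Positions that never open yield
    missing (NaN) pairs.
    """
    if open_threshold < 0:
        raise ValueError("open_threshold must be >= 0")
    if abs(seg.source_fs - field.fs_video) > 1e-6 * field.fs_video:
        raise ValueError("segmentation and field must share the frame rate")
    if seg.boundaries[-1] > field.n_frames:
        raise ValueError("segmentation extends past the end of the field")
    n_cycles, n_pos = seg.n_valid, field.n_positions
    open_f = np.full((n_cycles, n_pos), np.nan)
    close_f = np.full((n_cycles, n_pos), np.nan)
    never = np.zeros((n_cycles, n_pos), dtype=bool)
    cycle_len = np.empty(n_cycles)
    for c, (s, e) in enumerate(zip(seg.starts, seg.ends)):
        lo, hi = int(np.round(s)), int(np.round(e))
        cycle_len[c] = hi - lo
        is_open = field.width[lo:hi] > open_threshold  # (frames, positions)
        any_open = is_open.any(axis=0)
        first_open = np.argmax(is_open, axis=0).astype(float)
        open_f[c, any_open] = first_open[any_open]
        for p in np.flatnonzero(any_open):
            closed_after = ~is_open[int(first_open[p]) :, p]
            if closed_after.any():
                close_f[c, p] = first_open[p] + np.argmax(closed_after)
            else:
                close_f[c, p] = hi - lo
                never[c, p] = True
    return OpenCloseInstants(open_f, close_f, never, cycle_len, seg.midpoint_times)


def normalize_and_average(
    instants: OpenCloseInstants,
    seg: CycleSegmentation,
    ws: WindowSet,
) -> list[ContourPair]:
    """Cycle-normalise the instants and average them per analysis window.

    Each instant is divided by its cycle's duration; per window and position
    the mean over contributing cycles is taken (missing pairs skipped). A
    window without cycles yields an all-missing :class:`ContourPair`.
    Returns the 11 contour pairs for windows -5 .. +5.
    """
    norm_open = instants.open_frames / instants.cycle_len[:, None]
    norm_close = instants.close_frames / instants.cycle_len[:, None]
    n_pos = norm_open.shape[1]
    positions = np.arange(n_pos)
    out: list[ContourPair] = []
    for k in range(N_WINDOWS):
        w_idx = k - HALF_SPAN
        if ws.missing[k]:
            sel = np.zeros(instants.cycle_times.size, dtype=bool)
        else:
            t0, t1 = ws.interval(w_idx)
            sel = (instants.cycle_times >= t0) & (instants.cycle_times < t1)
        o, c = norm_open[sel], norm_close[sel]
        defined = np.isfinite(o)
        coverage = defined.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_o = np.where(coverage > 0, np.nanmean(np.where(defined, o, np.nan), axis=0), np.nan) if o.size else np.full(n_pos, np.nan)
            mean_c = np.where(coverage > 0, np.nanmean(np.where(defined, c, np.nan), axis=0), np.nan) if c.size else np.full(n_pos, np.nan)
        nc_rate = np.where(
            coverage > 0,
            instants.never_closed[sel].sum(axis=0) / np.maximum(coverage, 1),
            np.nan,
        ) if o.size else np.full(n_pos, np.nan)
        out.append(
            ContourPair(
                positions=positions,
                open_contour=np.clip(mean_o, 0.0, 1.0),
                close_contour=np.clip(mean_c, 0.0, 1.0),
                coverage=coverage if o.size else np.zeros(n_pos, dtype=int),
                never_closed_rate=nc_rate,
                window_index=w_idx,
            )
        )
    return out


def contour_summary_metrics(cp: ContourPair) -> dict:
    """Scalar descriptors of one window's contour pair.

    * ``mean_open_duration`` — mean of (close - open) over defined positions.
    * ``ap_delay_slope`` — least-squares slope of the opening contour versus
      A-P position index (normalised intra-cycle time per position).
    * ``never_closed_fraction`` — mean never-closed rate over positions.

    All NaN when fewer than 3 positions are defined.
    """
    defined = np.isfinite(cp.open_contour) & np.isfinite(cp.close_contour)
    if defined.sum() < 3:
        return {
            "mean_open_duration": float("nan"),
            "ap_delay_slope": float("nan"),
            "never_closed_fraction": float("nan"),
        }
    o = cp.open_contour[defined]
    c = cp.close_contour[defined]
    p = cp.positions[defined].astype(float)
    slope = np.polyfit(p, o, 1)[0]
    nc = cp.never_closed_rate[np.isfinite(cp.never_closed_rate)]
    return {
        "mean_open_duration": float(np.mean(c - o)),
        "ap_delay_slope": float(slope),
        "never_closed_fraction": float(nc.mean()) if nc.size else float("nan"),
    }
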