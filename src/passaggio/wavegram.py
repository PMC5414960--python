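"""EGG / dEGG wavegrams: cycle-normalised waveforms stacked over time.

A wavegram visualises the evolution of the glottal-cycle shape: every
detected cycle is resampled to a fixed number of points, min-max normalised
to [0, 1], and written as one column of an image whose x axis is time
(cycle index) and whose y axis is normalised intra-cycle time. Register
events show up as sudden changes of the column pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .egg_cycles import CycleSegmentation
from .signal_io import SampledSignal

__all__ = ["Wavegram", "build_wavegram", "render_wavegram"]

log = logging.getLogger("passaggio.wavegram")


@dataclass
class Wavegram:
    """Cycle-normalised waveform intensity image.

    ``matrix[r, c]`` is the normalised amplitude of cycle ``c`` at
    intra-cycle time ``r / n_rows``; every column lies in [0, 1].
    """

    matrix: np.ndarray  # (n_rows, n_cycles)
    source: str  # "egg" | "degg"
    column_times: np.ndarray  # (n_cycles,) cycle start times, s

    def __post_init__(self) -> None:
        if self.matrix.min() < 0 or self.matrix.max() > 1:
            raise ValueError("wavegram values must lie in [0, 1]")
        if self.matrix.shape[1] != self.column_times.size:
            raise ValueError("one column per cycle required")


def build_wavegram(
    signal: SampledSignal,
    seg: CycleSegmentation,
    n_rows: int = 256,
    source: str = "egg",
) -> Wavegram:
    """Stack the valid cycles of ``signal`` as min-max normalised columns.

    Works for the EGG and its derivative alike (the dEGG is one sample
    shorter; cycle boundaries remain usable). A degenerate (flat) cycle
    yields a column of 0.5 and a warning.
    """
    if n_rows < 32:
        raise ValueError("n_rows must be >= 32")
    x = signal.samples
    grid = np.arange(x.size, dtype=float)
    frac = np.arange(n_rows) / n_rows
    cols = np.empty((n_rows, seg.n_valid))
    n_flat = 0
    for c, (s, e) in enumerate(zip(seg.starts, seg.ends)):
        cyc = np.interp(np.minimum(s + frac * (e - s), grid[-1]), grid, x)
        lo, hi = cyc.min(), cyc.max()
        if hi - lo <= 0:
            cols[:, c] = 0.5
            n_flat += 1
        else:
            cols[:, c] = (cyc - lo) / (hi - lo)
    if n_flat:
        log.warning("%d degenerate (flat) cycles mapped to 0.5 columns", n_flat)
    return Wavegram(cols, source, seg.starts / seg.source_fs + seg.t0)


def render_wavegram(w: Wavegram, path, cmap: str = "viridis", scale: int = 1) -> None:
    """Write the wavegram as a PNG (time on x, intra-cycle time upward on y).

    Output is deterministic: fixed colormap, no timestamps or metadata, so
    re-rendering the same wavegram is byte-identical.
    """
    rgba = colormaps[cmap](w.matrix)
    img = (rgba[::-1, :, :3] * 255).astype(np.uint8)  # flip: row 0 at bottom
    im = Image.fromarray(img)
    if scale > 1:
        im = im.resize((im.width * scale, im.height * scale), Image.NEAREST)
    im.save(path, format="PNG")
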