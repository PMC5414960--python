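"""Synthetic phonation generator with exact ground truth.

Emulates the study conditions this pipeline is built for: one-second upward
pitch glides (220->440 Hz across the first passaggio, 440->880 Hz across the
second), sampled at 20 kHz, with the fo change concentrated in a 50 ms
interval centred at 0.5 s. The generator emits a stereotypical EGG pulse
train with controllable contact quotient, a matching glottal-area /
displacement-field pair as segmented high-speed video would deliver, and
rater score matrices with controllable agreement — each together with a
:class:`SynthTruth` record (exact cycle boundaries, fo and OQ tracks,
opening/closing contours) for recovery tests.

Kinematics: fo is piecewise-constant per glottal cycle (each cycle has one
well-defined period; the sigmoid glide is sampled at cycle starts). This is
what "fixed cycle shape" means operationally — every cycle of a
stereotypical glide is exactly the same waveform in normalised intra-cycle
time, at any fo. A continuous intra-cycle chirp would itself deform the
cycle shape (by ~2% at the glide rates used here) and is not what a
cycle-separable voice source produces.

Transition strategies (the four patterns observed in sopranos navigating the
passaggi):

* ``stereotypical`` — fixed cycle shape throughout; the fo glide is the only
  change. The control condition: cycle-normalised shape descriptors must not
  react to it.
* ``smooth_oq_up`` / ``smooth_oq_down`` — gradual open-quotient ramp
  (decreasing resp. increasing relative closure duration).
* ``abrupt`` — register break: fo and open quotient jump at the transition
  instant, and the cycles within +-10 ms of the break carry random
  cycle-to-cycle open-quotient perturbations, the transient vibratory
  irregularity that makes real register breaks audible.
* ``contact_loss`` — three brief episodes around the transition in which
  vocal-fold contact is lost: the EGG amplitude and contact quotient taper
  to zero over the episode edges (the glottis never closes at the episode
  core), with mild shape irregularity during the episodes.

The EGG pulse model is an asymmetric raised-cosine contact pulse (rise
faster than release, as in real EGG); contact quotient = 1 - OQ. Any
shape-stable pulse family would do for the control property; this one also
gives the dEGG a single sharp positive peak per cycle to anchor detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .signal_io import DisplacementField, EGGSignal, GAWSeries, RatingTable

__all__ = [
    "GlideSpec",
    "SynthTruth",
    "synth_egg",
    "synth_gaw_field",
    "synth_ratings",
    "synth_cohort",
    "CohortPhonation",
    "LOWER_GLIDE",
    "UPPER_GLIDE",
]

STRATEGIES = ("stereotypical", "smooth_oq_down", "smooth_oq_up", "abrupt", "contact_loss")

FS_DEFAULT = 20_000.0  # Hz, both EGG and video frame rate in the emulated setup

# abrupt-strategy instability: OQ jitter SD and half-width around the break
# (the vibratory irregularity of a register break occupies roughly the same
# ~100 ms interval as the fo jump itself)
BREAK_JITTER_SD = 0.08
BREAK_JITTER_HALFWIDTH = 0.050  # s
# contact-loss episodes: core (no contact) and taper half-widths
EPISODE_CORE = 0.002  # s
EPISODE_TAPER = 0.006  # s
EPISODE_JITTER_SD = 0.010
# displacement field: closed fraction of the cycle after the last position
# closes (closure must fall strictly inside the cycle, not on its boundary)
CLOSE_MARGIN = 0.05


@dataclass
class GlideSpec:
    """Parameters of one synthetic pitch glide."""

    fo_start: float = 220.0
    fo_end: float = 440.0
    duration: float = 1.0
    transition_center: float = 0.5
    transition_width: float = 0.05
    strategy: str = "stereotypical"
    oq_start: float = 0.6
    oq_end: float = 0.6
    noise_sd: float = 0.0  # additive noise, relative to clean-signal SD
    fs: float = FS_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.transition_width < self.duration:
            raise ValueError("need 0 < transition_width < duration")
        for fo in (self.fo_start, self.fo_end):
            if not 100 <= fo <= 1200:
                raise ValueError("fo_start/fo_end must lie in [100, 1200] Hz")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for oq in (self.oq_start, self.oq_end):
            if not 0.05 < oq < 1:
                raise ValueError("open quotients must lie in (0.05, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SynthTruth:
    """Exact ground truth accompanying one synthetic phonation."""

    boundaries: np.ndarray  # float sample positions of cycle starts (contact)
    fo_track: np.ndarray  # Hz per sample (piecewise-constant per cycle)
    oq_per_cycle: np.ndarray
    contact_lost: np.ndarray  # bool per cycle
    transition_time: float
    fs: float
    # filled by synth_gaw_field:
    fs_video: Optional[float] = None
    ap_delay_slope: Optional[float] = None
    open_norm: Optional[np.ndarray] = None  # (n_cycles, n_positions)
    close_norm: Optional[np.ndarray] = None

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries) - 1

    @property
    def cycle_start_times(self) -> np.ndarray:
        return self.boundaries[:-1] / self.fs


# ---------------------------------------------------------------------------
# Shared kinematics (sampling-rate independent)
# ---------------------------------------------------------------------------


def _fo_glide(spec: GlideSpec, t: np.ndarray | float) -> np.ndarray:
    """Target fo at time t: sigmoid glide, or a hard step for abrupt breaks."""
    if spec.strategy == "abrupt":
        return np.where(np.asarray(t) < spec.transition_center, spec.fo_start, spec.fo_end)
    # logistic scale w/12 puts ~99.8% of the change inside the stated interval
    z = (np.asarray(t) - spec.transition_center) / (spec.transition_width / 12.0)
    return spec.fo_start + (spec.fo_end - spec.fo_start) * expit(z)


@dataclass
class _CycleTrack:
    """Continuous-time cycle plan shared by the EGG and field generators."""

    start_times: np.ndarray  # (n_cycles + 1,) cycle boundaries, s
    fo: np.ndarray  # (n_cycles,) Hz
    oq: np.ndarray  # (n_cycles,) effective open quotient
    amp: np.ndarray  # (n_cycles,) EGG amplitude factor in [0, 1]
    lost: np.ndarray  # (n_cycles,) bool, no vocal-fold contact at all


def _episode_amp(spec: GlideSpec, t: np.ndarray) -> np.ndarray:
    """Contact amplitude profile of the contact-loss strategy (1 = normal)."""
    c, w = spec.transition_center, spec.transition_width
    a = np.ones_like(t)
    for centre in (c - w, c, c + w):
        a = np.minimum(
            a, np.clip((np.abs(t - centre) - EPISODE_CORE) / EPISODE_TAPER, 0.0, 1.0)
        )
    return a


def _cycle_track(spec: GlideSpec) -> _CycleTrack:
    """Plan all cycles in continuous time (fs plays no role here)."""
    rng = np.random.default_rng(spec.seed)
    starts = [0.0]
    while starts[-1] < spec.duration:
        fo_k = float(_fo_glide(spec, starts[-1]))
        starts.append(starts[-1] + 1.0 / fo_k)
    starts = np.array(starts)  # last boundary may exceed duration (partial cycle)
    t_k = starts[:-1]
    fo = 1.0 / np.diff(starts)

    if spec.strategy in ("smooth_oq_down", "smooth_oq_up", "contact_loss"):
        # the underlying glide ramps the OQ linearly between the endpoints
        # (contact-loss episodes ride on top of the same baseline trajectory)
        frac = np.clip(t_k / spec.duration, 0.0, 1.0)
        oq = spec.oq_start + (spec.oq_end - spec.oq_start) * frac
    elif spec.strategy == "abrupt":
        oq = np.where(t_k < spec.transition_center, spec.oq_start, spec.oq_end)
    else:
        oq = np.full(t_k.size, spec.oq_start)

    amp = np.ones(t_k.size)
    lost = np.zeros(t_k.size, dtype=bool)
    if spec.strategy == "abrupt":
        near = np.abs(t_k - spec.transition_center) < BREAK_JITTER_HALFWIDTH
        oq = oq + near * rng.normal(0.0, BREAK_JITTER_SD, size=t_k.size)
    elif spec.strategy == "contact_loss":
        amp = _episode_amp(spec, t_k)
        lost = amp == 0.0
        in_episode = amp < 1.0
        oq = 1.0 - (1.0 - oq) * amp  # contact shortens as it is lost
        oq = oq + (in_episode & ~lost) * rng.normal(
            0.0, EPISODE_JITTER_SD, size=t_k.size
        )
        oq[lost] = 1.0
    oq = np.clip(oq, 0.1, 1.0)
    return _CycleTrack(starts, fo, oq, amp, lost)


def _per_sample(track: _CycleTrack, t: np.ndarray):
    """Cycle index and normalised intra-cycle time theta for sample times t."""
    ci = np.clip(np.searchsorted(track.start_times, t, side="right") - 1,
                 0, track.fo.size - 1)
    theta = (t - track.start_times[ci]) * track.fo[ci]
    return ci, np.clip(theta, 0.0, 1.0)


def _contact_pulse(theta: np.ndarray, cq: np.ndarray, rise_frac: float = 0.3) -> np.ndarray:
    """Asymmetric raised-cosine contact pulse on normalised cycle time theta.

    Contact spans theta in [0, cq): amplitude rises over the first
    ``rise_frac`` of the contact phase and releases over the rest; the open
    phase [cq, 1) is zero. Contacting is faster than de-contacting, matching
    the polarity convention used by cycle detection.
    """
    out = np.zeros_like(theta)
    a = rise_frac * cq
    rise = (theta < a) & (a > 0)
    fall = (theta >= a) & (theta < cq)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[rise] = 0.5 * (1.0 - np.cos(np.pi * theta[rise] / a[rise]))
        out[fall] = 0.5 * (
            1.0 + np.cos(np.pi * (theta[fall] - a[fall]) / (cq[fall] - a[fall]))
        )
    return out


def _truth(spec: GlideSpec, track: _CycleTrack, fs: float, n_samples: int) -> SynthTruth:
    t = np.arange(n_samples) / fs
    ci, _ = _per_sample(track, t)
    return SynthTruth(
        boundaries=track.start_times * fs,
        fo_track=track.fo[ci],
        oq_per_cycle=track.oq,
        contact_lost=track.lost,
        transition_time=spec.transition_center,
        fs=fs,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def synth_egg(spec: GlideSpec) -> tuple[EGGSignal, SynthTruth]:
    """Synthesize one EGG pitch glide and its exact ground truth."""
    track = _cycle_track(spec)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    ci, theta = _per_sample(track, t)
    cq = (1.0 - track.oq)[ci]
    amp = track.amp[ci]
    egg = amp * _contact_pulse(theta, cq)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 10_000)
        egg = egg + spec.noise_sd * egg.std() * rng.standard_normal(egg.size)
    return EGGSignal(egg, spec.fs), _truth(spec, track, spec.fs, n)


def synth_gaw_field(
    spec: GlideSpec,
    n_positions: int = 64,
    ap_delay_slope: float = 0.0,
    fs_video: Optional[float] = None,
    amp_px: float = 10.0,
    never_closed_positions: int = 0,
) -> tuple[GAWSeries, DisplacementField, SynthTruth]:
    """Synthesize a matching glottal width field and its row-sum GAW.

    Per cycle and A-P position ``p`` the local width is a half-sine pulse
    open for the fraction ``d = OQ - ap_delay_slope * (n_positions - 1)`` of
    the cycle, its onset delayed by ``ap_delay_slope * p`` (a "zipper"
    opening anterior -> posterior). The open span covers the programmed OQ
    of the cycle and the last position closes ``CLOSE_MARGIN`` before the
    cycle end, so every closure falls strictly inside the cycle.
    ``never_closed_positions`` posterior positions stay open permanently (a
    posterior gap); contact-loss episode cores keep every position open.

    The cycle plan is shared with :func:`synth_egg` (same spec => same
    cycles), so EGG- and video-derived measures can be cross-checked.
    """
    if n_positions < 8:
        raise ValueError("n_positions must be >= 8")
    if ap_delay_slope < 0:
        raise ValueError("ap_delay_slope must be >= 0")
    fsv = float(fs_video if fs_video is not None else spec.fs)
    track = _cycle_track(spec)
    total_delay = ap_delay_slope * (n_positions - 1)
    if np.any(track.oq - total_delay <= 0.02):
        raise ValueError("ap_delay_slope too steep for the programmed OQ")

    n = int(round(spec.duration * fsv))
    t = np.arange(n) / fsv
    ci, theta = _per_sample(track, t)
    theta = theta[:, None]

    p = np.arange(n_positions)
    # amplitude profile along the A-P axis: widest mid-glottis
    amp = amp_px * (0.5 + 0.5 * np.sin(np.pi * (p + 0.5) / n_positions))

    oq_f = track.oq[ci][:, None]
    d = oq_f - total_delay  # open-duration fraction per frame
    margin = np.minimum(CLOSE_MARGIN, 1.0 - oq_f)
    onset = 1.0 - oq_f - margin + ap_delay_slope * p[None, :]  # (frames, positions)
    u = (theta - onset) / d
    width = np.where(
        (u > 0.0) & (u < 1.0),
        amp[None, :] * np.sin(np.pi * np.clip(u, 0.0, 1.0)),
        0.0,
    )
    lost_f = track.lost[ci][:, None]
    # no contact at all: permanently open, full-cycle modulation
    width = np.where(lost_f, amp[None, :] * (0.25 + 0.5 * np.sin(np.pi * theta)), width)
    if never_closed_positions > 0:
        gap = slice(n_positions - never_closed_positions, n_positions)
        width[:, gap] = np.maximum(width[:, gap], 0.25 * amp[None, gap])

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 20_000)
        width = width + spec.noise_sd * width.std() * rng.standard_normal(width.shape)
    width = np.clip(width, 0.0, None)

    truth = _truth(spec, track, fsv, n)
    truth.fs_video = fsv
    truth.ap_delay_slope = ap_delay_slope
    margin_c = np.minimum(CLOSE_MARGIN, 1.0 - track.oq)
    open_norm = (1.0 - track.oq - margin_c)[:, None] + ap_delay_slope * p[None, :]
    close_norm = open_norm + (track.oq - total_delay)[:, None]
    open_norm[track.lost] = 0.0
    close_norm[track.lost] = 1.0
    if never_closed_positions > 0:
        open_norm[:, gap] = 0.0
        close_norm[:, gap] = 1.0
    truth.open_norm = open_norm
    truth.close_norm = close_norm

    field_obj = DisplacementField(width, fsv)
    return field_obj.gaw(), field_obj, truth


def synth_ratings(
    n_raters: int = 12,
    n_stimuli: int = 20,
    true_scores: Optional[np.ndarray] = None,
    rater_noise_sd: float = 0.5,
    rater_bias_sd: float = 0.3,
    seed: int = 0,
    stimulus_labels: Optional[list[str]] = None,
    duplicate_index: Optional[int] = 0,
) -> tuple[RatingTable, np.ndarray]:
    """Synthesize a rater x stimulus score matrix on the 1-5 scale.

    ``score = clip(round(true + rater_bias + noise), 1, 5)``. As in the
    emulated listening experiment, one stimulus is presented twice (the
    duplicate gets fresh noise), so the returned table has ``n_stimuli + 1``
    columns when ``duplicate_index`` is not None. Returns (table, truth).
    """
    rng = np.random.default_rng(seed)
    if true_scores is None:
        true_scores = rng.uniform(1.0, 5.0, size=n_stimuli)
    true_scores = np.asarray(true_scores, dtype=float)
    if true_scores.min() < 1 or true_scores.max() > 5:
        raise ValueError("true_scores must lie in [1, 5]")
    n_stimuli = true_scores.size
    if stimulus_labels is None:
        stimulus_labels = [f"s{i:02d}" for i in range(n_stimuli)]
    truth = true_scores
    if duplicate_index is not None:
        truth = np.append(true_scores, true_scores[duplicate_index])
        stimulus_labels = list(stimulus_labels) + [f"{stimulus_labels[duplicate_index]}_dup"]
    bias = rng.normal(0.0, rater_bias_sd, size=n_raters)
    noise = rng.normal(0.0, rater_noise_sd, size=(n_raters, truth.size))
    scores = np.clip(np.round(truth[None, :] + bias[:, None] + noise), 1, 5).astype(int)
    df = pd.DataFrame(scores, columns=stimulus_labels,
                      index=[f"r{i:02d}" for i in range(n_raters)])
    return RatingTable(df), truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

#: Task templates. The open-quotient ramps are set so that the mean OQ rises
#: ~10% (lower glide) and ~18% (upper glide) across the task, the average
#: behaviour observed in trained sopranos.
LOWER_GLIDE = dict(fo_start=220.0, fo_end=440.0, oq_start=0.60, oq_end=0.66)
UPPER_GLIDE = dict(fo_start=440.0, fo_end=880.0, oq_start=0.60, oq_end=0.708)


@dataclass
class CohortPhonation:
    """One synthetic phonation of a cohort, with its planted severity."""

    subject: str
    task: str  # "lower" | "upper"
    spec: GlideSpec
    severity: float  # planted register-event severity in [0, 1]
    true_rating: float  # 1 + 4 * severity

    n_positions: int = 32
    ap_delay_slope: float = 0.002

    def render(self):
        egg, _ = synth_egg(self.spec)
        gaw, fld, truth = synth_gaw_field(
            self.spec, n_positions=self.n_positions, ap_delay_slope=self.ap_delay_slope
        )
        return egg, gaw, fld, truth


def _severity_strategy(severity: float, direction_up: bool) -> str:
    if severity >= 0.7:
        return "abrupt"
    if severity >= 0.4:
        return "contact_loss"
    return "smooth_oq_up" if direction_up else "smooth_oq_down"


def synth_cohort(
    n_subjects: int = 10,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> list[CohortPhonation]:
    """A synthetic cohort: 2 pitch glides per subject, planted severities.

    Each subject performs the lower (220->440 Hz) and upper (440->880 Hz)
    glide. The planted severity drives both the transition strategy (smooth
    below 0.4, contact loss below 0.7, abrupt above) and the "true"
    perceptual rating 1 + 4 * severity, so a working pipeline must recover a
    positive severity/entropy association.
    """
    rng = np.random.default_rng(seed)
    phonations: list[CohortPhonation] = []
    for s in range(n_subjects):
        for task, template in (("lower", LOWER_GLIDE), ("upper", UPPER_GLIDE)):
            severity = float(rng.uniform(0.0, 1.0))
            strategy = _severity_strategy(severity, direction_up=True)
            spec = GlideSpec(
                strategy=strategy,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                transition_center=float(rng.uniform(0.4, 0.6)),
                **template,
            )
            phonations.append(
                CohortPhonation(
                    subject=f"S{s + 1}",
                    task=task,
                    spec=spec,
                    severity=severity,
                    true_rating=1.0 + 4.0 * severity,
                )
            )
    return phonations
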