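"""Per-phonation orchestration and cross-participant statistics.

``analyze_phonation`` runs the full chain on one recording — EGG cycle
detection, Fourier-descriptor sample entropy, the 11-window alignment at the
entropy maximum, GAW open-quotient statistics on that alignment, and the
spatio-temporal opening/closing contours — and returns a
:class:`PhonationResult`. The EGG drives the window alignment (better SNR
than the video-derived signals and immune to endoscope movement).

``cohort_report`` aggregates a cohort: first-order polynomial regressions of
mean perceptual rating against maximum FDSE_w and of maximum FDSE_w against
the between-window open-quotient variability (SD of delta OQ), per task, plus
the per-window OQ distributions. ``compute_icc`` quantifies rater agreement
(two-way random effects, absolute agreement, average of k raters by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import glottal_dynamics as gd
from .egg_cycles import compute_degg, detect_cycles, extract_cycles, precondition_egg
from .fdse import (
    SampleEntropyParams,
    WindowSet,
    fdse_cycle_trace,
    fdse_windows,
    fourier_descriptors,
    max_fdse_w,
)
from .gaw_metrics import OQTrace, gaw_cycles, open_quotient, window_oq
from .signal_io import (
    DEFAULT_CONFIG,
    DisplacementField,
    EGGSignal,
    GAWSeries,
    RatingTable,
)

__all__ = [
    "PhonationResult",
    "RegressionFit",
    "analyze_phonation",
    "fit_regression",
    "compute_icc",
    "cohort_report",
]

log = logging.getLogger("passaggio.stats")


@dataclass
class PhonationResult:
    """Everything the pipeline derives from one phonation."""

    participant: str = ""
    task: str = ""
    max_fdse_w: float = float("nan")
    windows: Optional[WindowSet] = None
    oq: Optional[OQTrace] = None
    contours: Optional[list] = None
    contour_metrics: Optional[list[dict]] = None
    error: Optional[str] = None  # structured failure record

    @property
    def sd_delta_oq(self) -> float:
        if self.oq is None or self.oq.sd_delta_oq is None:
            return float("nan")
        return self.oq.sd_delta_oq

    @property
    def oq_per_window(self) -> np.ndarray:
        if self.oq is None or self.oq.oq_per_window is None:
            return np.full(11, np.nan)
        return self.oq.oq_per_window


@dataclass
class RegressionFit:
    """First-order polynomial (least squares) regression summary."""

    slope: float
    intercept: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs at least 3 points")
        if not 0 <= self.r2 <= 1 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")


def analyze_phonation(
    egg: EGGSignal,
    gaw: Optional[GAWSeries] = None,
    field_: Optional[DisplacementField] = None,
    config: Optional[dict] = None,
    participant: str = "",
    task: str = "",
) -> PhonationResult:
    """Run the full per-phonation analysis chain.

    The GAW and displacement field are optional (EGG-only analysis yields the
    entropy results). Stage failures are recorded in ``result.error`` while
    preserving everything computed before the failure.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    res = PhonationResult(participant=participant, task=task)
    try:
        pegg = precondition_egg(egg, cfg["highpass_hz"])
        slen = max(int(cfg["degg_smooth_ms"] * 1e-3 * egg.fs) | 1, 1)
        degg = compute_degg(pegg, slen)
        seg = detect_cycles(degg, cfg["fo_min"], cfg["fo_max"], egg=pegg)
        cycles = extract_cycles(pegg, seg, cfg["n_resample"], cfg["normalization"])
        fds = fourier_descriptors(cycles, seg.midpoint_times)
        params = SampleEntropyParams(cfg["sampen_m"], cfg["sampen_r"], cfg["sampen_r_floor"])
        trace = fdse_cycle_trace(fds, params, cfg["block_len"])
        ws = fdse_windows(trace, seg, cfg["window_len"])
        res.windows = ws
        res.max_fdse_w = max_fdse_w(ws)
    except Exception as exc:  # noqa: BLE001 - structured failure record
        res.error = f"egg stage: {exc}"
        log.warning("phonation %s/%s failed: %s", participant, task, res.error)
        return res
    if gaw is not None:
        try:
            gseg = gaw_cycles(gaw, cfg["fo_min"], cfg["fo_max"])
            oq = open_quotient(gaw, gseg, cfg["open_threshold_frac"])
            res.oq = window_oq(oq, ws)
            if field_ is not None:
                inst = gd.local_open_close_instants(field_, gseg, cfg["open_threshold_px"])
                res.contours = gd.normalize_and_average(inst, gseg, ws)
                res.contour_metrics = [gd.contour_summary_metrics(c) for c in res.contours]
        except Exception as exc:  # noqa: BLE001
            res.error = f"gaw stage: {exc}"
            log.warning("phonation %s/%s failed: %s", participant, task, res.error)
    return res


def fit_regression(x, y) -> RegressionFit:
    """Least-squares line y = slope * x + intercept; r2 = squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("undefined fit: zero variance in x")
    fit = sps.linregress(x, y)
    return RegressionFit(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue) ** 2, int(x.size))


def compute_icc(rt: RatingTable, form: str = "ICC2k") -> tuple[float, str]:
    """Intraclass correlation of the raters over the stimuli.

    Default form ICC2k: two-way random effects, absolute agreement, average
    of k raters. Returns (value, form); NaN when the table is degenerate
    (zero between-stimulus variance).
    """
    import pingouin as pg

    if rt.n_raters < 2 or rt.n_stimuli < 2:
        raise ValueError("ICC needs at least 2 raters and 2 stimuli")
    long = rt.scores.reset_index(names="rater").melt(
        id_vars="rater", var_name="stimulus", value_name="score"
    )
    if long.groupby("stimulus")["score"].mean().nunique() == 1 and (
        long.groupby("stimulus")["score"].std() == 0
    ).all():
        return float("nan"), form
    icc = pg.intraclass_corr(
        data=long, targets="stimulus", raters="rater", ratings="score"
    )
    # accept both the Shrout-Fleiss and the McGraw-Wong labelling
    aliases = {
        "ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
        "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)",
    }
    wanted = {form, aliases.get(form, form)}
    row = icc.loc[icc["Type"].isin(wanted)]
    if row.empty:
        raise ValueError(f"unknown ICC form {form!r}")
    return float(row["ICC"].iloc[0]), form


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------


def _mean_ratings(ratings: RatingTable, aggregate: str = "mean") -> pd.Series:
    """Per-stimulus rating aggregated across raters; duplicates dropped."""
    scores = ratings.scores.loc[:, ~ratings.scores.columns.str.endswith("_dup")]
    return scores.median(axis=0) if aggregate == "median" else scores.mean(axis=0)


def cohort_report(
    results: list[PhonationResult],
    ratings: Optional[RatingTable] = None,
    out_dir=None,
    rating_aggregate: str = "mean",
) -> dict:
    """Cross-participant summary tables, regressions and (optional) figures.

    Stimulus labels in the rating table must be ``<participant>_<task>``.
    Per task, two regressions are fitted when at least 3 complete phonations
    exist: mean rating vs maximum FDSE_w, and maximum FDSE_w vs SD(delta OQ).
    Writes CSVs and PNGs under ``out_dir`` when given.
    """
    rows = []
    for r in results:
        rows.append(
            dict(
                participant=r.participant,
                task=r.task,
                max_fdse_w=r.max_fdse_w,
                sd_delta_oq=r.sd_delta_oq,
                error=r.error or "",
            )
        )
    summary = pd.DataFrame(rows)

    oq_rows = []
    for r in results:
        for k, v in zip(range(-5, 6), r.oq_per_window):
            oq_rows.append(
                dict(participant=r.participant, task=r.task, window=k, oq_mean=v)
            )
    oq_windows = pd.DataFrame(oq_rows)

    mean_rating = _mean_ratings(ratings, rating_aggregate) if ratings is not None else None
    regressions = []
    for task, grp in summary.groupby("task"):
        ok = grp[grp["error"] == ""]
        if mean_rating is not None:
            labels = ok["participant"] + "_" + ok["task"]
            have = labels.isin(mean_rating.index)
            x = mean_rating.loc[labels[have]].to_numpy()
            y = ok.loc[have, "max_fdse_w"].to_numpy()
            good = np.isfinite(x) & np.isfinite(y)
            if good.sum() >= 3:
                f = fit_regression(x[good], y[good])
                regressions.append(dict(task=task, x="mean_rating", y="max_fdse_w",
                                        slope=f.slope, intercept=f.intercept,
                                        r2=f.r2, n=f.n))
            else:
                log.warning("task %s: <3 rated phonations, rating regression skipped", task)
        x = ok["max_fdse_w"].to_numpy()
        y = ok["sd_delta_oq"].to_numpy()
        good = np.isfinite(x) & np.isfinite(y)
        if good.sum() >= 3:
            f = fit_regression(x[good], y[good])
            regressions.append(dict(task=task, x="max_fdse_w", y="sd_delta_oq",
                                    slope=f.slope, intercept=f.intercept,
                                    r2=f.r2, n=f.n))
        else:
            log.warning("task %s: <3 complete phonations, OQ regression skipped", task)
    regressions = pd.DataFrame(regressions)

    report = {"summary": summary, "oq_windows": oq_windows, "regressions": regressions}
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir) -> None:
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("summary", "oq_windows", "regressions"):
        report[name].to_csv(out / f"{name}.csv", index=False)

    oq = report["oq_windows"].dropna()
    if not oq.empty:
        tasks = sorted(oq["task"].unique())
        fig, axes = plt.subplots(1, len(tasks), figsize=(5 * len(tasks), 4), squeeze=False)
        for ax, task in zip(axes[0], tasks):
            sub = oq[oq["task"] == task]
            data = [sub.loc[sub["window"] == k, "oq_mean"].to_numpy() for k in range(-5, 6)]
            ax.boxplot(data, positions=range(-5, 6))
            ax.set(title=f"{task} glide", xlabel="analysis window", ylabel="OQ (GAW)")
        fig.tight_layout()
        fig.savefig(out / "oq_windows.png", dpi=120)
        plt.close(fig)

    summ = report["summary"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for task, grp in summ.groupby("task"):
        ax.scatter(grp["max_fdse_w"], grp["sd_delta_oq"], label=f"{task} glide")
    ax.set(xlabel="max FDSE_w", ylabel="SD(delta OQ)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fdse_vs_sd_delta_oq.png", dpi=120)
    plt.close(fig)
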