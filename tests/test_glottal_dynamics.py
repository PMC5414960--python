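import numpy as np
import pytest

import passaggio as pg
from passaggio.gaw_metrics import gaw_cycles
from passaggio.glottal_dynamics import (
    ContourPair,
    contour_summary_metrics,
    local_open_close_instants,
    normalize_and_average,
)


def _rect_field(n_cycles=12, period=100, n_pos=10, open_start=30, open_len=40,
                fs=2000.0, closed_positions=0):
    """Rectangular synchronous opening; optionally some never-opening rows."""
    width = np.zeros((n_cycles * period, n_pos))
    for c in range(n_cycles):
        lo = c * period + open_start
        width[lo : lo + open_len, closed_positions:] = 2.0
    fld = pg.DisplacementField(width, fs)
    seg = pg.CycleSegmentation(
        np.arange(0, n_cycles * period + 1, period, dtype=float), fs,
        fo_min=fs / period / 2, fo_max=fs / period * 2)
    return fld, seg


def test_rectangular_synchronous_opening_instants():
    fld, seg = _rect_field()
    inst = local_open_close_instants(fld, seg, open_threshold=0.5)
    assert np.all(inst.open_frames == 30)
    assert np.all(inst.close_frames == 70)
    assert not inst.never_closed.any()


def test_permanently_closed_positions_are_missing():
    fld, seg = _rect_field(closed_positions=3)
    inst = local_open_close_instants(fld, seg, open_threshold=0.5)
    assert np.isnan(inst.open_frames[:, :3]).all()
    assert np.isfinite(inst.open_frames[:, 3:]).all()


def test_zipper_opening_matches_programmed_delays():
    slope = 0.004
    spec = pg.GlideSpec(fo_start=250, fo_end=250, oq_start=0.6, oq_end=0.6)
    gaw, fld, truth = pg.synth_gaw_field(spec, n_positions=16, ap_delay_slope=slope)
    seg = gaw_cycles(gaw)
    inst = local_open_close_instants(fld, seg)
    norm_open = inst.open_frames / inst.cycle_len[:, None]
    # per-position delays relative to position 0, mid-phonation cycles
    rows = norm_open[10:-10]
    rel = rows - rows[:, [0]]
    prog = slope * np.arange(16)
    frame_frac = 1.0 / inst.cycle_len.mean()  # one frame in normalised time
    assert np.nanmax(np.abs(rel - prog)) < 2 * frame_frac


def test_normalize_and_average_is_plain_mean():
    # hand-built instants: one position with values {0.10, 0.12, 0.14}
    fld, seg = _rect_field(n_cycles=3)
    inst = local_open_close_instants(fld, seg)
    inst.open_frames[:, 0] = [10.0, 12.0, 14.0]  # cycle_len = 100
    ws = pg.WindowSet(
        window_len=3 * 100 / 2000.0,
        starts=np.array([-5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5]) * 0.15,
        fdse_w=np.zeros(11), missing=np.zeros(11, dtype=bool), center_grid_index=5)
    cps = normalize_and_average(inst, seg, ws)
    cp0 = cps[5]
    assert cp0.open_contour[0] == pytest.approx(0.12)
    assert cp0.coverage[0] == 3


def test_constant_pattern_average_equals_single_cycle(centred_windows):
    spec = pg.GlideSpec(oq_start=0.6, oq_end=0.6)
    gaw, fld, _ = pg.synth_gaw_field(spec, n_positions=16)
    seg = gaw_cycles(gaw)
    inst = local_open_close_instants(fld, seg)
    cps = normalize_and_average(inst, seg, centred_windows)
    cp = cps[5]
    single = inst.open_frames[50] / inst.cycle_len[50]
    assert np.nanmax(np.abs(cp.open_contour - single)) < 0.05


def test_temporal_ordering_invariant(centred_windows):
    spec = pg.GlideSpec(strategy="contact_loss", noise_sd=0.02, seed=3)
    gaw, fld, _ = pg.synth_gaw_field(spec, n_positions=16)
    seg = gaw_cycles(gaw)
    cps = normalize_and_average(local_open_close_instants(fld, seg), seg,
                                centred_windows)
    for cp in cps:
        both = np.isfinite(cp.open_contour) & np.isfinite(cp.close_contour)
        assert np.all(cp.open_contour[both] <= cp.close_contour[both])
        assert np.all(cp.open_contour[both] >= 0)
        assert np.all(cp.close_contour[both] <= 1)


def test_frame_rate_invariance(centred_windows):
    spec = pg.GlideSpec(fo_start=250, fo_end=250, oq_start=0.6, oq_end=0.6)
    contours = {}
    for fsv in (10000.0, 20000.0):
        gaw, fld, _ = pg.synth_gaw_field(spec, n_positions=16, fs_video=fsv)
        seg = gaw_cycles(gaw)
        cps = normalize_and_average(local_open_close_instants(fld, seg), seg,
                                    centred_windows)
        contours[fsv] = cps[5].open_contour
    frame_frac = 10000.0 / 250.0  # frames per cycle at the lower rate
    assert np.nanmax(np.abs(contours[10000.0] - contours[20000.0])) < 1 / frame_frac * 250 / 10000 + 0.03


def test_rectangular_summary_metrics():
    fld, seg = _rect_field()  # open 40% of the 100-frame cycle
    inst = local_open_close_instants(fld, seg)
    ws = pg.WindowSet(
        window_len=0.6, starts=(np.arange(11) - 5) * 0.6, fdse_w=np.zeros(11),
        missing=np.zeros(11, dtype=bool), center_grid_index=0)
    cp = normalize_and_average(inst, seg, ws)[5]
    m = contour_summary_metrics(cp)
    assert m["mean_open_duration"] == pytest.approx(0.40)
    assert m["ap_delay_slope"] == pytest.approx(0.0, abs=1e-12)
    assert m["never_closed_fraction"] == 0.0


def test_zipper_slope_recovered_within_10_percent(centred_windows):
    slope = 0.003
    spec = pg.GlideSpec(oq_start=0.6, oq_end=0.6)
    gaw, fld, _ = pg.synth_gaw_field(spec, n_positions=32, ap_delay_slope=slope)
    seg = gaw_cycles(gaw)
    cps = normalize_and_average(local_open_close_instants(fld, seg), seg,
                                centred_windows)
    m = contour_summary_metrics(cps[5])
    assert m["ap_delay_slope"] == pytest.approx(slope, rel=0.10)


def test_posterior_gap_fraction_exact(centred_windows):
    spec = pg.GlideSpec(oq_start=0.6, oq_end=0.6)
    gaw, fld, _ = pg.synth_gaw_field(spec, n_positions=32, never_closed_positions=8)
    seg = gaw_cycles(gaw)
    cps = normalize_and_average(local_open_close_instants(fld, seg), seg,
                                centred_windows)
    m = contour_summary_metrics(cps[5])
    assert m["never_closed_fraction"] == pytest.approx(8 / 32, abs=0.0)


def test_contact_loss_cycles_never_closed_everywhere():
    """On the generator's own cycle grid, the never-closed flag marks exactly
    the programmed contact-loss cycles (plus near-total-loss taper cycles)."""
    spec = pg.GlideSpec(strategy="contact_loss", seed=1)
    gaw, fld, truth = pg.synth_gaw_field(spec, n_positions=16)
    b = truth.boundaries[truth.boundaries <= fld.n_frames]  # full cycles only
    n_full = b.size - 1
    seg = pg.CycleSegmentation(b, truth.fs_video, fo_min=150, fo_max=1200)
    inst = local_open_close_instants(fld, seg)
    flagged = inst.never_closed.all(axis=1)
    lost = truth.contact_lost[:n_full][seg.valid]
    oq = truth.oq_per_cycle[:n_full][seg.valid]
    assert flagged[lost].all()  # every programmed loss cycle is flagged
    assert not flagged[oq <= 0.95].any()  # ordinary cycles never are


def test_cross_module_open_duration_matches_oq():
    spec = pg.GlideSpec(oq_start=0.6, oq_end=0.6)
    gaw, fld, _ = pg.synth_gaw_field(spec, n_positions=16)
    seg = gaw_cycles(gaw)
    from passaggio.gaw_metrics import open_quotient

    oq = np.nanmean(open_quotient(gaw, seg).oq_per_cycle)
    norm_open = local_open_close_instants(fld, seg)
    dur = (norm_open.close_frames - norm_open.open_frames) / norm_open.cycle_len[:, None]
    assert abs(np.nanmean(dur) - oq) < 0.05


def test_contour_pair_ordering_validated():
    with pytest.raises(ValueError):
        ContourPair(
            positions=np.arange(3),
            open_contour=np.array([0.5, 0.6, 0.7]),
            close_contour=np.array([0.4, 0.8, 0.9]),
            coverage=np.ones(3, dtype=int),
            never_closed_rate=np.zeros(3),
            window_index=0,
        )


def test_mismatched_frame_rate_raises(abrupt_phonation):
    fld = abrupt_phonation["field"]
    seg = gaw_cycles(abrupt_phonation["gaw"])
    bad = pg.DisplacementField(fld.width, fld.fs_video / 2)
    with pytest.raises(ValueError):
        local_open_close_instants(bad, seg)
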