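import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import passaggio as pg
from passaggio.fdse import (
    SampleEntropyParams,
    fdse_cycle_trace,
    fdse_windows,
    fourier_descriptors,
    max_fdse_w,
    sample_entropy,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def dft_oracle(cycle, k):
    """Direct discrete-sum DFT component k, scaled by 1/n."""
    n = len(cycle)
    return sum(cycle[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n)) / n


def sampen_oracle(series, m, r, r_floor):
    """Naive O(N^2) pair-counting sample entropy (pure python loops)."""
    x = np.atleast_2d(np.asarray(series, dtype=float).T).T
    n, d = x.shape
    if n <= m + 1:
        return float("nan")
    sd = x.std(axis=0)
    scale = np.sqrt(np.mean(x**2))
    tol = np.maximum(r * sd, r_floor * scale)
    tol = np.where(tol > 0, tol, np.finfo(float).tiny)

    def similar(i, j, length):
        for a in range(length):
            for c in range(d):
                if abs(x[i + a, c] - x[j + a, c]) > tol[c]:
                    return False
        return True

    nt = n - m
    b = a_cnt = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if similar(i, j, m):
                b += 1
                if similar(i, j, m + 1):
                    a_cnt += 1
    if b == 0 or a_cnt == 0:
        return float("nan")
    return -np.log(a_cnt / b)


# ---------------------------------------------------------------------------
# Fourier descriptors
# ---------------------------------------------------------------------------


def test_cosine_cycle_descriptor_closed_form():
    n = 64
    t = np.arange(n) / n
    fds = fourier_descriptors(np.cos(2 * np.pi * t)[None, :], np.array([0.0]))
    assert np.allclose(fds.descriptors[0], [0.5, 0.0, 0.0, 0.0], atol=1e-12)


def test_second_harmonic_cycle_energy_in_component_2():
    n = 64
    t = np.arange(n) / n
    fds = fourier_descriptors(np.cos(4 * np.pi * t)[None, :], np.array([0.0]),
                              phase_normalize=False)
    re1, im1, re2, im2 = fds.descriptors[0]
    assert abs(re1) < 1e-12 and abs(im1) < 1e-12
    assert re2 == pytest.approx(0.5, abs=1e-12)


def test_sawtooth_matches_brute_force_dft():
    n = 64
    saw = np.arange(n) / n - 0.5
    fds = fourier_descriptors(saw[None, :], np.array([0.0]), phase_normalize=False)
    x1, x2 = dft_oracle(saw, 1), dft_oracle(saw, 2)
    assert np.allclose(fds.descriptors[0], [x1.real, x1.imag, x2.real, x2.imag],
                       atol=1e-12)


def test_phase_normalization_removes_circular_shift():
    n, rng = 64, np.random.default_rng(0)
    base = np.cos(2 * np.pi * np.arange(n) / n) + 0.4 * np.sin(4 * np.pi * np.arange(n) / n)
    shifted = np.stack([np.roll(base, s) for s in range(0, 32, 4)])
    fds = fourier_descriptors(shifted, np.arange(8, dtype=float))
    assert np.abs(fds.descriptors - fds.descriptors[0]).max() < 1e-12


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------


def test_identical_vectors_give_zero_entropy():
    series = np.tile([0.3, -0.1, 0.2, 0.05], (50, 1))
    assert sample_entropy(series, SampleEntropyParams()) == 0.0


def test_too_short_series_is_undefined():
    params = SampleEntropyParams(m=2)
    assert np.isnan(sample_entropy(np.zeros((3, 4)), params))


@pytest.mark.parametrize("m", [1, 2, 3])
def test_matches_brute_force_oracle_exactly(m, rng):
    params = SampleEntropyParams(m=m, r=0.2, r_floor=0.05)
    for _ in range(34):  # ~100 series across the three m values
        n = int(rng.integers(10, 300))
        d = int(rng.integers(1, 5))
        x = np.cumsum(rng.standard_normal((n, d)), axis=0)  # random walk
        got = sample_entropy(x, params)
        want = sampen_oracle(x, m, 0.2, 0.05)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=0.0)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(scale=st.floats(1e-6, 1e6), seed=st.integers(0, 2**16), m=st.integers(1, 3))
def test_entropy_is_scale_invariant(scale, seed, m):
    """Both tolerance terms (r x SD and the RMS floor) scale with the data,
    so multiplying a series by any positive constant leaves entropy fixed."""
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.standard_normal((40, 3)), axis=0)
    params = SampleEntropyParams(m=m)
    a, b = sample_entropy(x, params), sample_entropy(scale * x, params)
    assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, rel=1e-9)


def test_monotone_response_to_added_noise():
    base = np.tile([0.3, 0.0, 0.1, -0.05], (60, 1))
    params = SampleEntropyParams()
    medians = []
    for noise_sd in (0.0, 0.002, 0.004, 0.006):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            vals.append(sample_entropy(base + noise_sd * r.standard_normal(base.shape), params))
        medians.append(np.nanmedian(vals))
    assert all(b >= a - 1e-12 for a, b in zip(medians, medians[1:]))


# ---------------------------------------------------------------------------
# Entropy trace and windows
# ---------------------------------------------------------------------------


def _egg_chain(spec):
    egg, truth = pg.synth_egg(spec)
    pegg = pg.precondition_egg(egg)
    seg = pg.detect_cycles(pg.compute_degg(pegg, 11), egg=pegg)
    fds = fourier_descriptors(pg.extract_cycles(pegg, seg), seg.midpoint_times)
    return seg, fds, truth


def test_trace_length_and_stationary_zero():
    seg, fds, _ = _egg_chain(pg.GlideSpec(fo_start=330, fo_end=330))
    trace = fdse_cycle_trace(fds, SampleEntropyParams(), block_len=40)
    assert trace.values.size == fds.descriptors.shape[0] - 40 + 1
    assert np.nanmax(trace.values) == 0.0


def test_windows_grid_and_alignment():
    seg, fds, truth = _egg_chain(
        pg.GlideSpec(strategy="abrupt", oq_start=0.6, oq_end=0.75, seed=3))
    trace = fdse_cycle_trace(fds, SampleEntropyParams())
    ws = fdse_windows(trace, seg)
    assert ws.grid_starts.size == 40  # 1 s phonation -> 40 x 25 ms segments
    assert ws.fdse_w.size == 11 and ws.starts.size == 11
    # window 0 attains the global maximum and covers the transition +-1 window
    assert max_fdse_w(ws) == np.nanmax(ws.grid_values)
    lo, hi = ws.interval(0)
    assert lo - 0.025 <= truth.transition_time < hi + 0.025


def test_edge_maximum_clamps_with_missing_flags():
    seg, fds, _ = _egg_chain(pg.GlideSpec(fo_start=330, fo_end=330))
    trace = fdse_cycle_trace(fds, SampleEntropyParams())
    ws = fdse_windows(trace, seg)
    # constant-entropy trace: earliest segment with a defined value wins
    first_defined = int(np.flatnonzero(np.isfinite(ws.grid_values))[0])
    assert ws.center_grid_index == first_defined
    # windows clamped off the grid (or without cycles) are flagged missing
    assert ws.missing[:5].all() and not ws.missing[5]


def test_scale_invariance_of_fdse():
    spec = pg.GlideSpec(strategy="abrupt", oq_start=0.6, oq_end=0.75, seed=4)
    egg, _ = pg.synth_egg(spec)
    scaled = pg.EGGSignal(egg.samples * 37.5, egg.fs)
    r1 = pg.analyze_phonation(egg)
    r2 = pg.analyze_phonation(scaled)
    assert r1.max_fdse_w == pytest.approx(r2.max_fdse_w, rel=1e-9)


def test_abrupt_exceeds_smooth_at_equal_noise():
    common = dict(oq_start=0.6, oq_end=0.75, noise_sd=0.02, seed=8)
    egg_a, _ = pg.synth_egg(pg.GlideSpec(strategy="abrupt", **common))
    egg_s, _ = pg.synth_egg(pg.GlideSpec(strategy="smooth_oq_up", **common))
    assert pg.analyze_phonation(egg_a).max_fdse_w > pg.analyze_phonation(egg_s).max_fdse_w
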