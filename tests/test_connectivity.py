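import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.special import i0, i1

from eegconn.connectivity import (bootstrap_baseline_mean, connection_summary,
                                  fuse_occipital, instantaneous_phase,
                                  plv_series, screen_eplv)
from eegconn.core import EpochSet

FS = 500.0


def _epochs(data, names):
    times = np.arange(-100, 501) / FS
    assert data.shape[2] == times.size
    return EpochSet(data, times, FS, names, ["A"] * data.shape[0])


# ------------------------------------------------------------------- fusion
def test_fusion_of_identical_channels_is_identity(rng):
    names = ["Oz", "O1", "O2", "POz", "PO3", "PO4"]
    one = rng.standard_normal((3, 1, 601))
    data = np.repeat(one, 6, axis=1)
    fused = fuse_occipital(_epochs(data, names))
    assert np.allclose(fused, one[:, 0, :])


def test_fusion_is_linear_and_zero_sum(rng):
    names = ["Oz", "O1", "O2", "POz", "PO3", "PO4"]
    a = rng.standard_normal((2, 6, 601))
    b = rng.standard_normal((2, 6, 601))
    f = lambda d: fuse_occipital(_epochs(d, names))
    assert np.allclose(f(a + b), f(a) + f(b))
    zero_sum = a - a.mean(axis=1, keepdims=True)
    assert np.abs(f(zero_sum)).max() < 1e-12


def test_fusion_missing_channel_named():
    with pytest.raises(ValueError, match="PO4"):
        fuse_occipital(_epochs(np.zeros((2, 5, 601)),
                               ["Oz", "O1", "O2", "POz", "PO3"]))


# -------------------------------------------------------------------- phase
def test_phase_slope_matches_frequency():
    t = np.arange(0, 2.0, 1 / FS)
    ph = instantaneous_phase(np.cos(2 * np.pi * 10 * t)[None], FS)[0]
    un = np.unwrap(ph)
    slope = np.polyfit(t[200:-200], un[200:-200], 1)[0]
    assert slope / (2 * np.pi) == pytest.approx(10.0, abs=0.05)
    # wraps ten times per second
    wraps = np.sum(np.diff(ph[200:-200]) < -np.pi)
    assert wraps == pytest.approx(10 * (t.size - 400) / FS, abs=1)


def test_sin_cos_quadrature():
    t = np.arange(0, 2.0, 1 / FS)
    ps = instantaneous_phase(np.sin(2 * np.pi * 8 * t)[None], FS)[0]
    pc = instantaneous_phase(np.cos(2 * np.pi * 8 * t)[None], FS)[0]
    gap = np.angle(np.exp(1j * (pc - ps)))[300:-300]
    assert np.abs(gap - np.pi / 2).max() < 0.02


def test_constant_input_errors():
    with pytest.raises(ValueError, match="constant"):
        instantaneous_phase(np.ones((2, 500)), FS)


# ---------------------------------------------------------------------- PLV
def test_identical_phases_give_unity():
    rng = np.random.default_rng(0)
    ph = rng.uniform(-np.pi, np.pi, (20, 50))
    s = plv_series(ph, ph)
    assert np.allclose(s.values, 1.0)


def test_uniform_null_expectation_is_one_over_n(rng):
    n = 100
    sp = rng.uniform(-np.pi, np.pi, (n, 300))
    tp = rng.uniform(-np.pi, np.pi, (n, 300))
    mean_plv = plv_series(sp, tp).values.mean()
    assert mean_plv == pytest.approx(1 / n, rel=0.3)


@pytest.mark.parametrize("kappa", [0.0, 1.0, 2.0, 4.0, 8.0])
def test_von_mises_concentration_recovery(kappa, rng):
    """Squared resultant matches the squared Bessel ratio (I1/I0)^2."""
    n = 200
    sp = rng.uniform(-np.pi, np.pi, (n, 100))
    tp = sp - rng.vonmises(0.7, kappa, (n, 100))   # lag Δ=0.7 is irrelevant
    est = plv_series(sp, tp).values.mean()
    expect = (i1(kappa) / i0(kappa)) ** 2
    assert est == pytest.approx(expect, abs=0.05)


def test_sqrt_convention_is_square_root(rng):
    sp = rng.uniform(-np.pi, np.pi, (50, 40))
    tp = sp - rng.vonmises(0.0, 2.0, (50, 40))
    sq = plv_series(sp, tp).values
    rt = plv_series(sp, tp, convention="sqrt").values
    assert np.allclose(rt, np.sqrt(sq))


def test_plv_symmetry_in_arguments(rng):
    sp = rng.uniform(-np.pi, np.pi, (30, 20))
    tp = rng.uniform(-np.pi, np.pi, (30, 20))
    assert np.allclose(plv_series(sp, tp).values, plv_series(tp, sp).values)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st_.integers(2, 40), st_.integers(1, 30), st_.integers(0, 2**31 - 1))
def test_plv_bounded_on_arbitrary_phases(n_epochs, n_times, seed):
    r = np.random.default_rng(seed)
    sp = r.uniform(-np.pi, np.pi, (n_epochs, n_times))
    tp = r.uniform(-np.pi, np.pi, (n_epochs, n_times))
    v = plv_series(sp, tp).values
    assert (v >= 0).all() and (v <= 1).all()


def test_plv_rejects_single_epoch():
    with pytest.raises(ValueError, match="2 epochs"):
        plv_series(np.zeros((1, 10)), np.ones((1, 10)))


# ---------------------------------------------------------------- baseline
def test_constant_baseline_is_exact():
    values = np.full(50, 0.3)
    mask = np.zeros(50, bool)
    mask[:10] = True
    assert bootstrap_baseline_mean(values, mask, n_boot=500, rng=0) == \
        pytest.approx(0.3)


def test_baseline_grand_mean_convex_and_lln(rng):
    values = np.concatenate([np.full(20, 0.1), np.full(20, 0.5),
                             np.zeros(60)])
    mask = np.zeros(100, bool)
    mask[:40] = True
    gm = bootstrap_baseline_mean(values, mask, n_boot=10_000, rng=3)
    assert 0.1 <= gm <= 0.5
    assert gm == pytest.approx(0.3, abs=0.01)


def test_baseline_too_short_errors():
    with pytest.raises(ValueError, match="2 time samples"):
        bootstrap_baseline_mean(np.arange(5.0), np.array([1, 0, 0, 0, 0], bool))


# ------------------------------------------------------------------ screen
def _null_stack(rng, n_part=6, n_targ=4, n_times=40, n_ep=30):
    times = np.linspace(-0.2, 0.6, n_times)
    stack = np.empty((n_part, n_targ, n_times))
    for p in range(n_part):
        for t in range(n_targ):
            sp = rng.uniform(-np.pi, np.pi, (n_ep, n_times))
            tp = rng.uniform(-np.pi, np.pi, (n_ep, n_times))
            stack[p, t] = plv_series(sp, tp).values
    return stack, times


def test_screen_constant_series_all_false(rng):
    times = np.linspace(-0.2, 0.6, 40)
    stack = np.full((5, 3, 40), 0.25)
    mask = screen_eplv(stack, times, ["a", "b", "c"], n_boot=200, seed=1)
    assert not mask.significant.any()


def test_screen_alpha_zero_all_false(rng):
    stack, times = _null_stack(rng)
    mask = screen_eplv(stack, times, list("abcd"), alpha=0.0, n_boot=200, seed=2)
    assert not mask.significant.any()


def test_screen_flags_elevated_target(rng):
    stack, times = _null_stack(rng)
    post = times >= 0.1
    stack[:, 2, post] += 0.5          # strong sustained elevation on one target
    mask = screen_eplv(stack, times, list("abcd"), n_boot=500, seed=3)
    assert mask.significant[2, post].mean() > 0.9
    assert mask.p_values[2, post].max() <= 0.05


def test_screen_requires_two_participants(rng):
    stack, times = _null_stack(rng, n_part=1)
    with pytest.raises(ValueError, match="2 participants"):
        screen_eplv(stack, times, list("abcd"), n_boot=100, seed=0)


def test_connection_summary_counts_and_tie_rule():
    times = np.linspace(-0.2, 0.6, 5)
    sig = np.zeros((3, 5), bool)
    mask = type("M", (), {"significant": sig, "times": times})
    s = connection_summary(mask)
    assert (s["counts"] == 0).all()
    assert s["peak_time"] == times[0]          # earliest on ties
    sig[1, 3] = True
    s = connection_summary(mask)
    assert s["peak_time"] == pytest.approx(times[3])
    assert s["peak_count"] == 1
    assert s["total_significant"] == 1
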