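import numpy as np
import pytest

from eegconn.core import EpochSet
from eegconn.montage import generate_montage
from eegconn.spectral import (compare_window_between_conditions, ersp,
                              erp_lateralization, morlet_tfr, mu_erd_ers,
                              surface_laplacian)

FS = 500.0
TIMES = np.arange(-100, 501) / FS


def _epochs(data, names, conditions=None):
    conditions = conditions or ["A"] * data.shape[0]
    return EpochSet(data, TIMES, FS, names, conditions)


def _tone_epochs(freq, amplitude=1.0, n_epochs=4, envelope=None, noise=0.0,
                 seed=0):
    rng = np.random.default_rng(seed)
    data = np.empty((n_epochs, 1, TIMES.size))
    for k in range(n_epochs):
        phase = rng.uniform(0, 2 * np.pi)
        x = amplitude * np.cos(2 * np.pi * freq * TIMES + phase)
        if envelope is not None:
            x = x * envelope
        data[k, 0] = x + noise * rng.standard_normal(TIMES.size)
    return _epochs(data, ["Cz"])


# ------------------------------------------------------------------- Morlet
def test_ridge_at_tone_frequency_and_flat_in_time():
    tfr = morlet_tfr(_tone_epochs(10.0), np.arange(5.0, 16.0))
    ridge = tfr.magnitude.mean(axis=(0, 1, 3))
    assert tfr.freqs[np.argmax(ridge)] == 10.0
    interior = ~tfr.edge_mask[np.where(tfr.freqs == 10.0)[0][0]]
    trace = tfr.magnitude[:, 0, np.where(tfr.freqs == 10.0)[0][0], interior]
    cv = trace.std() / trace.mean()
    assert cv < 0.05
    assert trace.mean() == pytest.approx(1.0, abs=0.05)  # unit-amplitude scaling


def test_linearity_in_amplitude():
    t1 = morlet_tfr(_tone_epochs(10.0, amplitude=1.0), [10.0])
    t2 = morlet_tfr(_tone_epochs(10.0, amplitude=2.0), [10.0])
    sel = ~t1.edge_mask[0]
    ratio = t2.magnitude[..., sel].mean() / t1.magnitude[..., sel].mean()
    assert ratio == pytest.approx(2.0, abs=0.02)


def test_two_tones_resolved():
    rng = np.random.default_rng(0)
    data = np.empty((3, 1, TIMES.size))
    for k in range(3):
        data[k, 0] = (np.cos(2 * np.pi * 6 * TIMES + rng.uniform(0, 6)) +
                      np.cos(2 * np.pi * 20 * TIMES + rng.uniform(0, 6)))
    tfr = morlet_tfr(_epochs(data, ["Cz"]), np.arange(3.0, 28.0), n_cycles=5.0)
    profile = tfr.magnitude[..., 150:450].mean(axis=(0, 1, 3))
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(profile, prominence=0.2)
    assert sorted(tfr.freqs[peaks].tolist()) == [6.0, 20.0]


def test_frequency_out_of_range_errors():
    with pytest.raises(ValueError, match="frequencies"):
        morlet_tfr(_tone_epochs(10.0), [300.0])


# -------------------------------------------------------------------- ERSP
def test_constant_magnitude_gives_zero_db():
    tfr = morlet_tfr(_tone_epochs(10.0), [10.0])
    m = ersp(tfr)
    sel = ~tfr.edge_mask[0]
    # the pre-stimulus baseline necessarily sits inside the flagged edge
    # zone; its residual coverage ripple bounds the attainable flatness
    assert np.abs(m.values[0, 0, sel]).max() < 0.25


@pytest.mark.parametrize("gain,expected", [(0.5, -3.01), (2.0, 3.01)])
def test_gain_recovery_in_db(gain, expected):
    envelope = np.ones(TIMES.size)
    win = (TIMES >= 0.3) & (TIMES <= 0.7)
    envelope[win] = gain
    tfr = morlet_tfr(_tone_epochs(10.0, envelope=envelope, n_epochs=8,
                                  noise=0.05),
                     np.arange(9.0, 12.0))
    m = ersp(tfr)
    core = (TIMES >= 0.4) & (TIMES <= 0.6)
    got = m.values[0][:, core].mean()
    assert got == pytest.approx(expected, abs=1.0)


def test_power_convention_doubles_db():
    envelope = np.ones(TIMES.size)
    win = (TIMES >= 0.3) & (TIMES <= 0.7)
    envelope[win] = 0.5
    tfr = morlet_tfr(_tone_epochs(10.0, envelope=envelope, n_epochs=4), [10.0])
    core = (TIMES >= 0.45) & (TIMES <= 0.55)
    mag = ersp(tfr).values[0, 0, core].mean()
    pow_ = ersp(tfr, convention="power").values[0, 0, core].mean()
    assert pow_ == pytest.approx(2 * mag, abs=0.1)


def test_zero_baseline_yields_nan_with_warning():
    data = np.zeros((2, 1, TIMES.size))
    data[:, 0, 350:] = np.cos(2 * np.pi * 10 * TIMES[350:])
    tfr = morlet_tfr(_epochs(data, ["Cz"]), [10.0])
    tfr.magnitude[..., TIMES < 0] = 0.0
    with pytest.warns(UserWarning, match="zero baseline"):
        m = ersp(tfr)
    assert np.isnan(m.values).all()


# ---------------------------------------------------------------- Laplacian
def test_laplacian_annihilates_uniform(montage):
    out = surface_laplacian(np.ones(64), montage)
    assert np.abs(out).max() < 1e-12


def test_laplacian_hotspot_signature(montage):
    hot = np.zeros(64)
    hot[montage.index("Cz")] = 1.0
    out = surface_laplacian(hot, montage)
    assert out[montage.index("Cz")] == pytest.approx(1.0)
    names, _ = montage.nearest_neighbours("Cz", 4)
    for n in names:
        assert out[montage.index(n)] < 0
    far = [c for c in montage.channel_names
           if c not in names + ["Cz"]
           and np.linalg.norm(np.subtract(montage.positions[c],
                                          montage.positions["Cz"])) > 0.5]
    assert np.abs(out[[montage.index(c) for c in far]]).max() < 0.05


def test_laplacian_attenuates_linear_gradient(montage):
    pos = montage.position_array()
    gradient = pos[:, 1]                      # anterior-posterior ramp
    out = surface_laplacian(gradient, montage)
    # interior channels ~0; rim channels keep some residual
    interior = np.linalg.norm(pos, axis=1) < 0.6
    assert np.abs(out[interior]).max() < 0.1 * np.ptp(gradient)


def test_laplacian_symmetric_input_sums_to_zeroish(montage):
    pos = montage.position_array()
    symmetric = np.cos(np.pi * pos[:, 1])     # left-right symmetric by design
    out = surface_laplacian(symmetric, montage)
    assert abs(out.sum()) < 0.15 * np.abs(symmetric).sum()


def test_laplacian_applies_along_named_axis(montage):
    rng = np.random.default_rng(0)
    block = rng.standard_normal((64, 3, 5))
    out = surface_laplacian(block, montage)
    single = surface_laplacian(block[:, 1, 2], montage)
    assert np.allclose(out[:, 1, 2], single)


# ---------------------------------------------------------------- mu ERD/ERS
def _mu_epochs(gain, window, channels, n_epochs=30, seed=0):
    """Alpha tone on given channels with a gain window, plus light noise."""
    rng = np.random.default_rng(seed)
    env = np.ones(TIMES.size)
    env[(TIMES >= window[0]) & (TIMES <= window[1])] = gain
    data = np.empty((n_epochs, len(channels), TIMES.size))
    for k in range(n_epochs):
        for c in range(len(channels)):
            ph = rng.uniform(0, 2 * np.pi)
            data[k, c] = env * np.cos(2 * np.pi * 10 * TIMES + ph) \
                + 0.1 * rng.standard_normal(TIMES.size)
    return _epochs(data, list(channels))


def test_erd_minimum_near_injected_window():
    epochs = _mu_epochs(0.5, (0.35, 0.45), ("C5", "CP3", "CP5"))
    tfr = morlet_tfr(epochs, np.arange(8.0, 14.0))
    res = mu_erd_ers(ersp(tfr), ["C5", "CP3", "CP5"])
    assert abs(res["erd_time"] - 0.40) <= 0.05
    assert res["erd_value"] < -1.5


def test_no_modulation_stays_flat():
    epochs = _mu_epochs(1.0, (0.3, 0.5), ("C5", "CP3", "CP5"))
    tfr = morlet_tfr(epochs, np.arange(8.0, 14.0))
    res = mu_erd_ers(ersp(tfr), ["C5", "CP3", "CP5"])
    assert np.abs(res["timecourse"]).max() < 1.0


def test_missing_roi_channel_errors():
    epochs = _mu_epochs(1.0, (0.3, 0.5), ("C5",))
    tfr = morlet_tfr(epochs, np.arange(8.0, 14.0))
    with pytest.raises(ValueError, match="CP3"):
        mu_erd_ers(ersp(tfr), ["C5", "CP3"])


def test_condition_comparison_detects_ers(rng):
    times = np.linspace(-0.2, 1.0, 61)
    sel = (times >= 0.1) & (times <= 0.2)
    a = rng.normal(0.0, 0.3, (19, 61))
    b = rng.normal(0.0, 0.3, (19, 61))
    a[:, sel] += 1.5
    res = compare_window_between_conditions(a, b, times, (0.1, 0.2), seed=4)
    assert res.p_value <= 0.05
    null = compare_window_between_conditions(b, b, times, (0.1, 0.2), seed=4)
    assert null.p_value > 0.05


# ----------------------------------------------------------------- ERP part
def _erp_epochs(amp_left, amp_right, latencies, conditions, n_per=25, seed=0):
    rng = np.random.default_rng(seed)
    labels, rows = [], []
    kernel = lambda lat: np.exp(-0.5 * ((TIMES - lat) / 0.03) ** 2)
    for cond in conditions:
        for _ in range(n_per):
            noise = 0.3 * rng.standard_normal((2, TIMES.size))
            left = right = 0.0
            for lat in latencies.get(cond, []):
                left = left + amp_left * kernel(lat)
                right = right + amp_right * kernel(lat)
            rows.append(np.stack([left + noise[0], right + noise[1]]))
            labels.append(cond)
    return EpochSet(np.array(rows), TIMES, FS, ["PO7", "PO8"], labels)


def test_symmetric_erps_give_zero_difference():
    epochs = _erp_epochs(4.0, 4.0, {"A": [0.26]}, ["A"])
    res = erp_lateralization(epochs)
    assert abs(res["per_condition"]["A"]["window_mean"]) < 0.2


def test_right_dominant_erp_gives_negative_difference():
    epochs = _erp_epochs(2.0, 6.0, {"A": [0.26]}, ["A"])
    res = erp_lateralization(epochs)
    a = res["per_condition"]["A"]
    assert a["window_mean"] < -2.0
    assert a["n_peaks"] >= 1


def test_two_components_give_two_peaks():
    epochs = _erp_epochs(2.0, 6.0, {"C": [0.15, 0.26], "A": [0.15]},
                         ["A", "C"])
    res = erp_lateralization(epochs, prominence=0.5)
    assert res["per_condition"]["C"]["n_peaks"] == 2
    assert res["per_condition"]["A"]["n_peaks"] == 1


def test_condition_anova_flags_lateralization_difference():
    epochs = _erp_epochs(2.0, 6.0, {"C": [0.26]}, ["A", "B", "C"])
    res = erp_lateralization(epochs)
    assert res["anova"]["p"] < 0.01
    assert res["anova"]["pairwise"][("A", "C")] is True
    assert res["anova"]["pairwise"][("A", "B")] is False


def test_missing_channel_errors():
    epochs = _erp_epochs(1.0, 1.0, {"A": [0.2]}, ["A"])
    with pytest.raises(ValueError, match="Cz"):
        erp_lateralization(epochs, left="Cz")
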