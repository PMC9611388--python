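import numpy as np
import pytest

from eegconn.core import BandSpec, ContinuousRecording, Event
from eegconn.preprocess import (amuse_decompose, bandpass_zero_phase,
                                extract_epochs, filter_bands,
                                rereference_common_average, reject_amplitude,
                                remove_eog_components)

FS = 500.0


def _rec(samples, events=(), fs=FS):
    names = [f"ch{i}" for i in range(samples.shape[0])]
    return ContinuousRecording(samples, fs, names, list(events))


# ---------------------------------------------------------------- reference
def test_car_zero_mean_and_idempotent(clean_recording):
    out = rereference_common_average(clean_recording)
    assert np.abs(out.samples.mean(axis=0)).max() < 1e-9
    again = rereference_common_average(out)
    assert np.allclose(again.samples, out.samples)


def test_car_examples():
    two = _rec(np.array([[5.0, 5.0], [-5.0, -5.0]]))
    assert np.allclose(rereference_common_average(two).samples, two.samples)
    offset = _rec(np.full((3, 4), 10.0))
    assert np.allclose(rereference_common_average(offset).samples, 0.0)


def test_car_single_channel_errors():
    with pytest.raises(ValueError, match="2 channels"):
        rereference_common_average(_rec(np.zeros((1, 10))))


# ----------------------------------------------------------------- bandpass
def test_passband_sinusoid_preserved():
    t = np.arange(0, 4.0, 1 / FS)
    x = np.cos(2 * np.pi * 10 * t)
    y = bandpass_zero_phase(_rec(np.array([x, x]))).samples[0]
    mid = slice(500, -500)
    amp = np.abs(np.fft.rfft(y[mid] * np.hanning(y[mid].size))).max() / \
        np.abs(np.fft.rfft(x[mid] * np.hanning(x[mid].size))).max()
    assert amp == pytest.approx(1.0, abs=0.01)
    # zero phase shift: cross-correlation peaks at lag 0
    lagged = np.array([np.dot(y[mid], np.roll(x, k)[mid]) for k in (-1, 0, 1)])
    assert lagged.argmax() == 1
    phase_gap = np.angle(np.vdot(np.fft.rfft(x[mid]), np.fft.rfft(y[mid])))
    assert abs(phase_gap) < 0.01


def test_stopband_and_dc_rejected():
    t = np.arange(0, 4.0, 1 / FS)
    hum = np.cos(2 * np.pi * 50 * t)
    y = bandpass_zero_phase(_rec(np.array([hum, hum]))).samples[0]
    assert np.abs(y[300:-300]).max() < 0.01
    dc = bandpass_zero_phase(_rec(np.full((2, 2000), 7.0))).samples
    assert np.abs(dc.mean()) < 1e-9


def test_high_cut_above_nyquist_errors():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_zero_phase(_rec(np.zeros((2, 1000))), 1.0, 300.0)


# -------------------------------------------------------------------- AMUSE
def test_amuse_recovers_two_sinusoid_mixture(rng):
    t = np.arange(0, 20.0, 1 / FS)
    sources = np.array([np.sin(2 * np.pi * 2 * t), np.sin(2 * np.pi * 20 * t)])
    theta = 0.7
    mixing = np.array([[np.cos(theta), -np.sin(theta)],
                       [np.sin(theta), np.cos(theta)]])
    rec = _rec(mixing @ sources)
    res = amuse_decompose(rec)
    corr = np.corrcoef(np.vstack([res.components, sources]))[:2, 2:]
    best = np.abs(corr).max(axis=1)
    assert (best >= 0.99).all()
    # zero-lag decorrelation contract
    c = np.corrcoef(res.components)
    assert np.abs(c - np.eye(2)).max() < 1e-6


def test_amuse_identity_mixing_recovered_up_to_perm_sign_scale(rng):
    # two AR-distinct noise sources, identity mixing
    n = 8000
    s1 = np.convolve(rng.standard_normal(n), np.ones(20) / 20, mode="same")
    s2 = rng.standard_normal(n)
    rec = _rec(np.array([s1, s2]))
    res = amuse_decompose(rec)
    # mixing recovered up to permutation/sign/scale: normalized columns of
    # the estimate match identity columns up to those symmetries
    m = res.mixing / np.linalg.norm(res.mixing, axis=0, keepdims=True)
    gram = np.abs(m.T @ np.eye(2))
    assert ((gram > 0.95).sum(axis=1) == 1).all()


def test_amuse_reconstruction_identity(clean_recording):
    rec = rereference_common_average(clean_recording)
    res = amuse_decompose(rec)
    recon = res.mixing @ res.components + res.mean
    assert np.abs(recon - rec.samples).max() < 1e-9


def test_amuse_duplicate_channels_error_names_offenders():
    t = np.arange(0, 5.0, 1 / FS)
    x = np.sin(2 * np.pi * 3 * t)
    y = np.sin(2 * np.pi * 11 * t)
    rec = ContinuousRecording(np.array([x, y, x, y]), FS,
                              ["a", "b", "a_copy", "b_copy"])
    with pytest.raises(ValueError, match="a_copy|a"):
        amuse_decompose(rec)


def test_remove_zero_components_is_identity(clean_recording):
    rec = rereference_common_average(clean_recording)
    res = amuse_decompose(rec)
    clean, removed = remove_eog_components(res, ["Fp1", "Fpz", "Fp2"],
                                           threshold=1.1)  # nothing can reach it
    assert removed == []
    assert np.abs(clean.samples - rec.samples).max() < 1e-9


def test_no_blinks_removes_nothing(clean_recording):
    rec = rereference_common_average(clean_recording)
    res = amuse_decompose(bandpass_zero_phase(rec))
    _, removed = remove_eog_components(res, ["Fp1", "Fpz", "Fp2"], threshold=0.7)
    assert removed == []


# ----------------------------------------------------------------- epoching
def test_epoch_counts_and_duration(small_recording, small_config):
    epochs = extract_epochs(small_recording, -0.2, 1.0)
    n_events = len(small_recording.events)
    assert epochs.n_epochs == n_events
    assert epochs.data.shape[2] == int(1.2 * FS) + 1
    assert epochs.times[0] == pytest.approx(-0.2)
    assert 0.0 in epochs.times
    assert (epochs.rejection_log["kept"]).all()


def test_event_at_edge_dropped_and_logged():
    rec = _rec(np.zeros((2, 1300)), events=[Event(0, "A"), Event(500, "A")])
    epochs = extract_epochs(rec, -0.2, 1.0)
    assert epochs.n_epochs == 1
    log = epochs.rejection_log
    assert len(log) == 2
    assert not log.loc[0, "kept"]
    assert "outside recording" in log.loc[0, "reason"]


def test_rejection_strictly_above_threshold():
    data = np.zeros((3, 2, 601))
    data[1, 0, 300] = 101.0     # dropped: strictly above
    data[2, 1, 300] = 100.0     # kept: exactly at threshold
    rec_times = np.arange(-100, 501) / FS
    from eegconn.core import EpochSet
    epochs = EpochSet(data, rec_times, FS, ["a", "b"], ["A", "B", "C"])
    out = reject_amplitude(epochs, 100.0)
    assert out.n_epochs == 2
    assert out.conditions == ["A", "C"]
    kept_plus_dropped = len(out.rejection_log)
    assert kept_plus_dropped == 3
    assert out.survival_fraction == pytest.approx(2 / 3)


def test_rejection_survival_matches_outlier_rate():
    """~2% outlier trials leave ~98% surviving (binomial 99% interval)."""
    from eegconn.synth import SynthConfig, generate_recording
    kept = total = 0
    for seed in range(4):
        cfg = SynthConfig(sessions=("s",), n_trials_per_condition=15,
                          blink_rate=0.0, outlier_trial_fraction=0.02,
                          seed=100 + seed)
        epochs = reject_amplitude(extract_epochs(generate_recording(cfg)))
        kept += epochs.n_epochs
        total += 60
    # 240 trials at p=0.02: 99% interval for dropped is [0, 11]
    assert total - kept <= 11


# ------------------------------------------------------------- band filters
def test_band_splitting_selectivity():
    t = np.arange(0, 3.0, 1 / FS)
    rec = _rec(np.array([np.cos(2 * np.pi * 10 * t), np.cos(2 * np.pi * 20 * t)]),
               events=[Event(750, "A"), Event(1450, "A")])
    epochs = extract_epochs(rec, -0.2, 1.0)
    bands = filter_bands(epochs)
    assert set(bands) == {"delta", "theta", "alpha", "beta"}
    assert all(b.n_epochs == epochs.n_epochs for b in bands.values())
    mid = slice(150, 450)
    rms = {name: np.sqrt((b.data[:, :, mid] ** 2).mean(axis=(0, 2)))
           for name, b in bands.items()}
    # 10 Hz channel survives only in alpha; 20 Hz only in beta
    assert rms["alpha"][0] > 0.5 and rms["beta"][0] < 0.05
    assert rms["beta"][1] > 0.5 and rms["alpha"][1] < 0.05
    assert rms["delta"][0] < 0.05 and rms["theta"][0] < 0.05


def test_filtering_and_epoching_commute(clean_recording):
    """Band-filter then epoch equals epoch then band-filter (source-linked)."""
    band = BandSpec("alpha", 8.0, 13.0)
    filtered = clean_recording.copy_with(
        __import__("eegconn.filters", fromlist=["fft_bandpass"]).fft_bandpass(
            clean_recording.samples, FS, band.low, band.high))
    filtered.events = clean_recording.events
    route_a = extract_epochs(filtered, -0.2, 1.0).data
    route_b = filter_bands(extract_epochs(clean_recording, -0.2, 1.0),
                           (band,))["alpha"].data
    assert np.abs(route_a - route_b).max() < 1e-6
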