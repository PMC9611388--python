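"""Time-frequency analysis: Morlet ERSP, surface Laplacian, ERD/ERS, ERPs.

Event-related spectral perturbation (ERSP) is computed per epoch as

    ERSP_{i,j} = 10 · log10( u_{i,j} / baseline_j ),

where u_{i,j} is the Morlet wavelet-coefficient magnitude at time i and
frequency j and baseline_j is its pre-stimulus average at that frequency,
then averaged across epochs.  The default operates on magnitudes exactly as
the formula above prints; ``convention="power"`` squares u first.

The surface Laplacian is the Hjorth finite-difference form: each channel's
value minus the inverse-distance-weighted mean of its k nearest neighbours
on the montage disc.  It sharpens focal activity and suppresses spatially
broad, volume-conducted components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, find_peaks

from .core import EpochSet
from .montage import Montage
from .stats import anova_one_way, permutation_test_independent

__all__ = [
    "TFR", "ERSPMap", "default_n_cycles", "morlet_tfr", "ersp",
    "surface_laplacian", "mu_erd_ers", "compare_window_between_conditions",
    "erp_lateralization",
]


@dataclass
class TFR:
    """Per-epoch Morlet wavelet magnitudes (epochs × channels × freqs × times)."""

    magnitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: list[str]
    edge_mask: np.ndarray        # (freqs, times) True where inside a half-width of an edge


@dataclass
class ERSPMap:
    """Across-epoch ERSP in dB, with the underlying magnitudes kept."""

    values: np.ndarray           # (channels, freqs, times), dB
    freqs: np.ndarray
    times: np.ndarray
    channels: list[str]
    baseline_window: tuple[float, float]
    magnitude: np.ndarray        # mean u over epochs, (channels, freqs, times)
    baseline: np.ndarray         # mean baseline_j over epochs, (channels, freqs)
    edge_mask: np.ndarray

    def band_average(self, band: tuple[float, float],
                     channels: list[str] | None = None) -> np.ndarray:
        """Time course averaged over a frequency band and channel set."""
        fsel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not fsel.any():
            raise ValueError(f"no analyzed frequencies inside band {band}")
        if channels is None:
            csel = np.arange(len(self.channels))
        else:
            missing = [c for c in channels if c not in self.channels]
            if missing:
                raise ValueError(f"channels missing from ERSP map: {missing}")
            csel = [self.channels.index(c) for c in channels]
        return self.values[csel][:, fsel, :].mean(axis=(0, 1))


def default_n_cycles(freqs: np.ndarray) -> np.ndarray:
    """Linear ramp: 3 cycles at 1 Hz up to 8 cycles at 30 Hz."""
    freqs = np.asarray(freqs, dtype=float)
    return np.clip(3.0 + 5.0 * (freqs - 1.0) / 29.0, 3.0, 8.0)


def _morlet_kernel(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet scaled for unit response to a unit sinusoid."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-0.5 * (t / sigma_t) ** 2)
    kernel = envelope * np.exp(2j * np.pi * freq * t)
    return kernel / (0.5 * envelope.sum())


def morlet_tfr(epochs: EpochSet, freqs, n_cycles=None,
               channels: list[str] | None = None) -> TFR:
    """Continuous Morlet wavelet magnitude per epoch, channel and frequency.

    ``channels`` restricts the decomposition (the full 4-D array is large);
    edge samples within one wavelet half-width (4σ_t) of either epoch edge
    are flagged in ``edge_mask``.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    fs = epochs.sampling_rate
    nyq = fs / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError(f"frequencies must lie in (0, {nyq}) Hz")
    if n_cycles is None:
        n_cycles = default_n_cycles(freqs)
    n_cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float), freqs.shape)
    if channels is None:
        channels = list(epochs.channel_names)
    idx = [epochs.channel_index(c) for c in channels]
    n_times = epochs.data.shape[-1]
    n_epochs = epochs.n_epochs

    # When the epoch set still points at the continuous recording it was cut
    # from, convolve on wider segments of that recording and crop: the
    # wavelet then never meets an artificial edge inside the epoch and the
    # pre-stimulus baseline is unbiased for noise and tone alike.
    source = getattr(epochs, "source", None)
    samples = getattr(epochs, "event_samples", [])
    halves = [int(np.ceil(4.0 * nc / (2.0 * np.pi * f) * fs))
              for f, nc in zip(freqs, n_cycles)]
    pad = max(halves) if halves else 0
    use_source = (source is not None and len(samples) == n_epochs
                  and n_epochs > 0)
    if use_source:
        i0 = int(round(epochs.times[0] * fs))
        i1 = int(round(epochs.times[-1] * fs))
        pad_l = min(pad, min(s + i0 for s in samples))
        pad_r = min(pad, source.n_times - 1 - max(s + i1 for s in samples))
        pad_l, pad_r = max(pad_l, 0), max(pad_r, 0)
        data = np.stack([
            source.samples[np.ix_(idx, range(s + i0 - pad_l, s + i1 + 1 + pad_r))]
            for s in samples])
    else:
        pad_l = pad_r = 0
        data = epochs.data[:, idx, :]

    mag = np.empty((n_epochs, len(idx), freqs.size, n_times))
    edge = np.zeros((freqs.size, n_times), dtype=bool)
    ones = np.ones(data.shape[-1])
    for j, (f, nc) in enumerate(zip(freqs, n_cycles)):
        kernel = _morlet_kernel(f, nc, fs)
        half = (kernel.size - 1) // 2
        conv = fftconvolve(data, kernel[None, None, :], mode="same", axes=-1)
        if use_source:
            mag[:, :, j, :] = np.abs(conv[..., pad_l:pad_l + n_times])
        else:
            # coverage normalization: exact for deterministic narrowband
            # input, approximate (√coverage would be exact) for noise —
            # hence edges stay flagged on this fallback path
            envelope = np.abs(kernel)
            coverage = fftconvolve(ones, envelope, mode="same") / envelope.sum()
            mag[:, :, j, :] = np.abs(conv / coverage)
        # flag samples whose wavelet support was not fully covered by data
        k_l = min(max(half - pad_l, 0), n_times)
        k_r = min(max(half - pad_r, 0), n_times)
        edge[j, :k_l] = True
        if k_r:
            edge[j, n_times - k_r:] = True
    return TFR(mag, freqs, epochs.times.copy(), list(channels), edge)


def ersp(tfr: TFR, baseline_window: tuple[float, float] = (-0.2, 0.0),
         convention: str = "magnitude") -> ERSPMap:
    """Baseline-normalized dB map, per epoch then averaged across epochs."""
    if convention not in ("magnitude", "power"):
        raise ValueError(f"unknown convention {convention!r}")
    lo, hi = baseline_window
    bsel = (tfr.times >= lo) & (tfr.times < hi)
    if not bsel.any():
        raise ValueError(f"baseline window {baseline_window} outside epoch times")
    u = tfr.magnitude if convention == "magnitude" else tfr.magnitude ** 2
    baseline = u[..., bsel].mean(axis=-1)                 # (epochs, channels, freqs)
    zero = baseline == 0
    if zero.any():
        warnings.warn("zero baseline magnitude; ERSP set to NaN there", stacklevel=2)
        baseline = np.where(zero, np.nan, baseline)
    db = 10.0 * np.log10(u / baseline[..., None])
    return ERSPMap(
        values=db.mean(axis=0),
        freqs=tfr.freqs.copy(),
        times=tfr.times.copy(),
        channels=list(tfr.channels),
        baseline_window=baseline_window,
        magnitude=tfr.magnitude.mean(axis=0),
        baseline=tfr.magnitude[..., bsel].mean(axis=-1).mean(axis=0),
        edge_mask=tfr.edge_mask.copy(),
    )


def surface_laplacian(values: np.ndarray, montage: Montage,
                      channels: list[str] | None = None, k: int = 4,
                      channel_axis: int = 0) -> np.ndarray:
    """Hjorth finite-difference Laplacian of a scalp topography.

    Each channel's value minus the 1/distance-weighted mean of its ``k``
    nearest montage neighbours (restricted to the channels present in
    ``values``).  Works on any array with a channel axis, e.g. an ERSP
    channel × frequency × time block.
    """
    values = np.asarray(values, dtype=float)
    if channels is None:
        channels = list(montage.channel_names)
    if values.shape[channel_axis] != len(channels):
        raise ValueError(
            f"axis {channel_axis} has length {values.shape[channel_axis]} "
            f"but {len(channels)} channels were named"
        )
    pos = montage.position_array(channels)
    n = len(channels)
    if n - 1 < k:
        warnings.warn(
            f"only {n - 1} neighbours available; using all of them", stacklevel=2)
        k = n - 1
    weights = np.zeros((n, n))
    for i in range(n):
        d = np.linalg.norm(pos - pos[i], axis=1)
        d[i] = np.inf
        nearest = np.argsort(d, kind="stable")[:k]
        w = 1.0 / d[nearest]
        weights[i, nearest] = w / w.sum()
    moved = np.moveaxis(values, channel_axis, 0)
    out = moved - np.tensordot(weights, moved, axes=(1, 0))
    return np.moveaxis(out, 0, channel_axis)


def mu_erd_ers(ersp_map: ERSPMap, roi_channels: list[str],
               band: tuple[float, float] = (8.0, 13.0)) -> dict:
    """ROI- and band-averaged ERSP time course with ERD/ERS excursions.

    ERD is the most negative post-stimulus value (desynchronization), ERS
    the most positive; both are reported with their times.
    """
    tc = ersp_map.band_average(band, roi_channels)
    post = ersp_map.times >= 0
    t_post, tc_post = ersp_map.times[post], tc[post]
    erd_i = int(np.argmin(tc_post))
    ers_i = int(np.argmax(tc_post))
    return {
        "times": ersp_map.times,
        "timecourse": tc,
        "erd_time": float(t_post[erd_i]),
        "erd_value": float(tc_post[erd_i]),
        "ers_time": float(t_post[ers_i]),
        "ers_value": float(tc_post[ers_i]),
    }


def compare_window_between_conditions(timecourses_a: np.ndarray,
                                      timecourses_b: np.ndarray,
                                      times: np.ndarray,
                                      window: tuple[float, float],
                                      n_resamples: int = 10_000,
                                      seed: int | None = None):
    """Permutation test of condition A > condition B ERSP inside a window.

    ``timecourses_*`` are (participants, times) ROI time courses; each
    participant contributes their window-mean ERSP to the test sample.
    """
    times = np.asarray(times, dtype=float)
    sel = (times >= window[0]) & (times <= window[1])
    if not sel.any():
        raise ValueError(f"window {window} contains no time samples")
    samp_a = np.asarray(timecourses_a)[:, sel].mean(axis=1)
    samp_b = np.asarray(timecourses_b)[:, sel].mean(axis=1)
    return permutation_test_independent(samp_a, samp_b,
                                        n_resamples=n_resamples, seed=seed)


def erp_lateralization(epochs: EpochSet, left: str = "PO7", right: str = "PO8",
                       window: tuple[float, float] = (0.246, 0.300),
                       prominence: float = 0.5, alpha: float = 0.05) -> dict:
    """Left-right ERP asymmetry between two posterior electrodes.

    Epochs are baseline-corrected (pre-stimulus mean subtracted), grand-
    averaged per condition at both channels, and the (left − right)
    difference waveform is summarized: per-condition window means ± SE over
    epochs, local-extrema count on the post-stimulus difference (peaks of
    |difference| with the given prominence in µV), and a one-way ANOVA with
    Tukey pairwise flags across conditions on the per-epoch window means.
    """
    for ch in (left, right):
        if ch not in epochs.channel_names:
            raise ValueError(f"channel {ch!r} not present")
    conditions = sorted(set(epochs.conditions))
    if not conditions:
        raise ValueError("no epochs to analyze")
    bsel = epochs.baseline_mask()
    li, ri = epochs.channel_index(left), epochs.channel_index(right)
    pair = epochs.data[:, [li, ri], :]
    pair = pair - pair[..., bsel].mean(axis=-1, keepdims=True)
    wsel = (epochs.times >= window[0]) & (epochs.times <= window[1])
    if not wsel.any():
        raise ValueError(f"analysis window {window} outside epoch times")
    post = epochs.times >= 0

    per_condition: dict[str, dict] = {}
    groups = []
    cond_labels = np.asarray(epochs.conditions)
    for cond in conditions:
        esel = cond_labels == cond
        if not esel.any():
            raise ValueError(f"condition {cond!r} has no epochs")
        erp_pair = pair[esel].mean(axis=0)            # (2, n_times)
        diff = erp_pair[0] - erp_pair[1]
        per_epoch = (pair[esel, 0][:, wsel] - pair[esel, 1][:, wsel]).mean(axis=1)
        peaks, _ = find_peaks(np.abs(diff[post]), prominence=prominence)
        per_condition[cond] = {
            "erp_left": erp_pair[0],
            "erp_right": erp_pair[1],
            "difference": diff,
            "window_mean": float(per_epoch.mean()),
            "window_se": float(per_epoch.std(ddof=1) / np.sqrt(per_epoch.size))
            if per_epoch.size > 1 else float("nan"),
            "n_peaks": int(peaks.size),
            "peak_times": epochs.times[post][peaks],
        }
        groups.append(per_epoch)
    result = {"conditions": conditions, "per_condition": per_condition,
              "times": epochs.times, "window": window}
    if len(conditions) >= 2 and all(g.size >= 2 for g in groups):
        f_stat, p, pairwise = anova_one_way(groups, alpha=alpha)
        result["anova"] = {
            "F": f_stat, "p": p,
            "pairwise": {(conditions[i], conditions[j]): flag
                         for (i, j), flag in pairwise.items()},
        }
    return result
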