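"""Preprocessing chain for continuous EEG.

Order of operations mirrors the analysis this package reproduces:
common-average re-reference → zero-phase 1–30 Hz bandpass → AMUSE blind
source separation with EOG-component removal → epoch extraction with a
200 ms pre-stimulus baseline → 100 µV amplitude rejection → band splitting
(delta/theta/alpha/beta).

Epoch sets keep a link to the continuous recording they were cut from, so
band filtering re-filters the continuous data and re-cuts the same epochs:
filtering and epoching then commute exactly and epoch-edge filter
transients never enter the analysis windows.  Epoch sets without a source
link are filtered per-epoch with mirror padding instead.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .core import BandSpec, ContinuousRecording, DEFAULT_BANDS, EpochSet
from .filters import fft_bandpass

__all__ = [
    "rereference_common_average", "bandpass_zero_phase",
    "AmuseResult", "amuse_decompose", "remove_eog_components",
    "extract_epochs", "reject_amplitude", "filter_bands",
]


def rereference_common_average(rec: ContinuousRecording) -> ContinuousRecording:
    """Subtract the across-channel mean at every sample."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    return rec.copy_with(rec.samples - rec.samples.mean(axis=0, keepdims=True))


def bandpass_zero_phase(rec: ContinuousRecording, low: float = 1.0,
                        high: float = 30.0) -> ContinuousRecording:
    """Zero-phase frequency-domain bandpass of the continuous recording."""
    return rec.copy_with(fft_bandpass(rec.samples, rec.sampling_rate, low, high))


class AmuseResult:
    """Output of AMUSE: uncorrelated components plus the mixing estimate.

    ``components`` is (n_components, n_times); ``mixing`` maps component
    space back to channel space (channels × components); ``unmixing`` is its
    inverse.  Components are ordered by descending symmetrized lag-τ
    covariance eigenvalue.
    """

    def __init__(self, components: np.ndarray, mixing: np.ndarray,
                 unmixing: np.ndarray, mean: np.ndarray, eigenvalues: np.ndarray,
                 rec: ContinuousRecording):
        self.components = components
        self.mixing = mixing
        self.unmixing = unmixing
        self.mean = mean
        self.eigenvalues = eigenvalues
        self.rec = rec


def amuse_decompose(rec: ContinuousRecording, lag: int = 1,
                    rank_tol: float = 1e-10) -> AmuseResult:
    """Second-order blind source separation (AMUSE).

    Whiten via the zero-lag covariance eigendecomposition, then
    eigendecompose the symmetrized lag-``lag`` covariance of the whitened
    data; its eigenvectors give the rotation that separates sources with
    distinct lagged autocovariances.
    """
    if rec.n_channels < 2:
        raise ValueError("AMUSE needs at least 2 channels")
    x = rec.samples
    if x.shape[1] <= 10 * lag:
        raise ValueError("recording too short for the requested lag")
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    c0 = xc @ xc.T / xc.shape[1]
    evals, evecs = np.linalg.eigh(c0)
    bad = evals < rank_tol * evals.max()
    # a common-average reference removes exactly one dimension; whiten onto
    # the remaining subspace silently.  Losing more than one indicates
    # duplicated or flat channels and is a data error.
    if bad.sum() > 1:
        offenders = sorted({
            rec.channel_names[i]
            for j in np.flatnonzero(bad)
            for i in np.flatnonzero(np.abs(evecs[:, j]) > 0.3)
        })
        raise ValueError(
            f"rank-deficient channel covariance; offending channels: {offenders}"
        )
    keep = ~bad
    evals, evecs = evals[keep], evecs[:, keep]
    whiten = (evecs / np.sqrt(evals)).T          # rows scaled: D^-1/2 E^T
    z = whiten @ xc
    c_tau = z[:, :-lag] @ z[:, lag:].T / (z.shape[1] - lag)
    c_sym = (c_tau + c_tau.T) / 2.0
    lam, v = np.linalg.eigh(c_sym)
    order = np.argsort(lam)[::-1]
    lam, v = lam[order], v[:, order]
    unmixing = v.T @ whiten
    mixing = evecs @ np.diag(np.sqrt(evals)) @ v  # == pinv(unmixing)
    components = unmixing @ xc
    return AmuseResult(components, mixing, unmixing, mean, lam, rec)


def remove_eog_components(result: AmuseResult, eog_proxy_channels: list[str],
                          threshold: float = 0.7
                          ) -> tuple[ContinuousRecording, list[int]]:
    """Zero components correlated with frontal proxy channels and rebuild.

    A component is flagged when its absolute Pearson correlation with any
    proxy channel's (pre-decomposition) time series reaches ``threshold``.
    Returns the reconstructed recording and the removed component indices.
    """
    rec = result.rec
    proxy_idx = [rec.channel_index(c) for c in eog_proxy_channels]
    proxies = rec.samples[proxy_idx] - rec.samples[proxy_idx].mean(axis=1, keepdims=True)
    comps = result.components - result.components.mean(axis=1, keepdims=True)
    removed: list[int] = []
    for i, comp in enumerate(comps):
        cs = comp.std()
        if cs == 0:
            continue
        r = np.abs(proxies @ comp) / (np.linalg.norm(proxies, axis=1) * np.linalg.norm(comp))
        if np.any(r >= threshold):
            removed.append(i)
    if len(removed) == result.components.shape[0]:
        raise ValueError(
            "every component flagged as EOG; threshold "
            f"{threshold} is likely misconfigured"
        )
    kept = result.components.copy()
    kept[removed] = 0.0
    clean = result.mixing @ kept + result.mean
    return rec.copy_with(clean), removed


def extract_epochs(rec: ContinuousRecording, tmin: float = -0.2,
                   tmax: float = 1.0) -> EpochSet:
    """Cut one stimulus-locked epoch per event.

    Events whose window would cross a recording edge are dropped and logged.
    The time axis runs ``tmin`` to ``tmax`` inclusive, with t = 0 on the grid.
    """
    fs = rec.sampling_rate
    i0, i1 = int(round(tmin * fs)), int(round(tmax * fs))
    times = np.arange(i0, i1 + 1) / fs
    data, conds, sessions, samples = [], [], [], []
    log_rows = []
    for k, ev in enumerate(rec.events):
        lo, hi = ev.sample + i0, ev.sample + i1 + 1
        if lo < 0 or hi > rec.n_times:
            log_rows.append({"epoch": k, "condition": ev.condition,
                             "kept": False, "reason": "epoch window outside recording"})
            continue
        data.append(rec.samples[:, lo:hi])
        conds.append(ev.condition)
        sessions.append(ev.session)
        samples.append(ev.sample)
        log_rows.append({"epoch": k, "condition": ev.condition,
                         "kept": True, "reason": ""})
    log = pd.DataFrame(log_rows, columns=["epoch", "condition", "kept", "reason"])
    epochs = EpochSet(
        np.array(data) if data else np.empty((0, rec.n_channels, times.size)),
        times, fs, list(rec.channel_names), conds, sessions,
        baseline_window=(tmin, 0.0) if tmin < 0 else (tmin, tmax),
        rejection_log=log,
    )
    epochs.source = rec
    epochs.event_samples = samples
    return epochs


def reject_amplitude(epochs: EpochSet, threshold: float = 100.0) -> EpochSet:
    """Drop epochs containing any potential strictly above ``threshold`` µV."""
    peak = np.abs(epochs.data).max(axis=(1, 2)) if epochs.n_epochs else np.empty(0)
    keep = peak <= threshold
    log = epochs.rejection_log.copy()
    if not len(log):
        log = pd.DataFrame({"epoch": range(epochs.n_epochs),
                            "condition": epochs.conditions,
                            "kept": True, "reason": ""})
    kept_ids = log.index[log["kept"]].tolist()
    for local, ok in enumerate(keep):
        if not ok and local < len(kept_ids):
            row = kept_ids[local]
            log.loc[row, ["kept", "reason"]] = [False, f"amplitude > {threshold:g} uV"]
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size == 0:
        warnings.warn("amplitude rejection removed every epoch", stacklevel=2)
    out = replace(
        epochs,
        data=epochs.data[kept_idx],
        conditions=[epochs.conditions[i] for i in kept_idx],
        sessions=[epochs.sessions[i] for i in kept_idx],
        rejection_log=log,
    )
    out.source = getattr(epochs, "source", None)
    src_samples = getattr(epochs, "event_samples", [])
    out.event_samples = [src_samples[i] for i in kept_idx] if src_samples else []
    out.survival_fraction = float(kept_idx.size / max(epochs.n_epochs, 1))
    return out


def _filter_epochset(epochs: EpochSet, band: BandSpec) -> EpochSet:
    source = getattr(epochs, "source", None)
    samples = getattr(epochs, "event_samples", [])
    fs = epochs.sampling_rate
    if source is not None and len(samples) == epochs.n_epochs and epochs.n_epochs:
        # filter the continuous data once, then re-cut the surviving epochs:
        # commutes exactly with epoching and avoids epoch-edge transients
        filtered = fft_bandpass(source.samples, fs, band.low, band.high)
        i0 = int(round(epochs.times[0] * fs))
        i1 = int(round(epochs.times[-1] * fs))
        data = np.stack([filtered[:, s + i0: s + i1 + 1] for s in samples])
        source = source.copy_with(filtered)   # keep the link consistent
    else:
        # mirror-pad 200 ms per side to tame the circular-FFT edge
        pad = int(round(0.2 * fs))
        pad = min(pad, max(epochs.data.shape[-1] - 1, 1))
        padded = np.concatenate(
            [epochs.data[..., pad:0:-1], epochs.data, epochs.data[..., -2:-pad - 2:-1]],
            axis=-1,
        )
        data = fft_bandpass(padded, fs, band.low, band.high)[..., pad:pad + epochs.data.shape[-1]]
    out = epochs.copy_with(data)
    out.source = source
    out.event_samples = list(samples)
    return out


def filter_bands(epochs: EpochSet,
                 bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> dict[str, EpochSet]:
    """Zero-phase band-filtered copies of the epoch set, one per band."""
    for band in bands:
        band.validate(epochs.sampling_rate)
    return {band.name: _filter_epochset(epochs, band) for band in bands}
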