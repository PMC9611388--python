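"""Synthetic multichannel EEG with known ground truth.

The generator emulates the statistical structure of a visual-object EEG
study: 500 Hz multichannel recordings, four stimulus conditions presented in
randomized order within object sessions, a 1 s fixation cross before each
stimulus and a 1–2 s jittered inter-trial interval.  On top of a 1/f^α
pink-noise background it injects

* **phase coupling** — a band-limited oscillation added to the occipital
  seed channels and a phase-lagged, von-Mises-jittered copy added to target
  channels inside a post-stimulus window (ground truth for connectivity);
* **band-power modulation** — the background's band-limited component has
  its envelope scaled by a gain inside a window (<1 = ERD, >1 = ERS);
* **ERP components** — Gaussian-windowed deflections, optionally with
  left/right amplitude asymmetry;
* **artifacts** — frontal-dominant blink transients (rank-1 in space, so a
  second-order blind separation can find them) and rare >100 µV outlier
  excursions on single channels.

Everything is reproducible bit-for-bit from ``SynthConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ContinuousRecording, Event
from .filters import fft_bandpass
from .montage import Montage, generate_montage

__all__ = [
    "CouplingSpec", "PowerModSpec", "ErpSpec", "SynthConfig", "TruthTables",
    "generate_recording", "ground_truth",
]

_ALL_CONDITIONS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class CouplingSpec:
    """Seed-to-target phase coupling injected in a post-stimulus window.

    A sinusoid at ``band_center`` with a fresh uniform phase per trial is
    added to every channel of ``seed_region``; each target channel receives
    a copy shifted by ``phase_lag`` plus von Mises(0, ``concentration``)
    phase noise drawn per trial and target.  ``concentration`` (κ) may be
    ``inf`` for perfectly locked phases; κ = 0 gives uniform jitter.
    """

    target_channels: tuple[str, ...]
    band_center: float                       # Hz
    phase_lag: float = 0.0                   # radians
    concentration: float = 4.0               # von Mises κ
    window: tuple[float, float] = (0.15, 0.40)   # s post-onset
    conditions: tuple[str, ...] = _ALL_CONDITIONS
    seed_region: str = "OCC_SEED"
    amplitude: float = 5.0                   # µV


@dataclass(frozen=True)
class PowerModSpec:
    """Multiplicative gain on the background's band-limited envelope."""

    channels: tuple[str, ...]
    band: tuple[float, float]                # Hz
    gain: float                              # <1 ERD, >1 ERS
    window: tuple[float, float]              # s post-onset
    conditions: tuple[str, ...] = _ALL_CONDITIONS


@dataclass(frozen=True)
class ErpSpec:
    """Gaussian-windowed evoked deflection.

    ``amplitude`` is either one µV value for all listed channels or a
    mapping channel → µV (used to create PO7/PO8-style lateral asymmetry).
    """

    channels: tuple[str, ...]
    latency: float                           # s post-onset
    width: float = 0.03                      # Gaussian σ, s
    amplitude: float | dict[str, float] = 5.0
    conditions: tuple[str, ...] = _ALL_CONDITIONS

    def amplitude_for(self, channel: str) -> float:
        if isinstance(self.amplitude, dict):
            return float(self.amplitude.get(channel, 0.0))
        return float(self.amplitude)


@dataclass
class SynthConfig:
    """Full description of one synthetic participant's recording session."""

    sampling_rate: float = 500.0
    montage_preset: str = "paper64"
    channel_names: tuple[str, ...] | None = None   # default: full montage
    n_trials_per_condition: int = 35
    conditions: tuple[str, ...] = _ALL_CONDITIONS
    sessions: tuple[str, ...] = ("orange", "bottle", "phone")
    epoch_window: tuple[float, float] = (-0.2, 1.0)
    noise_exponent: float = 1.0              # 1/f^α spectral slope
    noise_amplitude: float = 15.0            # µV RMS per channel
    coupling_specs: tuple[CouplingSpec, ...] = ()
    power_specs: tuple[PowerModSpec, ...] = ()
    erp_specs: tuple[ErpSpec, ...] = ()
    blink_rate: float = 6.0                  # events / minute
    outlier_trial_fraction: float = 0.02
    fixation_duration: float = 1.0           # s before each stimulus
    stimulus_duration: float = 1.0           # s (unstated upstream; default 1 s)
    iti_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def resolve_montage(self) -> Montage:
        return generate_montage(self.montage_preset)

    def resolved_channels(self, montage: Montage | None = None) -> list[str]:
        montage = montage or self.resolve_montage()
        if self.channel_names is None:
            return list(montage.channel_names)
        return list(self.channel_names)

    def validate(self) -> None:
        montage = self.resolve_montage()
        channels = self.resolved_channels(montage)
        unknown = [c for c in channels if c not in montage.positions]
        if unknown:
            raise ValueError(f"channels not in montage {self.montage_preset!r}: {unknown}")
        if not 0.0 <= self.outlier_trial_fraction <= 1.0:
            raise ValueError("outlier_trial_fraction must be in [0, 1]")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window must be (tmin, tmax) with tmin < tmax")
        top = 30.0
        for spec in self.coupling_specs:
            top = max(top, spec.band_center)
            if spec.concentration < 0:
                raise ValueError("von Mises concentration must be >= 0")
            self._check_window(spec.window, "coupling")
            self._check_channels(spec.target_channels, channels)
            montage.region(spec.seed_region)
        for spec in self.power_specs:
            top = max(top, spec.band[1])
            if spec.gain <= 0:
                raise ValueError("power gain must be > 0")
            self._check_window(spec.window, "power modulation")
            self._check_channels(spec.channels, channels)
        for spec in self.erp_specs:
            if not self.epoch_window[0] <= spec.latency <= self.epoch_window[1]:
                raise ValueError(
                    f"ERP latency {spec.latency} s outside epoch window {self.epoch_window}"
                )
            self._check_channels(spec.channels, channels)
        if self.sampling_rate <= 2 * top:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz must exceed twice the highest "
                f"synthesized frequency ({top} Hz)"
            )

    def _check_window(self, window: tuple[float, float], what: str) -> None:
        lo, hi = window
        if lo >= hi or lo < self.epoch_window[0] or hi > self.epoch_window[1]:
            raise ValueError(
                f"{what} window {window} outside epoch window {self.epoch_window}"
            )

    @staticmethod
    def _check_channels(requested: tuple[str, ...], available: list[str]) -> None:
        missing = [c for c in requested if c not in available]
        if missing:
            raise ValueError(f"spec references channels not being synthesized: {missing}")


@dataclass
class TruthTables:
    """Machine-readable record of every injected effect, for scoring."""

    coupling: pd.DataFrame   # channel, band_center, tmin, tmax, condition, kappa, phase_lag
    power: pd.DataFrame      # channel, band_low, band_high, gain, tmin, tmax, condition
    erp: pd.DataFrame        # channel, latency, width, amplitude, condition


def ground_truth(config: SynthConfig) -> TruthTables:
    """Tabulate which (channel, band, window, condition) cells carry effects."""
    config.validate()
    coupling_rows, power_rows, erp_rows = [], [], []
    for spec in config.coupling_specs:
        for cond in spec.conditions:
            for ch in spec.target_channels:
                coupling_rows.append({
                    "channel": ch, "band_center": spec.band_center,
                    "tmin": spec.window[0], "tmax": spec.window[1],
                    "condition": cond, "kappa": spec.concentration,
                    "phase_lag": spec.phase_lag,
                })
    for spec in config.power_specs:
        for cond in spec.conditions:
            for ch in spec.channels:
                power_rows.append({
                    "channel": ch, "band_low": spec.band[0], "band_high": spec.band[1],
                    "gain": spec.gain, "tmin": spec.window[0], "tmax": spec.window[1],
                    "condition": cond,
                })
    for spec in config.erp_specs:
        for cond in spec.conditions:
            for ch in spec.channels:
                erp_rows.append({
                    "channel": ch, "latency": spec.latency, "width": spec.width,
                    "amplitude": spec.amplitude_for(ch), "condition": cond,
                })
    cols_c = ["channel", "band_center", "tmin", "tmax", "condition", "kappa", "phase_lag"]
    cols_p = ["channel", "band_low", "band_high", "gain", "tmin", "tmax", "condition"]
    cols_e = ["channel", "latency", "width", "amplitude", "condition"]
    return TruthTables(
        coupling=pd.DataFrame(coupling_rows, columns=cols_c),
        power=pd.DataFrame(power_rows, columns=cols_p),
        erp=pd.DataFrame(erp_rows, columns=cols_e),
    )


def _pink_noise(rng: np.random.Generator, n_channels: int, n_times: int,
                exponent: float, amplitude: float) -> np.ndarray:
    """1/f^α noise, each channel scaled to ``amplitude`` µV RMS."""
    white = rng.standard_normal((n_channels, n_times))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_times)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n_times, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return x * (amplitude / rms)


def _window_envelope(n: int, sampling_rate: float, ramp: float = 0.05) -> np.ndarray:
    """Unit-plateau envelope with raised-cosine ramps of ``ramp`` seconds."""
    env = np.ones(n)
    k = min(int(round(ramp * sampling_rate)), n // 2)
    if k > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
        env[:k] = edge
        env[-k:] = edge[::-1]
    return env


def _blink_template(sampling_rate: float, duration: float = 0.4) -> np.ndarray:
    n = int(round(duration * sampling_rate))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))


def generate_recording(config: SynthConfig, return_parts: bool = False):
    """Render one synthetic participant.

    Returns the :class:`~eegconn.core.ContinuousRecording`; with
    ``return_parts=True`` also a dict of the injected artifact waveforms
    (``blink_source``: the shared blink time course, ``blink_weights``:
    its per-channel spatial gain) for artifact-removal scoring.
    """
    config.validate()
    montage = config.resolve_montage()
    channels = config.resolved_channels(montage)
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)
    ch_index = {c: i for i, c in enumerate(channels)}

    # --- trial timeline -------------------------------------------------
    trial_conditions: list[str] = []
    trial_sessions: list[str] = []
    for session in config.sessions:
        conds = np.repeat(config.conditions, config.n_trials_per_condition)
        conds = conds[rng.permutation(conds.size)]
        trial_conditions.extend(conds.tolist())
        trial_sessions.extend([session] * conds.size)
    n_trials = len(trial_conditions)
    itis = rng.uniform(*config.iti_range, size=n_trials)
    onsets = np.empty(n_trials)
    t = config.fixation_duration
    for i in range(n_trials):
        onsets[i] = t
        t += config.stimulus_duration + itis[i] + config.fixation_duration
    tail = max(config.epoch_window[1], config.stimulus_duration) + 1.0
    n_times = int(np.ceil((onsets[-1] + tail) * fs))
    onset_samples = np.round(onsets * fs).astype(int)

    # --- background -----------------------------------------------------
    data = _pink_noise(rng, len(channels), n_times,
                       config.noise_exponent, config.noise_amplitude)

    # --- band-power modulation (scales the background's band component) --
    for spec in config.power_specs:
        i0_off = int(round(spec.window[0] * fs))
        seg_len = int(round((spec.window[1] - spec.window[0]) * fs))
        env = _window_envelope(seg_len, fs)
        for ch in spec.channels:
            row = ch_index[ch]
            band_component = fft_bandpass(data[row], fs, *spec.band)
            for tr in range(n_trials):
                if trial_conditions[tr] not in spec.conditions:
                    continue
                s0 = onset_samples[tr] + i0_off
                seg = slice(s0, s0 + seg_len)
                data[row, seg] += (spec.gain - 1.0) * env * band_component[seg]

    # --- phase coupling -------------------------------------------------
    # NB: after common-average referencing, -1/n_channels of every injected
    # oscillation necessarily reappears in all other channels; amplitudes
    # must stay small enough that this reference leak sits below the group
    # screen's detection floor or "uninjected" loses its meaning.
    for spec in config.coupling_specs:
        seed_rows = [ch_index[c] for c in montage.region(spec.seed_region)
                     if c in ch_index]
        if not seed_rows:
            raise ValueError(f"no channels of seed region {spec.seed_region!r} synthesized")
        target_rows = [ch_index[c] for c in spec.target_channels]
        i0_off = int(round(spec.window[0] * fs))
        seg_len = int(round((spec.window[1] - spec.window[0]) * fs))
        env = _window_envelope(seg_len, fs)
        t_rel = np.arange(seg_len) / fs
        omega = 2 * np.pi * spec.band_center
        for tr in range(n_trials):
            phase0 = rng.uniform(0, 2 * np.pi)
            if np.isinf(spec.concentration):
                jitters = np.zeros(len(target_rows))
            else:
                jitters = rng.vonmises(0.0, spec.concentration, size=len(target_rows))
            if trial_conditions[tr] not in spec.conditions:
                continue   # draws above keep the stream aligned across conditions
            s0 = onset_samples[tr] + i0_off
            seg = slice(s0, s0 + seg_len)
            carrier = spec.amplitude * env
            data[seed_rows, seg] += carrier * np.cos(omega * t_rel + phase0)
            for row, jit in zip(target_rows, jitters):
                data[row, seg] += carrier * np.cos(
                    omega * t_rel + phase0 + spec.phase_lag + jit)

    # --- ERPs -----------------------------------------------------------
    for spec in config.erp_specs:
        half = int(round(4 * spec.width * fs))
        t_rel = np.arange(-half, half + 1) / fs
        kernel = np.exp(-0.5 * (t_rel / spec.width) ** 2)
        lat = int(round(spec.latency * fs))
        for tr in range(n_trials):
            if trial_conditions[tr] not in spec.conditions:
                continue
            center = onset_samples[tr] + lat
            seg = slice(center - half, center + half + 1)
            for ch in spec.channels:
                data[ch_index[ch], seg] += spec.amplitude_for(ch) * kernel

    # --- blink artifacts ------------------------------------------------
    blink_source = np.zeros(n_times)
    pole = np.array([0.0, 0.95])
    dists = np.linalg.norm(montage.position_array(channels) - pole, axis=1)
    blink_weights = np.exp(-dists / 0.35)
    n_blinks = rng.poisson(config.blink_rate * (n_times / fs) / 60.0)
    template = _blink_template(fs)
    for _ in range(n_blinks):
        s0 = int(rng.uniform(0, n_times - template.size))
        blink_source[s0:s0 + template.size] += 120.0 * template
    data += blink_weights[:, None] * blink_source[None, :]

    # --- outlier trials -------------------------------------------------
    frontal = set(montage.region("FRONTAL_POLE"))
    candidate_rows = [i for c, i in ch_index.items() if c not in frontal]
    outlier_flags = rng.random(n_trials) < config.outlier_trial_fraction
    sigma = 0.06
    half = int(round(4 * sigma * fs))
    t_rel = np.arange(-half, half + 1) / fs
    pulse = 180.0 * np.exp(-0.5 * (t_rel / sigma) ** 2)
    for tr in np.flatnonzero(outlier_flags):
        row = candidate_rows[rng.integers(len(candidate_rows))]
        lo = onset_samples[tr] + int(round((config.epoch_window[0] + 0.1) * fs))
        hi = onset_samples[tr] + int(round((config.epoch_window[1] - 0.1) * fs))
        center = int(rng.uniform(lo, hi))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[row, center - half:center + half + 1] += sign * pulse

    events = [Event(int(s), c, sess)
              for s, c, sess in zip(onset_samples, trial_conditions, trial_sessions)]
    rec = ContinuousRecording(data, fs, channels, events)
    if return_parts:
        return rec, {"blink_source": blink_source, "blink_weights": blink_weights,
                     "outlier_trials": np.flatnonzero(outlier_flags)}
    return rec
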