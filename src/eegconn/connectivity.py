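"""Occipital-seeded phase-locking connectivity and the ePLV screen.

The seed is a virtual channel: the time-domain average of the six
occipital/parieto-occipital electrodes (Oz, O1, O2, POz, PO3, PO4).
Instantaneous phase comes from the analytic signal (Hilbert transform) of
band-limited epochs.  The phase-locking value at time t across n epochs is
the *squared* resultant length of the phase differences,

    PLV_t = [mean_k cos(Δθ_k,t)]² + [mean_k sin(Δθ_k,t)]²,

whose null expectation for uniform phases is 1/n.  (The conventional
resultant length — the square root — is available as ``convention="sqrt"``;
the screening below is invariant to that monotone choice.)

A PLV time point becomes an *effective* PLV (ePLV) when the across-
participant sample of PLVs at that point is significantly above the
participants' baseline levels, judged by the paired bootstrap test: for
each participant the pre-stimulus baseline PLVs are bootstrap-averaged into
a grand mean, and at each (electrode, time) the across-participant PLVs are
paired against those grand means (one-tailed, PLV > baseline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import BandSpec, EpochSet
from .montage import Montage, OCCIPITAL_SEED
from .stats import bootstrap_paired_pvalues

__all__ = [
    "PLVSeries", "EPLVMask", "fuse_occipital", "instantaneous_phase",
    "plv_series", "bootstrap_baseline_mean", "screen_eplv", "connection_summary",
]


@dataclass
class PLVSeries:
    """Seed-to-target phase locking over time (values in [0, 1])."""

    values: np.ndarray            # (n_times,)
    times: np.ndarray             # s
    n_epochs: int
    seed_region: str = "OCC_SEED"
    target: str = ""
    band: BandSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_epochs < 2:
            raise ValueError("PLV needs at least 2 epochs")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("PLV values must lie in [0, 1]")


@dataclass
class EPLVMask:
    """Significance screen over (target electrode, time)."""

    significant: np.ndarray       # (n_targets, n_times) bool
    p_values: np.ndarray          # (n_targets, n_times)
    targets: list[str]
    times: np.ndarray
    alpha: float
    baseline_means: np.ndarray    # (n_participants, n_targets) grand bootstrap means
    n_boot: int
    seed: int | None


def fuse_occipital(epochs: EpochSet, montage: Montage | None = None) -> np.ndarray:
    """Average the six occipital-seed channels into one virtual channel.

    Returns (n_epochs, n_times).  Fusion is at the signal level, before any
    phase extraction, so it is linear in the input.
    """
    labels = montage.region("OCC_SEED") if montage is not None else list(OCCIPITAL_SEED)
    missing = [c for c in labels if c not in epochs.channel_names]
    if missing:
        raise ValueError(f"occipital seed channels missing from epochs: {missing}")
    idx = [epochs.channel_index(c) for c in labels]
    return epochs.data[:, idx, :].mean(axis=1)


def instantaneous_phase(signal: np.ndarray, sampling_rate: float,
                        pad: float = 0.2) -> np.ndarray:
    """Analytic-signal phase in (−π, π], along the last axis.

    The input must be band-limited for the phase to be meaningful.  Each
    epoch is mirror-padded ``pad`` seconds per side before the Hilbert
    transform; the pads are discarded, keeping edge transients out of the
    baseline window.
    """
    x = np.asarray(signal, dtype=float)
    if np.ptp(x, axis=-1).max() == 0:
        raise ValueError("constant input has no defined instantaneous phase")
    n = x.shape[-1]
    k = min(int(round(pad * sampling_rate)), n - 1)
    if k > 0:
        x = np.concatenate([x[..., k:0:-1], x, x[..., -2:-k - 2:-1]], axis=-1)
    phase = np.angle(hilbert(x, axis=-1))
    return phase[..., k:k + n] if k > 0 else phase


def plv_series(seed_phases: np.ndarray, target_phases: np.ndarray,
               times: np.ndarray | None = None, convention: str = "squared",
               **meta) -> PLVSeries:
    """Across-epoch phase locking at every time point.

    ``seed_phases`` and ``target_phases`` are (n_epochs, n_times) radian
    arrays on the same time axis.  ``convention="squared"`` (default) is the
    squared resultant length; ``"sqrt"`` gives the conventional resultant.
    """
    sp = np.asarray(seed_phases, dtype=float)
    tp = np.asarray(target_phases, dtype=float)
    if sp.shape != tp.shape:
        raise ValueError(f"phase arrays differ in shape: {sp.shape} vs {tp.shape}")
    n = sp.shape[0]
    if n < 2:
        raise ValueError("PLV needs at least 2 epochs")
    diff = sp - tp
    values = np.cos(diff).mean(axis=0) ** 2 + np.sin(diff).mean(axis=0) ** 2
    if convention == "sqrt":
        values = np.sqrt(values)
    elif convention != "squared":
        raise ValueError(f"unknown convention {convention!r}")
    if times is None:
        times = np.arange(sp.shape[1], dtype=float)
    return PLVSeries(values, np.asarray(times, dtype=float), n, **meta)


def bootstrap_baseline_mean(values: np.ndarray, baseline_mask: np.ndarray,
                            n_boot: int = 10_000,
                            rng: np.random.Generator | int | None = None) -> float:
    """Grand mean of bootstrap averages of the baseline-window PLVs.

    Draws the baseline values with replacement (same size), averages,
    repeats ``n_boot`` times, and returns the mean of those averages — the
    central-limit baseline level a participant's series is tested against.
    """
    base = np.asarray(values, dtype=float)[np.asarray(baseline_mask, dtype=bool)]
    if base.size < 2:
        raise ValueError("baseline window must contain at least 2 time samples")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, base.size, size=(n_boot, base.size))
    return float(base[idx].mean(axis=1).mean())


def screen_eplv(plv_stack: np.ndarray, times: np.ndarray, targets: list[str],
                baseline_window: tuple[float, float] = (-0.2, 0.0),
                alpha: float = 0.05, n_boot: int = 10_000,
                seed: int | None = None) -> EPLVMask:
    """Screen a participants × targets × times PLV stack into ePLVs.

    At each (target, time), the across-participant PLV sample is paired
    against the per-participant baseline grand means and tested one-tailed
    (PLV > baseline) with the paired bootstrap; the mask marks p′ ≤ alpha.
    """
    stack = np.asarray(plv_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("plv_stack must be (participants, targets, times)")
    n_part, n_targ, n_times = stack.shape
    if n_part < 2:
        raise ValueError("ePLV screening needs at least 2 participants")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    times = np.asarray(times, dtype=float)
    base_mask = (times >= baseline_window[0]) & (times < baseline_window[1])
    if base_mask.sum() < 2:
        raise ValueError("baseline window must contain at least 2 time samples")
    rng = np.random.default_rng(seed)
    baseline_means = np.empty((n_part, n_targ))
    for p in range(n_part):
        for t in range(n_targ):
            baseline_means[p, t] = bootstrap_baseline_mean(
                stack[p, t], base_mask, n_boot=n_boot, rng=rng)
    p_values = np.empty((n_targ, n_times))
    for t in range(n_targ):
        # (n_times, n_participants) paired differences vs the baseline level
        diffs = (stack[:, t, :] - baseline_means[:, t][:, None]).T
        p_values[t] = bootstrap_paired_pvalues(np.ascontiguousarray(diffs), n_boot, rng)
    significant = p_values <= alpha
    if alpha == 0:
        significant[:] = False
    return EPLVMask(significant, p_values, list(targets), times, alpha,
                    baseline_means, n_boot, seed)


def connection_summary(mask: EPLVMask) -> dict:
    """Connections per time sample and the (earliest) peak-connection time."""
    counts = mask.significant.sum(axis=0)
    peak_idx = int(np.argmax(counts))  # argmax takes the earliest tie
    return {
        "counts": counts,
        "times": mask.times,
        "peak_time": float(mask.times[peak_idx]),
        "peak_count": int(counts[peak_idx]),
        "total_significant": int(mask.significant.sum()),
    }
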