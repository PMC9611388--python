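"""End-to-end orchestration: synthesize → preprocess → connectivity → spectra.

The pipeline loops participants outermost, caching per-participant
intermediates (band-wise PLV stacks, mu-rhythm ERSP time courses, ERP
window means) under ``<outdir>/cache`` so the group-level screens can be
re-run without recomputation, then runs the group analyses:

* per frequency band, the ePLV screen of occipital-seeded PLVs against
  bootstrap baseline levels, with connection counts over time;
* the mu-rhythm (8–13 Hz) ERD/ERS time course over the somatosensory ROI,
  compared between two conditions by permutation test at the ERS window;
* an alpha-ERSP scalp topography snapshot, surface-Laplacian sharpened;
* the PO7–PO8 ERP lateralization contrast with a one-way ANOVA.

Every stochastic stage derives its seed from ``RunConfig.seed`` and the
participant index, and all group tables are written as TSV so a re-run with
the same configuration reproduces them byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import preprocess as pre
from . import spectral as spec
from .core import BandSpec, DEFAULT_BANDS
from .montage import generate_montage
from .synth import CouplingSpec, ErpSpec, PowerModSpec, SynthConfig

__all__ = ["RunConfig", "ResultsBundle", "validate", "run", "demo_config"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs, with the global seed."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    n_participants: int = 19
    montage_preset: str = "paper64"
    bandpass: tuple[float, float] = (1.0, 30.0)
    amuse_lag: int = 1
    eog_threshold: float = 0.7
    reject_threshold: float = 100.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    alpha: float = 0.05
    n_boot: int = 10_000
    plv_convention: str = "squared"
    plv_decim: int = 5
    ersp_freqs: tuple[float, ...] = tuple(float(f) for f in range(8, 14))
    mu_roi: str = "LS"
    ers_window: tuple[float, float] = (0.10, 0.20)
    topo_snapshot: float = 0.40
    erp_left: str = "PO7"
    erp_right: str = "PO8"
    erp_window: tuple[float, float] = (0.246, 0.300)
    condition_objects: str = "A"
    condition_interactions: str = "D"
    seed: int = 0

    def participant_seed(self, i: int) -> int:
        return int((self.seed * 1009 + 7919 * (i + 1)) % (2**31))


@dataclass
class ResultsBundle:
    """Paths and in-memory copies of everything the run produced."""

    outdir: Path
    rejection_report: pd.DataFrame
    eplv_masks: dict[str, conn.EPLVMask]
    connection_summaries: pd.DataFrame
    mu_timecourses: dict[str, np.ndarray]     # condition -> (participants, times)
    mu_times: np.ndarray
    ers_test: dict
    topography: pd.DataFrame
    erp_table: pd.DataFrame
    erp_anova: dict
    manifest: dict


def validate(config: RunConfig) -> list[str]:
    """Collect configuration errors without computing anything."""
    errors: list[str] = []
    try:
        montage = generate_montage(config.montage_preset)
    except ValueError as exc:
        return [str(exc)]
    if not 0 < config.alpha < 1:
        errors.append(f"alpha must be in (0,1), got {config.alpha}")
    if config.n_participants < 2:
        errors.append("need at least 2 participants for the group screen")
    if config.n_boot < 1:
        errors.append("n_boot must be positive")
    if config.plv_decim < 1:
        errors.append("plv_decim must be >= 1")
    for ch in (config.erp_left, config.erp_right):
        if ch not in montage.positions:
            errors.append(f"unknown electrode {ch!r} in ERP contrast")
    try:
        montage.region(config.mu_roi)
    except KeyError as exc:
        errors.append(str(exc).strip('"'))
    for band in config.bands:
        try:
            band.validate(config.synth.sampling_rate)
        except ValueError as exc:
            errors.append(str(exc))
    lo, hi = config.bandpass
    if not 0 < lo < hi < config.synth.sampling_rate / 2:
        errors.append(f"bandpass {config.bandpass} invalid for fs={config.synth.sampling_rate}")
    for cond in (config.condition_objects, config.condition_interactions):
        if cond not in config.synth.conditions:
            errors.append(f"condition {cond!r} not generated by the synth config")
    try:
        config.synth.validate()
    except ValueError as exc:
        errors.append(f"synth: {exc}")
    return errors


def _preprocess_participant(config: RunConfig, participant: int):
    """Synthesize and fully preprocess one participant; returns clean epochs."""
    from .synth import generate_recording
    synth_cfg = replace(config.synth, seed=config.participant_seed(participant))
    rec = generate_recording(synth_cfg)
    rec = pre.rereference_common_average(rec)
    rec = pre.bandpass_zero_phase(rec, *config.bandpass)
    decomposition = pre.amuse_decompose(rec, lag=config.amuse_lag)
    montage = generate_montage(config.montage_preset)
    proxies = [c for c in montage.region("FRONTAL_POLE") if c in rec.channel_names]
    rec, removed = pre.remove_eog_components(
        decomposition, proxies, threshold=config.eog_threshold)
    epochs = pre.extract_epochs(rec, *config.synth.epoch_window)
    epochs = pre.reject_amplitude(epochs, threshold=config.reject_threshold)
    return epochs, removed


def _participant_connectivity(config: RunConfig, epochs) -> dict[str, np.ndarray]:
    """Band-wise PLV stacks (targets × decimated times) for one participant."""
    montage = generate_montage(config.montage_preset)
    seed_set = set(montage.region("OCC_SEED"))
    targets = [c for c in epochs.channel_names if c not in seed_set]
    per_band = pre.filter_bands(epochs, config.bands)
    out: dict[str, np.ndarray] = {}
    d = config.plv_decim
    for band in config.bands:
        band_epochs = per_band[band.name]
        seed_signal = conn.fuse_occipital(band_epochs, montage)
        seed_phase = conn.instantaneous_phase(seed_signal, epochs.sampling_rate)
        rows = []
        for target in targets:
            tphase = conn.instantaneous_phase(
                band_epochs.get_channel(target), epochs.sampling_rate)
            series = conn.plv_series(
                seed_phase[:, ::d], tphase[:, ::d],
                times=epochs.times[::d], convention=config.plv_convention,
                target=target, band=band)
            rows.append(series.values)
        out[band.name] = np.array(rows)
    return out


def _hash_config(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(str(type(o)))
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig, outdir: str | Path, figures: bool = False,
        log=print) -> ResultsBundle:
    """Execute the full analysis and write the results bundle to ``outdir``."""
    errors = validate(config)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    outdir = Path(outdir)
    cache = outdir / "cache"
    cache.mkdir(parents=True, exist_ok=True)
    montage = generate_montage(config.montage_preset)
    seed_set = set(montage.region("OCC_SEED"))
    t0 = time.time()

    # ---- per-participant stage (cached) --------------------------------
    rejection_rows = []
    erp_rows = []
    mu_tc: dict[str, list[np.ndarray]] = {config.condition_objects: [],
                                          config.condition_interactions: []}
    plv_stacks: dict[str, list[np.ndarray]] = {b.name: [] for b in config.bands}
    topo_values = []
    targets: list[str] = []
    plv_times = mu_times = None
    for i in range(config.n_participants):
        cache_file = cache / f"participant_{i:02d}.npz"
        if cache_file.exists():
            stage = dict(np.load(cache_file, allow_pickle=True))
            log(f"[pipeline] participant {i}: loaded cache")
        else:
            stage = _compute_participant(config, i, montage)
            np.savez_compressed(cache_file, **stage)
            log(f"[pipeline] participant {i}: computed "
                f"({time.time() - t0:.0f}s elapsed)")
        for band in config.bands:
            plv_stacks[band.name].append(stage[f"plv_{band.name}"])
        plv_times = stage["plv_times"]
        mu_times = stage["mu_times"]
        for cond in mu_tc:
            mu_tc[cond].append(stage[f"mu_tc_{cond}"])
        topo_values.append(stage["topo_alpha"])
        targets = [str(c) for c in stage["targets"]]
        rej = stage["rejection"]
        rejection_rows.append({
            "participant": i, "n_events": int(rej[0]), "n_kept": int(rej[1]),
            "n_amplitude_rejected": int(rej[2]), "n_eog_components": int(rej[3]),
            "survival_fraction": float(rej[1] / max(rej[0], 1)),
        })
        for cond, wmean in zip(stage["erp_conditions"], stage["erp_window_means"]):
            erp_rows.append({"participant": i, "condition": str(cond),
                             "window_mean": float(wmean)})

    rejection_report = pd.DataFrame(rejection_rows)
    rejection_report.to_csv(outdir / "rejection_report.tsv", sep="\t", index=False)

    # ---- group stage: ePLV screens -------------------------------------
    eplv_masks: dict[str, conn.EPLVMask] = {}
    summary_rows = []
    for k, band in enumerate(config.bands):
        stack = np.stack(plv_stacks[band.name])       # (part, targets, times)
        mask = conn.screen_eplv(
            stack, plv_times, targets,
            baseline_window=(config.synth.epoch_window[0], 0.0),
            alpha=config.alpha, n_boot=config.n_boot,
            seed=int((config.seed + 10_001 + k) % (2**31)))
        eplv_masks[band.name] = mask
        table = pd.DataFrame({
            "band": band.name,
            "electrode": np.repeat(targets, plv_times.size),
            "time": np.tile(np.round(plv_times, 6), len(targets)),
            "plv_mean": np.round(stack.mean(axis=0).ravel(), 9),
            "p_value": np.round(mask.p_values.ravel(), 9),
            "significant": mask.significant.ravel(),
        })
        table.to_csv(outdir / f"eplv_{band.name}.tsv", sep="\t", index=False)
        s = conn.connection_summary(mask)
        summary_rows.append({"band": band.name, "peak_time": s["peak_time"],
                             "peak_count": s["peak_count"],
                             "total_significant": s["total_significant"]})
        log(f"[pipeline] band {band.name}: peak {s['peak_count']} connections "
            f"at {s['peak_time'] * 1000:.0f} ms")
    connection_summaries = pd.DataFrame(summary_rows)
    connection_summaries.to_csv(outdir / "connection_summary.tsv", sep="\t", index=False)

    # ---- group stage: mu-rhythm ERD/ERS --------------------------------
    mu_stacks = {c: np.stack(v) for c, v in mu_tc.items()}
    mu_table_rows = []
    for cond, stack_tc in mu_stacks.items():
        mu_table_rows.append(pd.DataFrame({
            "condition": cond, "time": np.round(mu_times, 6),
            "ersp_mean": np.round(stack_tc.mean(axis=0), 9),
            "ersp_se": np.round(stack_tc.std(axis=0, ddof=1)
                                / np.sqrt(stack_tc.shape[0]), 9),
        }))
    pd.concat(mu_table_rows).to_csv(outdir / "ersp_mu_timecourse.tsv",
                                    sep="\t", index=False)
    ers_res = spec.compare_window_between_conditions(
        mu_stacks[config.condition_interactions],
        mu_stacks[config.condition_objects],
        mu_times, config.ers_window, n_resamples=config.n_boot,
        seed=int((config.seed + 20_001) % (2**31)))
    ers_test = {"window": config.ers_window, "v0": ers_res.statistic_v0,
                "p": ers_res.p_value,
                "significant": bool(ers_res.p_value <= config.alpha)}
    log(f"[pipeline] ERS window {config.ers_window}: interactions - objects "
        f"= {ers_res.statistic_v0:+.2f} dB, permutation p = {ers_res.p_value:.4f}")

    # ---- group stage: Laplacian topography snapshot --------------------
    topo = np.stack(topo_values).mean(axis=0)         # (channels,)
    lap = spec.surface_laplacian(topo, montage, list(montage.channel_names))
    pos = montage.position_array()
    topography = pd.DataFrame({
        "channel": montage.channel_names,
        "x": np.round(pos[:, 0], 6), "y": np.round(pos[:, 1], 6),
        "ersp_alpha_db": np.round(topo, 9),
        "laplacian": np.round(lap, 9),
    })
    topography.to_csv(outdir / "topography_alpha.tsv", sep="\t", index=False)

    # ---- group stage: ERP lateralization -------------------------------
    erp_df = pd.DataFrame(erp_rows)
    erp_groups = [erp_df.loc[erp_df.condition == c, "window_mean"].to_numpy()
                  for c in sorted(erp_df.condition.unique())]
    from .stats import anova_one_way
    conds_sorted = sorted(erp_df.condition.unique())
    erp_anova: dict = {}
    if len(erp_groups) >= 2 and all(g.size >= 2 for g in erp_groups):
        f_stat, p, pairwise = anova_one_way(erp_groups, alpha=config.alpha)
        erp_anova = {"F": f_stat, "p": p,
                     "pairwise": {f"{conds_sorted[i]}-{conds_sorted[j]}": flag
                                  for (i, j), flag in pairwise.items()}}
        log(f"[pipeline] PO7-PO8 lateralization ANOVA: F = {f_stat:.2f}, p = {p:.4f}")
    erp_table = (erp_df.groupby("condition")["window_mean"]
                 .agg(["mean", "sem", "count"]).reset_index())
    erp_table.to_csv(outdir / "erp_lateralization.tsv", sep="\t", index=False)

    manifest = {
        "config_hash": _hash_config(config),
        "seed": config.seed,
        "participant_seeds": [config.participant_seed(i)
                              for i in range(config.n_participants)],
        "n_boot": config.n_boot,
        "versions": {"python": sys.version.split()[0],
                     "numpy": np.__version__, "pandas": pd.__version__},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "elapsed_s": round(time.time() - t0, 1),
        "ers_test": ers_test,
        "erp_anova": erp_anova,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    if figures:
        _write_figures(outdir, montage, topography, mu_stacks, mu_times, config)

    return ResultsBundle(outdir, rejection_report, eplv_masks, connection_summaries,
                         mu_stacks, mu_times, ers_test, topography,
                         erp_table, erp_anova, manifest)


def _compute_participant(config: RunConfig, i: int, montage) -> dict:
    """All per-participant computation, returned as plain arrays for caching."""
    epochs, removed = _preprocess_participant(config, i)
    n_events = len(epochs.rejection_log)
    n_kept = int(epochs.rejection_log["kept"].sum()) if n_events else epochs.n_epochs
    n_amp = int((epochs.rejection_log["reason"].str.contains("amplitude")).sum()) \
        if n_events else 0

    stage: dict = {"rejection": np.array([n_events, n_kept, n_amp, len(removed)])}
    plv = _participant_connectivity(config, epochs)
    for name, stack in plv.items():
        stage[f"plv_{name}"] = stack
    seed_set = set(montage.region("OCC_SEED"))
    stage["targets"] = np.array(
        [c for c in epochs.channel_names if c not in seed_set])
    stage["plv_times"] = epochs.times[::config.plv_decim]

    # mu-rhythm ERSP over all channels (topography) and the ROI time course
    tfr = spec.morlet_tfr(epochs, np.array(config.ersp_freqs))
    ersp_map = spec.ersp(tfr, baseline_window=(config.synth.epoch_window[0], 0.0))
    snap = int(np.argmin(np.abs(ersp_map.times - config.topo_snapshot)))
    stage["topo_alpha"] = ersp_map.values[:, :, snap].mean(axis=1)
    stage["mu_times"] = ersp_map.times
    roi = montage.region(config.mu_roi)
    for cond in (config.condition_objects, config.condition_interactions):
        sel = [k for k, c in enumerate(epochs.conditions) if c == cond]
        cond_tfr = spec.TFR(tfr.magnitude[sel], tfr.freqs, tfr.times,
                            tfr.channels, tfr.edge_mask)
        cond_map = spec.ersp(cond_tfr,
                             baseline_window=(config.synth.epoch_window[0], 0.0))
        stage[f"mu_tc_{cond}"] = cond_map.band_average((8.0, 13.0), roi)

    erp = spec.erp_lateralization(epochs, config.erp_left, config.erp_right,
                                  window=config.erp_window)
    stage["erp_conditions"] = np.array(erp["conditions"])
    stage["erp_window_means"] = np.array(
        [erp["per_condition"][c]["window_mean"] for c in erp["conditions"]])
    return stage


def _write_figures(outdir, montage, topography, mu_stacks, mu_times, config):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    figdir = Path(outdir) / "figures"
    figdir.mkdir(exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
    for ax, col, title in zip(axes, ["ersp_alpha_db", "laplacian"],
                              ["alpha ERSP (dB)", "surface Laplacian"]):
        sc = ax.scatter(topography.x, topography.y, c=topography[col],
                        cmap="RdBu_r", s=120, edgecolors="k")
        ax.add_patch(plt.Circle((0, 0), 1.0, fill=False))
        ax.set_title(title)
        ax.set_aspect("equal")
        ax.axis("off")
        fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(figdir / "topography_alpha.png", dpi=120)
    plt.close(fig)
    fig, ax = plt.subplots(figsize=(7, 4))
    for cond, stack in mu_stacks.items():
        m = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        ax.plot(mu_times, m, label=f"condition {cond}")
        ax.fill_between(mu_times, m - se, m + se, alpha=0.3)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mu ERSP (dB)")
    ax.legend()
    fig.savefig(figdir / "mu_timecourse.png", dpi=120)
    plt.close(fig)


def demo_config(seed: int = 0, n_participants: int = 19,
                n_trials_per_condition: int = 12,
                n_boot: int = 1000) -> RunConfig:
    """Desk-scale demonstration configuration.

    One session, 4 conditions × ``n_trials_per_condition`` trials per
    participant.  Injects theta coupling from the occipital seed to three
    distal electrodes (ground truth for the ePLV screen), a mu-rhythm ERD
    and an interaction-only early ERS over the left somatosensory ROI, and
    a right-lateralized PO7/PO8 ERP in condition C.
    """
    synth = SynthConfig(
        sessions=("demo",),
        n_trials_per_condition=n_trials_per_condition,
        coupling_specs=(
            CouplingSpec(target_channels=("C3", "C4", "P4"), band_center=5.5,
                         concentration=4.0, window=(0.15, 0.40),
                         conditions=("A", "B", "C", "D")),
        ),
        power_specs=(
            PowerModSpec(channels=("C5", "CP3", "CP5"), band=(8.0, 13.0),
                         gain=0.5, window=(0.30, 0.70),
                         conditions=("A", "B", "C", "D")),
            PowerModSpec(channels=("C5", "CP3", "CP5"), band=(8.0, 13.0),
                         gain=1.8, window=(0.10, 0.20), conditions=("D",)),
        ),
        erp_specs=(
            ErpSpec(channels=("PO7", "PO8"), latency=0.15, width=0.03,
                    amplitude=4.0),
            ErpSpec(channels=("PO7", "PO8"), latency=0.26, width=0.03,
                    amplitude={"PO7": 2.0, "PO8": 6.0}, conditions=("C",)),
        ),
        blink_rate=6.0,
        outlier_trial_fraction=0.02,
        seed=seed,
    )
    return RunConfig(synth=synth, n_participants=n_participants,
                     n_boot=n_boot, seed=seed)
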